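"""Protein-level consequences of aberrant splicing events.

Given a built transcript and an observed splicing outcome (exon skipping,
partial exon deletion via a cryptic splice site, or intron retention), this
module edits the mRNA, re-derives the coding sequence from the original
start codon, names the protein change in HGVS p. notation, counts the
disrupted residues, and applies the >10%-of-protein PVS1_Strong rule.

Disrupted-residue conventions
-----------------------------
* in-frame deletion / delins: residues ``start..end`` inclusive;
* in-frame insertion: the number of inserted residues;
* frameshift and premature stop: every residue from the first altered one to
  the natural C-terminus, the first altered residue itself excluded from the
  count (``protein_length − first_altered``).

HGVS naming trims the maximal common prefix first and then the maximal
common suffix of the remainders, which places ambiguous deletions at their
3'-most (highest-numbered) representation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .reference import TranscriptModel, translate_cds


@dataclass(frozen=True)
class SpliceEvent:
    """One aberrant splicing outcome on a transcript element.

    ``element_index`` is the 1-based exon ordinal (skipping / partial
    deletion) or intron ordinal (retention) in transcript orientation.
    ``sub_interval`` is a 1-based inclusive range within the element, also in
    transcript orientation: required for partial exon deletions; for
    retentions it selects a sub-intronic segment that must stay anchored to
    one end of the intron (omitted = full retention).
    """

    event_type: str
    element_index: int
    sub_interval: tuple[int, int] | None = None

    EVENT_TYPES = ("exon_skipping", "partial_exon_deletion", "intron_retention")

    def __post_init__(self) -> None:
        if self.event_type not in self.EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.event_type == "partial_exon_deletion" and self.sub_interval is None:
            raise ValueError("partial_exon_deletion requires a sub_interval")
        if self.sub_interval is not None:
            s, e = self.sub_interval
            if s < 1 or e < s:
                raise ValueError(f"invalid sub_interval {self.sub_interval}")

    def describe(self, length_hint: int | None = None) -> str:
        elem = "Intron" if self.event_type == "intron_retention" else "Exon"
        if self.event_type == "exon_skipping":
            return f"Exon {self.element_index} skipping"
        if self.sub_interval is None:
            return f"Intron {self.element_index} retention"
        s, e = self.sub_interval
        nbp = e - s + 1
        verb = "retention" if self.event_type == "intron_retention" else "deletion"
        return f"{elem} {self.element_index} {nbp}bp {verb}"


@dataclass
class EditedTranscript:
    """Outcome of applying splicing events to a transcript's mRNA."""

    alt_mrna: str
    alt_cds: str | None  # from the original start codon to the mRNA 3' end
    net_cds_indel: int  # net inserted − deleted nucleotides within the CDS span
    start_lost: bool = False
    touches_cds: bool = True


@dataclass
class ProteinConsequence:
    """An HGVS p.-style protein change with disrupted-residue bookkeeping."""

    kind: str  # inframe_deletion | inframe_delins | inframe_insertion | frameshift | stop_gain | none
    start_res: int | None = None
    end_res: int | None = None
    inserted: str = ""
    fs_first_res: int | None = None
    fs_ref_aa: str | None = None
    fs_new_aa: str | None = None
    fs_stop_offset: int | None = None
    no_stop_found: bool = False
    hgvs_p: str = "p.(=)"
    disrupted_count: int = 0
    disrupted_fraction: float = 0.0
    note: str = ""


@dataclass(frozen=True)
class Pvs1Call:
    strength: str  # PVS1_Strong | not_met
    rationale: str


@dataclass(frozen=True)
class NcsvClass:
    """One of the six region × splicing-outcome classes (labels A–F)."""

    region: str  # exonic | intronic
    outcome: str
    label: str

    LABELS = {
        ("exonic", "exon_skipping"): "A",
        ("intronic", "exon_skipping"): "B",
        ("exonic", "partial_exon_deletion"): "C",
        ("intronic", "partial_exon_deletion"): "D",
        ("exonic", "intron_retention"): "E",
        ("intronic", "intron_retention"): "F",
    }


# ---------------------------------------------------------------------- #
# event application


def apply_event(t: TranscriptModel, events: SpliceEvent | list[SpliceEvent]) -> EditedTranscript:
    """Edit the mRNA of ``t`` according to one or more splicing events.

    Compound outcomes (one variant, several products of the same allele that
    co-occur in one molecule) are applied together; edits are positioned on
    the *reference* element coordinates and applied 3'→5' so indices stay
    valid. The CDS is re-derived from the original start codon; if an event
    removes the start codon, ``start_lost`` is set and ``alt_cds`` is None.
    """
    if isinstance(events, SpliceEvent):
        events = [events]
    if t.mrna is None:
        raise ValueError("transcript not built")

    lengths = t.exon_lengths()
    exon_t_start = []
    off = 0
    for ln in lengths:
        exon_t_start.append(off)
        off += ln

    # edits: (t_pos, deleted_len, inserted_seq); insertion at t_pos means
    # "insert before mRNA offset t_pos"
    edits: list[tuple[int, int, str]] = []
    for e in events:
        k = e.element_index
        if e.event_type in ("exon_skipping", "partial_exon_deletion"):
            if not 1 <= k <= t.n_exons:
                raise ValueError(f"exon index {k} out of range for {t.transcript_id}")
            a = exon_t_start[k - 1]
            ln = lengths[k - 1]
            if e.event_type == "exon_skipping":
                edits.append((a, ln, ""))
            else:
                s, sub_e = e.sub_interval
                if sub_e > ln:
                    raise ValueError(f"sub_interval {e.sub_interval} exceeds exon length {ln}")
                edits.append((a + s - 1, sub_e - s + 1, ""))
        else:  # intron_retention
            if not 1 <= k <= t.n_exons - 1:
                raise ValueError(f"intron index {k} out of range for {t.transcript_id}")
            intron = t.intron_seqs[k - 1]
            if e.sub_interval is None:
                seg, anchor = intron, "donor"
            else:
                s, sub_e = e.sub_interval
                if sub_e > len(intron):
                    raise ValueError(f"sub_interval {e.sub_interval} exceeds intron length {len(intron)}")
                if s != 1 and sub_e != len(intron):
                    raise ValueError("retention sub_interval must be anchored to one intron end")
                seg = intron[s - 1 : sub_e]
                anchor = "donor" if s == 1 else "acceptor"
            junction = exon_t_start[k - 1] + lengths[k - 1]  # first base of exon k+1
            edits.append((junction, 0, seg))

    # apply 3'→5'; insertions at the same point as a deletion start go after it
    alt = t.mrna
    for pos, dlen, ins in sorted(edits, key=lambda x: (x[0], x[1]), reverse=True):
        alt = alt[:pos] + ins + alt[pos + dlen :]

    # start-codon tracking and net in-CDS indel
    o = t._cds_offset
    cds_end_t = o + len(t.cds) - 1
    start_lost = False
    new_o = o
    net = 0
    touches = False
    for pos, dlen, ins in edits:
        del_lo, del_hi = pos, pos + dlen - 1
        if dlen and del_lo <= o + 2 and del_hi >= o:
            start_lost = True
        if dlen:
            ov = max(0, min(del_hi, cds_end_t) - max(del_lo, o) + 1)
            net -= ov
            if ov:
                touches = True
        else:
            if o < pos <= cds_end_t + 1:
                net += len(ins)
                touches = True
        if dlen and del_hi < o:
            new_o -= dlen
        elif dlen and del_lo < o:  # partial overlap upstream of start
            start_lost = True
        elif not dlen and pos <= o:
            new_o += len(ins)

    if start_lost:
        return EditedTranscript(alt, None, net, start_lost=True, touches_cds=touches)
    alt_cds = alt[new_o:]
    return EditedTranscript(alt, alt_cds, net, touches_cds=touches)


# ---------------------------------------------------------------------- #
# HGVS p. derivation


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def protein_consequence(
    ref_protein: str,
    alt_cds: str | None,
    frame_shifted: bool | None = None,
) -> ProteinConsequence:
    """Name the protein change between ``ref_protein`` and the edited CDS.

    ``frame_shifted`` should be supplied from the event arithmetic
    (``EditedTranscript.net_cds_indel % 3 != 0``) when available; with None it
    is inferred from whether the alternate translation recovers the reference
    C-terminus.
    """
    L = len(ref_protein)
    if alt_cds is None:
        return ProteinConsequence(kind="none", hgvs_p="p.?", note="start codon lost")
    if not alt_cds:
        raise ValueError("empty alternate CDS")
    alt, stopped = translate_cds(alt_cds)

    if alt == ref_protein and stopped:
        return ProteinConsequence(kind="none")

    p = _lcp(ref_protein, alt)
    if p >= L:
        return ProteinConsequence(
            kind="none", note="change begins beyond the reference C-terminus (stop-region only)"
        )

    # pure truncation: translation stops right where the proteins diverge
    if stopped and len(alt) == p and p < L:
        first = p + 1
        cons = ProteinConsequence(
            kind="stop_gain",
            start_res=first,
            end_res=first,
            fs_first_res=first,
            fs_ref_aa=ref_protein[p],
            hgvs_p=f"p.{ref_protein[p]}{first}*",
        )
        return _with_fraction(cons, L)

    if frame_shifted is None:
        s_probe = _lcs(ref_protein[p:], alt[p:])
        frame_shifted = (not stopped) or s_probe == 0

    if frame_shifted:
        first = p + 1
        if p >= len(alt):  # divergence is past the alt translation end
            first = len(alt) + 1
        ref_aa = ref_protein[first - 1] if first <= L else "*"
        new_aa = alt[first - 1] if first <= len(alt) else "?"
        n_stop = len(alt) - (first - 1) + 1 if stopped else None
        hgvs = f"p.{ref_aa}{first}{new_aa}fs*{n_stop if n_stop is not None else '?'}"
        cons = ProteinConsequence(
            kind="frameshift",
            fs_first_res=first,
            fs_ref_aa=ref_aa,
            fs_new_aa=new_aa,
            fs_stop_offset=n_stop,
            no_stop_found=not stopped,
            hgvs_p=hgvs,
        )
        return _with_fraction(cons, L)

    # in-frame: trim the maximal common suffix of the remainders
    s = min(_lcs(ref_protein[p:], alt[p:]), L - p, len(alt) - p)
    ref_int = ref_protein[p : L - s]
    alt_int = alt[p : len(alt) - s]

    if not stopped or (not ref_int and not alt_int):
        # frame nominally preserved but no clean in-frame description
        return protein_consequence(ref_protein, alt_cds, frame_shifted=True)

    if not alt_int:  # in-frame deletion
        start, end = p + 1, L - s
        if start == end:
            hgvs = f"p.{ref_protein[start - 1]}{start}del"
        else:
            hgvs = f"p.{ref_protein[start - 1]}{start}_{ref_protein[end - 1]}{end}del"
        cons = ProteinConsequence(kind="inframe_deletion", start_res=start, end_res=end, hgvs_p=hgvs)
        return _with_fraction(cons, L)

    if not ref_int:  # in-frame insertion between residues p and p+1
        left, right = p, p + 1
        left_aa = ref_protein[left - 1] if left >= 1 else "?"
        right_aa = ref_protein[right - 1] if right <= L else "*"
        hgvs = f"p.{left_aa}{left}_{right_aa}{right}ins{alt_int}"
        cons = ProteinConsequence(
            kind="inframe_insertion", start_res=left, end_res=right, inserted=alt_int, hgvs_p=hgvs
        )
        return _with_fraction(cons, L)

    start, end = p + 1, L - s
    if start == end:
        hgvs = f"p.{ref_protein[start - 1]}{start}delins{alt_int}"
    else:
        hgvs = f"p.{ref_protein[start - 1]}{start}_{ref_protein[end - 1]}{end}delins{alt_int}"
    cons = ProteinConsequence(
        kind="inframe_delins", start_res=start, end_res=end, inserted=alt_int, hgvs_p=hgvs
    )
    return _with_fraction(cons, L)


def disrupted_fraction(c: ProteinConsequence, protein_length: int) -> tuple[int, float]:
    """Disrupted residue count and fraction for a consequence on a protein.

    Counting conventions are documented in the module docstring.
    """
    L = protein_length
    if c.kind == "none":
        return 0, 0.0
    if c.kind in ("inframe_deletion", "inframe_delins"):
        if not 1 <= c.start_res <= c.end_res <= L:
            raise ValueError(f"residue range {c.start_res}-{c.end_res} outside protein of length {L}")
        n = c.end_res - c.start_res + 1
    elif c.kind == "inframe_insertion":
        n = len(c.inserted)
    elif c.kind in ("frameshift", "stop_gain"):
        first = c.fs_first_res
        if first is None or not 1 <= first <= L:
            raise ValueError(f"first altered residue {first} outside protein of length {L}")
        n = L - first
    else:
        raise ValueError(f"unknown consequence kind {c.kind!r}")
    return n, n / L


def _with_fraction(c: ProteinConsequence, protein_length: int) -> ProteinConsequence:
    c.disrupted_count, c.disrupted_fraction = disrupted_fraction(c, protein_length)
    return c


def pvs1_call(c: ProteinConsequence, protein_length: int | None = None, threshold: float = 0.10) -> Pvs1Call:
    """PVS1 strength: Strong iff a LoF-type change disrupts >10% of the protein.

    The inequality is strict; in-frame changes never qualify regardless of
    extent.
    """
    if c.kind not in ("frameshift", "stop_gain"):
        return Pvs1Call("not_met", f"{c.kind or 'no'} change is not a LoF-type consequence")
    frac = c.disrupted_fraction
    if protein_length is not None:
        _, frac = disrupted_fraction(c, protein_length)
    if frac > threshold:
        return Pvs1Call("PVS1_Strong", f"LoF-type change disrupts {frac:.2%} (> {threshold:.0%}) of the protein")
    return Pvs1Call("not_met", f"LoF-type change disrupts only {frac:.2%} (≤ {threshold:.0%}) of the protein")


def ncsv_classify(region: str, events: SpliceEvent | list[SpliceEvent]) -> list[NcsvClass]:
    """Six-class taxonomy: variant region × splicing outcome.

    ``region`` is 'exonic' or 'intronic' (the variant's location); compound
    events yield one class per distinct outcome.
    """
    if region not in ("exonic", "intronic"):
        raise ValueError(f"region must be exonic or intronic, got {region!r}")
    if isinstance(events, SpliceEvent):
        events = [events]
    out = []
    seen = set()
    for e in events:
        key = (region, e.event_type)
        if key in seen:
            continue
        seen.add(key)
        out.append(NcsvClass(region=region, outcome=e.event_type, label=NcsvClass.LABELS[key]))
    return out


# ---------------------------------------------------------------------- #
# HGVS p. parsing (round-trip support)

_P_DEL = re.compile(r"^p\.([A-Z])(\d+)(?:_([A-Z])(\d+))?del$")
_P_DELINS = re.compile(r"^p\.([A-Z])(\d+)(?:_([A-Z])(\d+))?delins([A-Z]+)$")
_P_INS = re.compile(r"^p\.([A-Z?])(\d+)_([A-Z*])(\d+)ins([A-Z]+)$")
_P_FS = re.compile(r"^p\.([A-Z*])(\d+)([A-Z?])fs\*(\d+|\?)$")
_P_STOP = re.compile(r"^p\.([A-Z])(\d+)\*$")


def parse_hgvs_p(text: str) -> ProteinConsequence:
    """Reconstruct kind/positions from an HGVS p. string emitted by this module."""
    text = text.strip().replace("‐", "-")
    if text in ("p.(=)", "p.="):
        return ProteinConsequence(kind="none")
    m = _P_DELINS.match(text)
    if m:
        a1, p1, a2, p2, ins = m.groups()
        start, end = int(p1), int(p2) if p2 else int(p1)
        return ProteinConsequence(kind="inframe_delins", start_res=start, end_res=end, inserted=ins, hgvs_p=text)
    m = _P_DEL.match(text)
    if m:
        a1, p1, a2, p2 = m.groups()
        start, end = int(p1), int(p2) if p2 else int(p1)
        return ProteinConsequence(kind="inframe_deletion", start_res=start, end_res=end, hgvs_p=text)
    m = _P_INS.match(text)
    if m:
        a1, p1, a2, p2, ins = m.groups()
        return ProteinConsequence(
            kind="inframe_insertion", start_res=int(p1), end_res=int(p2), inserted=ins, hgvs_p=text
        )
    m = _P_FS.match(text)
    if m:
        ref_aa, pos, new_aa, n = m.groups()
        return ProteinConsequence(
            kind="frameshift",
            fs_first_res=int(pos),
            fs_ref_aa=ref_aa,
            fs_new_aa=new_aa,
            fs_stop_offset=None if n == "?" else int(n),
            no_stop_found=n == "?",
            hgvs_p=text,
        )
    m = _P_STOP.match(text)
    if m:
        aa, pos = m.groups()
        first = int(pos)
        return ProteinConsequence(
            kind="stop_gain", start_res=first, end_res=first, fs_first_res=first, fs_ref_aa=aa, hgvs_p=text
        )
    raise ValueError(f"cannot parse HGVS p. string {text!r}")
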