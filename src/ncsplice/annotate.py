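"""Variant consequence classification, junction context and splicing prioritization.

The prioritization rule is a union of two arms: a variant is flagged as a
potential splicing variant when nine or more integrated prediction methods
call it splice-altering (SPCards count ≥ 9) or when its SpliceAI delta score
is ≥ 0.5. Canonical splice-dinucleotide variants (intron offsets ±1/±2) are
treated as an established loss-of-function class and excluded from the
non-canonical candidate set, together with stop-gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .reference import (
    CdnaPosition,
    OutOfTranscriptError,
    TranscriptModel,
    map_g_to_c,
    parse_hgvs_c,
    reverse_complement,
)

CONSEQUENCE_CLASSES = (
    "frameshift",
    "intronic",
    "nonframeshift",
    "missense",
    "canonical_splicing",
    "start_loss",
    "stop_gain",
    "stop_loss",
    "synonymous",
    "utr",
)

#: splicing consensus windows (signed distances, inclusive)
DONOR_WINDOW = (-3, 8)
ACCEPTOR_WINDOW = (-12, 2)

PREDICTOR_TOOLS = ("SIFT", "PolyPhen2", "MutationTaster")
#: predictor letters counted as a damaging call
DAMAGING_CALLS = {"SIFT": {"D"}, "PolyPhen2": {"D", "P"}, "MutationTaster": {"D"}}


@dataclass
class AnnotatedVariant:
    """One genomic variant with the annotations the pipeline consumes.

    ``spliceai`` in [0, 1] and ``spcards_count`` in [0, 18] may be missing
    (None); allele frequencies and missense predictor calls likewise.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript_id: str = ""
    hgvs_c: str = ""
    consequence_class: str | None = None
    spliceai: float | None = None
    spcards_count: int | None = None
    af: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, object] = field(default_factory=dict)
    cadd: float | None = None
    zygosity: str | None = None
    prior_validation: str = "none"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.contig}:{self.pos}")
        if self.spliceai is not None and not 0.0 <= self.spliceai <= 1.0:
            raise ValueError(f"SpliceAI score {self.spliceai} outside [0, 1]")
        if self.spcards_count is not None and not 0 <= self.spcards_count <= 18:
            raise ValueError(f"SPCards count {self.spcards_count} outside [0, 18]")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class JunctionContext:
    """Signed distance of a variant to its nearest exon/intron junction.

    Sign convention (matching the distance-to-junction column style of
    curated splicing tables): along transcript direction relative to the
    junction — intronic past a donor is positive, intronic ahead of an
    acceptor negative, the exonic base immediately 5' of a donor is −1, and
    the exonic base k past an acceptor is +k.
    """

    junction_side: str  # donor | acceptor
    signed_distance: int
    region: str  # exonic | intronic
    in_consensus: bool

    @staticmethod
    def consensus(junction_side: str, signed_distance: int) -> bool:
        lo, hi = DONOR_WINDOW if junction_side == "donor" else ACCEPTOR_WINDOW
        return lo <= signed_distance <= hi


@dataclass(frozen=True)
class PrioritizationDecision:
    prioritized: bool
    arms: frozenset[str]
    excluded_reason: str = "none"


def classify_variant(v: AnnotatedVariant, t: TranscriptModel) -> str:
    """Assign a single consequence class to ``v`` on transcript ``t``.

    Canonical splicing iff the position is intronic at offset |k| ≤ 2.
    Exonic SNVs are classified by re-translating the mutated codon; exonic
    indels by length difference mod 3.
    """
    cpos = map_g_to_c(t, v.pos)  # raises OutOfTranscriptError outside the span
    if cpos.intron_offset != 0:
        return "canonical_splicing" if abs(cpos.intron_offset) <= 2 else "intronic"
    if cpos.utr is not None:
        return "utr"
    if not v.is_snv:
        return "frameshift" if abs(len(v.ref) - len(v.alt)) % 3 else "nonframeshift"

    # exonic SNV inside the CDS span: re-translate the affected codon
    alt_base = v.alt if t.strand == "+" else reverse_complement(v.alt)
    ref_base = v.ref if t.strand == "+" else reverse_complement(v.ref)
    idx = cpos.base - 1  # 0-based within CDS
    if t.cds[idx] != ref_base:
        raise ValueError(
            f"ref allele mismatch at {v.contig}:{v.pos}: genome has {t.cds[idx]}, variant says {ref_base}"
        )
    codon_i = idx // 3
    codon = t.cds[codon_i * 3 : codon_i * 3 + 3]
    within = idx % 3
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    is_stop_codon_pos = codon_i == len(t.cds) // 3 - 1
    if old_aa == new_aa:
        return "synonymous"
    if codon_i == 0 and old_aa == "M":
        return "start_loss"
    if is_stop_codon_pos and old_aa == "*":
        return "stop_loss" if new_aa != "*" else "synonymous"
    if new_aa == "*":
        return "stop_gain"
    return "missense"


def junction_context(v: AnnotatedVariant, t: TranscriptModel) -> JunctionContext | None:
    """Distance of ``v`` to the nearest splice junction of ``t``.

    Returns None for single-exon transcripts (no junctions). Equidistant
    ties break toward the junction implied by the variant's HGVS c. anchor
    when one is present, otherwise toward the donor.
    """
    if t.n_exons < 2:
        return None
    cpos = map_g_to_c(t, v.pos)

    if cpos.intron_offset != 0:
        side = "donor" if cpos.intron_offset > 0 else "acceptor"
        d = cpos.intron_offset
        return JunctionContext(side, d, "intronic", JunctionContext.consensus(side, d))

    # exonic: locate the exon, measure to both of its junctions
    toff = t.g_to_t(v.pos)
    lengths = t.exon_lengths()
    off = 0
    for i, ln in enumerate(lengths):
        if toff < off + ln:
            within = toff - off  # 0-based within exon
            candidates: list[tuple[int, int, str]] = []
            if i > 0:  # exon has an upstream acceptor
                d_acc = within + 1
                candidates.append((abs(d_acc), d_acc, "acceptor"))
            if i < t.n_exons - 1:  # exon has a downstream donor
                d_don = -(ln - within)
                candidates.append((abs(d_don), d_don, "donor"))
            if not candidates:
                return None
            best = min(c[0] for c in candidates)
            tied = [c for c in candidates if c[0] == best]
            if len(tied) == 2:
                anchor = _anchor_side(v.hgvs_c)
                pick = next((c for c in tied if c[2] == anchor), None)
                chosen = pick or next(c for c in tied if c[2] == "donor")
            else:
                chosen = tied[0]
            _, d, side = chosen
            return JunctionContext(side, d, "exonic", JunctionContext.consensus(side, d))
        off += ln
    raise OutOfTranscriptError(f"position {v.pos} not exonic on {t.transcript_id}")


def _anchor_side(hgvs_c: str) -> str | None:
    if not hgvs_c:
        return None
    try:
        cpos = parse_hgvs_c(hgvs_c)
    except ValueError:
        return None
    if cpos.intron_offset > 0:
        return "donor"
    if cpos.intron_offset < 0:
        return "acceptor"
    return None


def prioritize(
    v: AnnotatedVariant, spcards_min: int = 9, spliceai_min: float = 0.5
) -> PrioritizationDecision:
    """Dual-threshold splicing prioritization (union of the two arms).

    A missing score on one arm never blocks the other; with both scores
    missing the variant is simply not prioritized.
    """
    arms = set()
    if v.spcards_count is not None and v.spcards_count >= spcards_min:
        arms.add("spcards")
    if v.spliceai is not None and v.spliceai >= spliceai_min:
        arms.add("spliceai")
    return PrioritizationDecision(prioritized=bool(arms), arms=frozenset(arms))


def select_for_validation(
    catalog: list[AnnotatedVariant], requeue: set[str] | None = None
) -> list[AnnotatedVariant]:
    """Pick prioritized non-LoF candidates for splicing validation.

    Canonical splicing and stop-gain variants are established LoF classes and
    are dropped; previously validated variants are dropped unless explicitly
    re-queued by key. What remains are the intronic/missense/synonymous (and
    other non-LoF) potential NCSVs.
    """
    requeue = requeue or set()
    out = []
    for v in catalog:
        if v.consequence_class in ("canonical_splicing", "stop_gain"):
            continue
        if v.prior_validation == "validated" and v.key not in requeue:
            continue
        out.append(v)
    return out


def missense_deleterious(v: AnnotatedVariant, cadd_min: float = 20.0) -> tuple[bool, str]:
    """Deleteriousness call for a missense variant from four predictors.

    Deleterious iff at least 3 of {SIFT, PolyPhen-2, MutationTaster, CADD}
    call damaging (CADD damaging ⇔ score > ``cadd_min``). When all four are
    missing the variant is retained as deleterious-unknown rather than
    silently dropped.
    """
    calls = 0
    available = 0
    for tool in PREDICTOR_TOOLS:
        val = v.predictor_calls.get(tool)
        if val not in (None, "", "NA"):
            available += 1
            if val in DAMAGING_CALLS[tool]:
                calls += 1
    if v.cadd is not None:
        available += 1
        if v.cadd > cadd_min:
            calls += 1
    if available == 0:
        return True, "all predictors missing; retained as deleterious-unknown"
    if calls >= 3:
        return True, f"{calls}/4 predictors damaging"
    return False, f"{calls}/4 predictors damaging"
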