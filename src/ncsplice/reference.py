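"""Toy-scale transcript models and genomic ↔ cDNA (HGVS c.) coordinate mapping.

A :class:`TranscriptModel` carries the exon/intron architecture of a single
protein-coding transcript on a :class:`GenomeRef`. Once built against a genome
it exposes the spliced mRNA, the CDS (stop codon included) and the translated
protein, plus bidirectional mapping between genomic positions and
CDS-anchored HGVS-style coordinates (``c.N``, ``c.N+k``, ``c.N-k``).

Conventions
-----------
* Genomic coordinates are 1-based, inclusive (VCF/GTF style).
* Exons are listed 5'→3' in *transcript* orientation; on the minus strand the
  first exon therefore has the largest genomic coordinates.
* ``cds_start`` is the genomic position of the first base of the start codon,
  ``cds_end`` the genomic position of the last base of the stop codon; the
  stop codon is part of the CDS span but not of the protein.
* Intronic positions anchor to the nearer exon per HGVS: the first half of an
  intron is ``c.N+k`` off the upstream exon, the second half ``c.N-k`` off the
  downstream exon (midpoint of an odd-length intron anchors upstream).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

DNA_RE = re.compile(r"^[ACGTNacgtn]+$")
STRICT_DNA_RE = re.compile(r"^[ACGTacgt]+$")

STOP_CODONS = {"TAA", "TAG", "TGA"}


class TranscriptValidationError(ValueError):
    """A transcript model violates a structural invariant.

    ``invariant`` names the failed check so callers can branch on it.
    """

    def __init__(self, invariant: str, message: str):
        self.invariant = invariant
        super().__init__(f"{invariant}: {message}")


class OutOfTranscriptError(ValueError):
    """A genomic position falls outside the transcript span (exons + introns)."""


@dataclass
class GenomeRef:
    """A reference genome as a mapping of contig name → DNA sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            if not DNA_RE.match(seq):
                raise ValueError(f"contig {name!r} contains non-IUPAC-DNA characters")
            self.contigs[name] = seq.upper()

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the 1-based inclusive slice ``[start, end]`` of ``contig``."""
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"{contig}:{start}-{end} outside contig bounds (len {len(seq)})")
        return seq[start - 1 : end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass(frozen=True)
class CdnaPosition:
    """A CDS-anchored coordinate: ``c.{base}`` with an optional intron offset.

    ``intron_offset`` is 0 for exonic positions, positive for positions past a
    donor (``c.base+k``) and negative for positions ahead of an acceptor
    (``c.base-k``). ``utr`` flags positions outside the CDS on the mRNA
    ('5' or '3'); fine-grained UTR numbering is not modelled.
    """

    base: int
    intron_offset: int = 0
    utr: str | None = None

    def __str__(self) -> str:
        if self.utr == "5":
            core = f"c.-{self.base}"
        elif self.utr == "3":
            core = f"c.*{self.base}"
        else:
            core = f"c.{self.base}"
        if self.intron_offset > 0:
            return f"{core}+{self.intron_offset}"
        if self.intron_offset < 0:
            return f"{core}{self.intron_offset}"
        return core


@dataclass
class TranscriptModel:
    """A protein-coding transcript: ordered exons plus a CDS span.

    Derived sequence fields (``mrna``, ``cds``, ``protein``) are populated by
    :func:`build_transcript`.
    """

    transcript_id: str
    gene: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    mrna: str | None = None
    cds: str | None = None
    protein: str | None = None
    intron_seqs: list[str] | None = None
    # transcript-space offsets (0-based) of the CDS within the mRNA
    _cds_offset: int | None = field(default=None, repr=False)

    # ------------------------------------------------------------------ #
    # structure helpers (valid before sequence derivation)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def protein_length(self) -> int:
        if self.protein is None:
            raise ValueError("transcript not built; call build_transcript first")
        return len(self.protein)

    def exon_lengths(self) -> list[int]:
        return [end - start + 1 for start, end in self.exons]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals of introns, ordered 5'→3' in transcript orientation."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out

    def span(self) -> tuple[int, int]:
        """Genomic (min, max) over all exons."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    # ------------------------------------------------------------------ #
    # transcript-space walking

    def g_to_t(self, gpos: int) -> int | None:
        """0-based offset of a genomic position within the spliced mRNA, or None."""
        off = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                if self.strand == "+":
                    return off + (gpos - s)
                return off + (e - gpos)
            off += e - s + 1
        return None

    def t_to_g(self, t: int) -> int:
        """Genomic position of a 0-based mRNA offset."""
        if t < 0:
            raise OutOfTranscriptError(f"negative mRNA offset {t}")
        off = 0
        for s, e in self.exons:
            length = e - s + 1
            if t < off + length:
                if self.strand == "+":
                    return s + (t - off)
                return e - (t - off)
            off += length
        raise OutOfTranscriptError(f"mRNA offset {t} beyond transcript length {off}")


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate a coding sequence with the standard genetic code.

    Stops at the first stop codon; returns ``(residues, stop_reached)``.
    Trailing bases short of a full codon are ignored.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon ({len(cds)} nt)")
    if not STRICT_DNA_RE.match(cds):
        raise ValueError("CDS contains non-ACGT characters")
    cds = cds.upper()
    usable = len(cds) - len(cds) % 3
    prot = str(Seq(cds[:usable]).translate())
    stop_idx = prot.find("*")
    if stop_idx >= 0:
        return prot[:stop_idx], True
    return prot, False


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_transcript(genome: GenomeRef, model: TranscriptModel) -> TranscriptModel:
    """Derive and validate mRNA/CDS/protein for ``model`` against ``genome``.

    Raises :class:`TranscriptValidationError` naming the violated invariant:
    exon ordering/overlap, CDS placement, CDS length divisible by 3, start
    codon ATG, internal stop codons, or N bases inside the CDS.
    """
    if model.contig not in genome:
        raise TranscriptValidationError("contig", f"{model.contig!r} not in genome")
    if model.strand not in "+-":
        raise TranscriptValidationError("strand", f"invalid strand {model.strand!r}")
    if not model.exons:
        raise TranscriptValidationError("exons", "transcript has no exons")

    # exon sanity: non-overlapping, sorted 5'→3' in transcript orientation
    for s, e in model.exons:
        if s > e:
            raise TranscriptValidationError("exons", f"exon interval {s}-{e} reversed")
    keys = [s for s, _ in model.exons]
    ordered = keys == sorted(keys) if model.strand == "+" else keys == sorted(keys, reverse=True)
    if not ordered:
        raise TranscriptValidationError("exons", "exons not sorted 5'→3' in transcript orientation")
    genomic_sorted = sorted(model.exons)
    for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
        if s2 <= e1:
            raise TranscriptValidationError("exons", f"exons {s1}-{e1} and {s2}-{e2} overlap")

    mrna = "".join(genome.fetch(model.contig, s, e) for s, e in sorted(model.exons))
    if model.strand == "-":
        mrna = reverse_complement(mrna)

    t_start = model.g_to_t(model.cds_start)
    t_end = model.g_to_t(model.cds_end)
    if t_start is None or t_end is None:
        raise TranscriptValidationError("cds", "CDS boundary not inside the exon union")
    if t_start > t_end:
        raise TranscriptValidationError("cds", "CDS start downstream of CDS end in transcript space")

    cds = mrna[t_start : t_end + 1]
    if "N" in cds:
        raise TranscriptValidationError("cds_alphabet", "N bases inside the CDS")
    if len(cds) % 3 != 0:
        raise TranscriptValidationError("cds_frame", f"CDS length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        raise TranscriptValidationError("start_codon", f"CDS does not begin with ATG ({cds[:3]})")
    if cds[-3:] not in STOP_CODONS:
        raise TranscriptValidationError("stop_codon", f"CDS does not end in a stop codon ({cds[-3:]})")
    protein, stopped = translate_cds(cds)
    if len(protein) != len(cds) // 3 - 1:
        raise TranscriptValidationError(
            "internal_stop", "CDS contains an internal stop codon"
        )

    intron_seqs = []
    for istart, iend in model.introns():
        seq = genome.fetch(model.contig, istart, iend)
        intron_seqs.append(seq if model.strand == "+" else reverse_complement(seq))

    built = replace(model, mrna=mrna, cds=cds, protein=protein, intron_seqs=intron_seqs)
    built._cds_offset = t_start
    return built


# ---------------------------------------------------------------------- #
# coordinate mapping


def _require_built(t: TranscriptModel) -> None:
    if t.mrna is None or t._cds_offset is None:
        raise ValueError("transcript not built; call build_transcript first")


def _cdna_of_t(t: TranscriptModel, toff: int) -> CdnaPosition:
    """CdnaPosition for a 0-based mRNA offset."""
    rel = toff - t._cds_offset
    cds_len = len(t.cds)
    if rel < 0:
        return CdnaPosition(base=-rel, utr="5")
    if rel >= cds_len:
        return CdnaPosition(base=rel - cds_len + 1, utr="3")
    return CdnaPosition(base=rel + 1)


def map_g_to_c(t: TranscriptModel, gpos: int) -> CdnaPosition:
    """Map a genomic position to a CDS-anchored HGVS-style coordinate.

    Exonic positions yield ``intron_offset == 0``; intronic positions anchor
    to the nearer junction (upstream exon for the first half of the intron,
    downstream exon for the second half).
    """
    _require_built(t)
    toff = t.g_to_t(gpos)
    if toff is not None:
        return _cdna_of_t(t, toff)

    # intronic: find the intron containing gpos
    off = 0
    lengths = t.exon_lengths()
    for i, (istart, iend) in enumerate(t.introns()):
        lo, hi = min(istart, iend), max(istart, iend)
        ilen = hi - lo + 1
        if lo <= gpos <= hi:
            # distance into the intron measured in transcript orientation
            if t.strand == "+":
                d_from_donor = gpos - lo + 1
            else:
                d_from_donor = hi - gpos + 1
            upstream_last_t = sum(lengths[: i + 1]) - 1
            if d_from_donor <= (ilen + 1) // 2:
                anchor = _cdna_of_t(t, upstream_last_t)
                return replace(anchor, intron_offset=d_from_donor)
            anchor = _cdna_of_t(t, upstream_last_t + 1)
            return replace(anchor, intron_offset=-(ilen - d_from_donor + 1))
        off += 1
    lo, hi = t.span()
    raise OutOfTranscriptError(f"{t.contig}:{gpos} outside transcript span {lo}-{hi}")


def map_c_to_g(t: TranscriptModel, cpos: CdnaPosition) -> int:
    """Inverse of :func:`map_g_to_c` on the same domain."""
    _require_built(t)
    if cpos.utr == "5":
        toff = t._cds_offset - cpos.base
    elif cpos.utr == "3":
        toff = t._cds_offset + len(t.cds) - 1 + cpos.base
    else:
        if cpos.base < 1:
            raise OutOfTranscriptError(f"invalid c. base {cpos.base}")
        toff = t._cds_offset + cpos.base - 1
    if toff < 0 or toff >= len(t.mrna):
        raise OutOfTranscriptError(f"{cpos} outside the mRNA")
    anchor_g = t.t_to_g(toff)
    if cpos.intron_offset == 0:
        return anchor_g
    step = 1 if t.strand == "+" else -1
    return anchor_g + step * cpos.intron_offset


def parse_hgvs_c(text: str) -> CdnaPosition:
    """Parse a position-only HGVS c. expression such as ``c.2859+4`` or ``c.634-8``.

    Allele changes after the position (``A>G`` etc.) are ignored; only the
    coordinate is extracted.
    """
    m = re.match(r"c\.\s*(\*|-)?(\d+)\s*(?:([+-])\s*(\d+))?", text.replace("‐", "-").replace("−", "-"))
    if not m:
        raise ValueError(f"cannot parse HGVS c. position from {text!r}")
    utr_mark, base, sign, off = m.groups()
    utr = {"*": "3", "-": "5", None: None}[utr_mark]
    intron_offset = 0
    if sign:
        intron_offset = int(off) if sign == "+" else -int(off)
    return CdnaPosition(base=int(base), intron_offset=intron_offset, utr=utr)
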