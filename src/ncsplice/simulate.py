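"""Synthetic genomes, transcripts, variant catalogs and cohorts with truth labels.

Everything the pipeline consumes can be generated here at toy scale with a
recorded seed: multi-exon coding transcripts on random contigs (one X contig
for hemizygous screening), spiked splice-altering variants whose protein
consequence is computed by an independent string-surgery oracle, correlated
SpliceAI/SPCards-like scores from a Gaussian copula, and patient genotype
tables with planted homozygous / compound-heterozygous / hemizygous
configurations plus decoys.

The module also contains :func:`reconstruct_printed_event`, which engineers
a toy transcript and splice event whose true protein consequence reproduces
a given printed HGVS p. alteration at a given protein length — the basis of
the curated-table golden tests.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import norm

from .annotate import AnnotatedVariant, classify_variant
from .cohort import PatientGenotypes
from .consequence import SpliceEvent
from .reference import GenomeRef, TranscriptModel, build_transcript

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = tuple(standard_dna_table.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in AA_TO_CODONS:
    AA_TO_CODONS[_aa].sort()
AMINO_ACIDS = sorted(AA_TO_CODONS)
_NONSTOP_CODONS = sorted(standard_dna_table.forward_table)

_BASES = "ACGT"


# ---------------------------------------------------------------------- #
# small sequence helpers


def _rand_dna(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _rand_protein(rng, n: int) -> str:
    body = "".join(rng.choice(AMINO_ACIDS, size=n - 1))
    return "M" + body


def _back_translate(rng, protein: str) -> str:
    return "".join(rng.choice(AA_TO_CODONS[aa]) for aa in protein)


def _rand_stop(rng) -> str:
    return str(rng.choice(list(STOP_CODONS)))


def _rand_nonstop_codon(rng) -> str:
    return str(rng.choice(_NONSTOP_CODONS))


def oracle_translate(cds: str) -> tuple[str, bool]:
    """Plain codon-table loop translation (independent of the engine path)."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TO_AA[cds[i : i + 3]]
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


# ---------------------------------------------------------------------- #
# configuration


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study conditions emulated.

    ``score_correlation`` is the target product-moment correlation of the
    emitted (SPCards count, SpliceAI) pairs; ``planted_*`` is the pattern mix
    planted into the cohort (remaining patients receive decoy
    configurations).
    """

    seed: int = 0
    n_transcripts: int = 20
    exon_count_range: tuple[int, int] = (3, 7)
    exon_length_range: tuple[int, int] = (60, 240)
    intron_length_range: tuple[int, int] = (80, 300)
    minus_strand_fraction: float = 0.25
    n_variants: int = 2000
    spike_fraction: float = 0.10
    score_correlation: float = 0.83
    spiked_score_shift: float = 1.2
    consensus_spike_share: float = 0.7
    separated_scores: bool = False
    common_af_fraction: float = 0.08
    common_af_value: float = 0.05
    cohort_size: int = 34
    planted_hom: int = 7
    planted_comp_het: int = 9
    planted_hemi: int = 1

    def validate(self) -> None:
        for name in ("exon_count_range", "exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"infeasible {name}: {(lo, hi)}")
        if not -1.0 <= self.score_correlation <= 1.0:
            raise ValueError("score_correlation outside [-1, 1]")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction outside [0, 1]")
        planted = self.planted_hom + self.planted_comp_het + self.planted_hemi
        if planted > self.cohort_size:
            raise ValueError("planted patterns exceed cohort size")
        if self.exon_count_range[0] < 3:
            raise ValueError("need at least 3 exons per transcript for internal events")


@dataclass
class TruthRecord:
    """Ground truth for one generated variant."""

    variant_key: str
    transcript_id: str
    is_splice_altering: bool
    events: list[SpliceEvent] = field(default_factory=list)
    region: str | None = None
    expected_kind: str | None = None
    expected_hgvs_p: str | None = None
    expected_count: int | None = None
    expected_fraction: float | None = None
    planted_pattern: str | None = None


# ---------------------------------------------------------------------- #
# transcriptome generation


def gen_transcriptome(cfg: SimulationConfig) -> tuple[GenomeRef, list[TranscriptModel]]:
    """Random multi-exon coding transcripts, one per contig, deterministic per seed.

    Every transcript has a valid ORF (ATG start, single terminal stop), the
    CDS spanning the whole mRNA, GT..AG intron ends, and the last transcript
    sits on an X contig so hemizygous genotypes can be exercised.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    contig_seqs: dict[str, str] = {}
    raw_models: list[TranscriptModel] = []

    for i in range(cfg.n_transcripts):
        contig = "chrX" if i == cfg.n_transcripts - 1 else f"chr{i + 1}"
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        ex_lens = [int(rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1)) for _ in range(n_ex)]
        total = sum(ex_lens)
        ex_lens[-1] += (3 - total % 3) % 3
        total = sum(ex_lens)
        protein = _rand_protein(rng, total // 3 - 1)
        cds = _back_translate(rng, protein) + _rand_stop(rng)

        intron_lens = [int(rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1)) for _ in range(n_ex - 1)]
        introns = ["GT" + _rand_dna(rng, ln - 4) + "AG" for ln in intron_lens]

        pad5, pad3 = _rand_dna(rng, 50), _rand_dna(rng, 50)
        seq = pad5
        coords = []
        off = 0
        for j, ln in enumerate(ex_lens):
            start = len(seq) + 1
            seq += cds[off : off + ln]
            coords.append((start, len(seq)))
            off += ln
            if j < n_ex - 1:
                seq += introns[j]
        seq += pad3

        strand = "-" if (contig != "chrX" and rng.random() < cfg.minus_strand_fraction) else "+"
        if strand == "-":
            L = len(seq)
            seq = str(_revcomp(seq))
            coords = [(L - e + 1, L - s + 1) for s, e in coords]
            cds_start = coords[0][1]
            cds_end = coords[-1][0]
        else:
            cds_start = coords[0][0]
            cds_end = coords[-1][1]

        contig_seqs[contig] = seq
        raw_models.append(
            TranscriptModel(
                transcript_id=f"TX{i + 1:03d}",
                gene=f"GENE{i + 1:03d}",
                contig=contig,
                strand=strand,
                exons=coords,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )

    genome = GenomeRef(contig_seqs)
    return genome, [build_transcript(genome, m) for m in raw_models]


def _revcomp(seq: str) -> str:
    from .reference import reverse_complement

    return reverse_complement(seq)


# ---------------------------------------------------------------------- #
# independent splicing oracle (string surgery on the exon list)


def oracle_apply(t: TranscriptModel, events: list[SpliceEvent]) -> tuple[str, int]:
    """Alternate CDS by direct list surgery on exon/intron sequences.

    Returns (alt_cds from the original start codon to the mRNA 3' end,
    net inserted − deleted nucleotides). Independent of the engine's
    edit-tracking implementation; assumes events do not touch the first exon
    (the generator guarantees this).
    """
    lengths = t.exon_lengths()
    pieces: list[str] = []
    off = 0
    for ln in lengths:
        pieces.append(t.mrna[off : off + ln])
        off += ln
    inserts: dict[int, str] = {}  # after exon index (0-based) -> retained seq
    net = 0
    for e in events:
        if e.event_type == "exon_skipping":
            net -= len(pieces[e.element_index - 1])
            pieces[e.element_index - 1] = ""
        elif e.event_type == "partial_exon_deletion":
            s, se = e.sub_interval
            exon = pieces[e.element_index - 1]
            pieces[e.element_index - 1] = exon[: s - 1] + exon[se:]
            net -= se - s + 1
        else:
            intron = t.intron_seqs[e.element_index - 1]
            if e.sub_interval is None:
                seg = intron
            else:
                s, se = e.sub_interval
                seg = intron[s - 1 : se]
            inserts[e.element_index - 1] = inserts.get(e.element_index - 1, "") + seg
            net += len(seg)
    out = []
    for i, piece in enumerate(pieces):
        out.append(piece)
        if i in inserts:
            out.append(inserts[i])
    alt_mrna = "".join(out)
    return alt_mrna[t._cds_offset :], net


def oracle_consequence(ref_protein: str, alt_cds: str, net: int) -> dict:
    """Expected consequence by brute-force prefix/suffix scanning.

    Implements the same naming and counting conventions as the engine but by
    a separate, deliberately plain code path (index loops over the two
    proteins), so agreement between the two is informative.
    """
    L = len(ref_protein)
    alt, stopped = oracle_translate(alt_cds)
    if alt == ref_protein and stopped:
        return {"kind": "none", "hgvs_p": "p.(=)", "count": 0, "fraction": 0.0}

    p = 0
    while p < len(ref_protein) and p < len(alt) and ref_protein[p] == alt[p]:
        p += 1
    if p >= L:
        return {"kind": "none", "hgvs_p": "p.(=)", "count": 0, "fraction": 0.0}

    if stopped and len(alt) == p and p < L:
        first = p + 1
        return {
            "kind": "stop_gain",
            "hgvs_p": f"p.{ref_protein[p]}{first}*",
            "count": L - first,
            "fraction": (L - first) / L,
        }

    if net % 3 != 0 or not stopped:
        first = p + 1
        new = alt[p] if p < len(alt) else "?"
        n = len(alt) - p + 1 if stopped else None
        hgvs = f"p.{ref_protein[p]}{first}{new}fs*{n if n is not None else '?'}"
        return {"kind": "frameshift", "hgvs_p": hgvs, "count": L - first, "fraction": (L - first) / L}

    s = 0
    while (
        s < len(ref_protein) - p
        and s < len(alt) - p
        and ref_protein[len(ref_protein) - 1 - s] == alt[len(alt) - 1 - s]
    ):
        s += 1
    ref_int = ref_protein[p : L - s]
    alt_int = alt[p : len(alt) - s]
    if not ref_int and not alt_int:
        first = p + 1
        hgvs = f"p.{ref_protein[p]}{first}{alt[p]}fs*{len(alt) - p + 1}"
        return {"kind": "frameshift", "hgvs_p": hgvs, "count": L - first, "fraction": (L - first) / L}
    if not alt_int:
        start, end = p + 1, L - s
        if start == end:
            hgvs = f"p.{ref_protein[start - 1]}{start}del"
        else:
            hgvs = f"p.{ref_protein[start - 1]}{start}_{ref_protein[end - 1]}{end}del"
        n = end - start + 1
        return {"kind": "inframe_deletion", "hgvs_p": hgvs, "count": n, "fraction": n / L}
    if not ref_int:
        left, right = p, p + 1
        hgvs = f"p.{ref_protein[left - 1]}{left}_{ref_protein[right - 1] if right <= L else '*'}{right}ins{alt_int}"
        return {"kind": "inframe_insertion", "hgvs_p": hgvs, "count": len(alt_int), "fraction": len(alt_int) / L}
    start, end = p + 1, L - s
    if start == end:
        hgvs = f"p.{ref_protein[start - 1]}{start}delins{alt_int}"
    else:
        hgvs = f"p.{ref_protein[start - 1]}{start}_{ref_protein[end - 1]}{end}delins{alt_int}"
    n = end - start + 1
    return {"kind": "inframe_delins", "hgvs_p": hgvs, "count": n, "fraction": n / L}


# ---------------------------------------------------------------------- #
# spiked variants


_EVENT_CLASSES = [
    ("exonic", "exon_skipping"),
    ("intronic", "exon_skipping"),
    ("exonic", "partial_exon_deletion"),
    ("intronic", "partial_exon_deletion"),
    ("exonic", "intron_retention"),
    ("intronic", "intron_retention"),
]


def spike_events(
    genome: GenomeRef, transcripts: list[TranscriptModel], cfg: SimulationConfig
) -> tuple[list[AnnotatedVariant], list[TruthRecord]]:
    """Generate the variant catalog: spiked splice-altering variants + decoys.

    Each spike gets a junction-proximal variant consistent with its event
    (within the consensus window for ``consensus_spike_share`` of spikes), an
    event covering all six region × outcome classes in rotation, and a truth
    record holding the oracle-computed protein consequence. Decoys are random
    exonic/intronic variants with no event.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    n_spike = int(round(cfg.n_variants * cfg.spike_fraction))
    variants: list[AnnotatedVariant] = []
    truths: list[TruthRecord] = []
    used_pos: set[tuple[str, int]] = set()

    eligible = [t for t in transcripts if t.n_exons >= 3]
    if not eligible:
        raise ValueError("no transcript large enough for internal splice events")

    for i in range(cfg.n_variants):
        spiked = i < n_spike
        t = eligible[int(rng.integers(len(eligible)))] if spiked else transcripts[int(rng.integers(len(transcripts)))]
        if spiked:
            region, ev_type = _EVENT_CLASSES[i % len(_EVENT_CLASSES)]
            try:
                event = _make_event(rng, t, ev_type)
            except ValueError:
                region, ev_type = region, "exon_skipping"
                event = _make_event(rng, t, "exon_skipping")
            v = _place_variant(rng, genome, t, event, region, cfg, used_pos)
            if v is None:
                continue
            alt_cds, net = oracle_apply(t, [event])
            exp = oracle_consequence(t.protein, alt_cds, net)
            truths.append(
                TruthRecord(
                    variant_key=v.key,
                    transcript_id=t.transcript_id,
                    is_splice_altering=True,
                    events=[event],
                    region=region,
                    expected_kind=exp["kind"],
                    expected_hgvs_p=exp["hgvs_p"],
                    expected_count=exp["count"],
                    expected_fraction=exp["fraction"],
                )
            )
        else:
            v = _place_decoy(rng, genome, t, used_pos)
            if v is None:
                continue
            truths.append(TruthRecord(variant_key=v.key, transcript_id=t.transcript_id, is_splice_altering=False))
        variants.append(v)

    _assign_afs(rng, variants, truths, cfg)
    return variants, truths


def _make_event(rng, t: TranscriptModel, ev_type: str) -> SpliceEvent:
    internal = list(range(2, t.n_exons))  # 1-based exon ordinals, keep start & stop exons
    if ev_type == "exon_skipping":
        return SpliceEvent("exon_skipping", int(rng.choice(internal)))
    if ev_type == "partial_exon_deletion":
        for k in rng.permutation(internal):
            ln = t.exon_lengths()[k - 1]
            if ln < 24:
                continue
            d = int(rng.integers(4, min(ln - 8, 90)))
            s = int(rng.integers(3, ln - d - 2))
            return SpliceEvent("partial_exon_deletion", int(k), (s, s + d - 1))
        raise ValueError("no exon large enough for a partial deletion")
    # intron_retention
    k = int(rng.integers(1, t.n_exons))
    ilen = len(t.intron_seqs[k - 1])
    mode = rng.random()
    if mode < 0.4:
        return SpliceEvent("intron_retention", k)
    d = int(rng.integers(2, min(80, ilen - 2)))
    if mode < 0.7:
        return SpliceEvent("intron_retention", k, (1, d))
    return SpliceEvent("intron_retention", k, (ilen - d + 1, ilen))


def _place_variant(rng, genome, t, event, region, cfg, used_pos):
    """A junction-proximal SNV consistent with the event's element."""
    in_consensus = rng.random() < cfg.consensus_spike_share
    if event.event_type == "intron_retention":
        intron_idx = event.element_index - 1
    elif event.element_index - 1 > 0:
        intron_idx = event.element_index - 2 if rng.random() < 0.5 else event.element_index - 1
        intron_idx = min(intron_idx, t.n_exons - 2)
    else:
        intron_idx = 0

    for _ in range(20):
        if region == "intronic":
            ilen = len(t.intron_seqs[intron_idx])
            donor_side = rng.random() < 0.5
            if donor_side:
                off = int(rng.integers(3, 9)) if in_consensus else int(rng.integers(9, max(10, min(30, ilen // 2))))
            else:
                off = int(rng.integers(3, 13)) if in_consensus else int(rng.integers(13, max(14, min(30, ilen // 2))))
            lo, hi = t.introns()[intron_idx]
            if off >= hi - lo:  # intron too short for this offset
                continue
            if t.strand == "+":
                gpos = lo + off - 1 if donor_side else hi - off + 1
            else:
                gpos = hi - off + 1 if donor_side else lo + off - 1
        else:
            exon_ord = event.element_index if event.event_type != "intron_retention" else event.element_index
            exon_ord = min(max(exon_ord, 1), t.n_exons)
            ln = t.exon_lengths()[exon_ord - 1]
            if in_consensus:
                d = int(rng.integers(1, 4))
                within = ln - d  # 0-based offset: distance -d to the donor
            else:
                within = int(rng.integers(3, ln - 3))
            toff = sum(t.exon_lengths()[: exon_ord - 1]) + within
            gpos = t.t_to_g(toff)
        if (t.contig, gpos) in used_pos:
            continue
        used_pos.add((t.contig, gpos))
        ref = genome.contigs[t.contig][gpos - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        v = AnnotatedVariant(contig=t.contig, pos=gpos, ref=ref, alt=alt, gene=t.gene, transcript_id=t.transcript_id)
        try:
            v.consequence_class = classify_variant(v, t)
        except ValueError:
            continue
        if region == "intronic" and v.consequence_class == "canonical_splicing":
            continue  # NCSVs live outside the ±2 dinucleotides
        return v
    return None


def _place_decoy(rng, genome, t, used_pos):
    for _ in range(20):
        lo, hi = t.span()
        gpos = int(rng.integers(lo, hi + 1))
        if (t.contig, gpos) in used_pos:
            continue
        used_pos.add((t.contig, gpos))
        ref = genome.contigs[t.contig][gpos - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        v = AnnotatedVariant(contig=t.contig, pos=gpos, ref=ref, alt=alt, gene=t.gene, transcript_id=t.transcript_id)
        try:
            v.consequence_class = classify_variant(v, t)
        except ValueError:
            continue
        return v
    return None


def _assign_afs(rng, variants, truths, cfg):
    truth_by_key = {tr.variant_key: tr for tr in truths}
    for v in variants:
        tr = truth_by_key.get(v.key)
        if not tr.is_splice_altering and rng.random() < cfg.common_af_fraction:
            v.af = {"gnomAD_EAS": cfg.common_af_value}
        else:
            v.af = {}


# ---------------------------------------------------------------------- #
# correlated scores


@lru_cache(maxsize=16)
def _calibrated_latent_rho(target: float, spike_fraction: float, shift: float) -> float:
    """Latent Gaussian correlation whose transformed scores hit ``target``.

    The discretisation of SPCards to 0–18, the probit marginal of SpliceAI
    and the common mean shift of spiked variants all perturb the
    product-moment correlation away from the latent value, so the latent
    correlation is solved for once by bisection on a fixed, seed-independent
    Monte-Carlo draw (common random numbers keep the curve smooth and
    monotone).
    """
    if abs(target) < 1e-12:
        return 0.0
    rng = np.random.default_rng(987654321)
    n = 60000
    z1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    sh = np.where(rng.random(n) < spike_fraction, shift, 0.0)

    def r_of(lat: float) -> float:
        z2 = lat * z1 + math.sqrt(max(0.0, 1 - lat * lat)) * e
        a = np.clip(np.rint(18 * norm.cdf(z1 + sh)), 0, 18)
        b = norm.cdf(z2 + sh)
        return float(np.corrcoef(a, b)[0, 1])

    lo, hi = -0.9999, 0.9999
    if r_of(hi) < target:
        return hi
    if r_of(lo) > target:
        return lo
    for _ in range(40):
        mid = (lo + hi) / 2
        if r_of(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def gen_scores(
    variants: list[AnnotatedVariant], truths: list[TruthRecord], cfg: SimulationConfig
) -> None:
    """Assign correlated (spcards_count, spliceai) in place.

    Default model: bivariate Gaussian copula with a common upward latent
    shift for spiked variants; ``spcards = round(18·Φ(z1))`` clipped to
    [0, 18], ``spliceai = Φ(z2)``. With ``separated_scores`` the spiked and
    decoy score ranges are fully disjoint across both thresholds (for
    sensitivity/specificity-by-construction checks).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    truth_by_key = {tr.variant_key: tr for tr in truths}
    spiked = np.array([truth_by_key[v.key].is_splice_altering for v in variants])

    if cfg.separated_scores:
        for v, sp in zip(variants, spiked):
            if sp:
                v.spliceai = float(rng.uniform(0.6, 0.99))
                v.spcards_count = int(rng.integers(10, 19))
            else:
                v.spliceai = float(rng.uniform(0.0, 0.4))
                v.spcards_count = int(rng.integers(0, 9))
        return

    lat = _calibrated_latent_rho(cfg.score_correlation, cfg.spike_fraction, cfg.spiked_score_shift)
    n = len(variants)
    z1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z2 = lat * z1 + math.sqrt(max(0.0, 1 - lat * lat)) * e
    sh = np.where(spiked, cfg.spiked_score_shift, 0.0)
    spcards = np.clip(np.rint(18 * norm.cdf(z1 + sh)), 0, 18).astype(int)
    spliceai = np.clip(norm.cdf(z2 + sh), 0.0, 1.0)
    for v, c, s in zip(variants, spcards, spliceai):
        v.spcards_count = int(c)
        v.spliceai = float(min(s, 1.0))


# ---------------------------------------------------------------------- #
# cohort generation


def gen_cohort(
    genome: GenomeRef,
    transcripts: list[TranscriptModel],
    variants: list[AnnotatedVariant],
    truths: list[TruthRecord],
    cfg: SimulationConfig,
) -> tuple[list[PatientGenotypes], list[TruthRecord]]:
    """Patient genotype tables with planted inheritance patterns + decoys.

    Planted positives are spiked NCSVs that already pass the score and
    frequency filters; compound hets get a synthesized trans LoF partner in
    the same gene. Decoy patients rotate through configurations the screen
    must reject: a lone heterozygous NCSV, a cis pair, a common-frequency
    homozygous NCSV, and a het NCSV with a benign missense partner.
    Patients are all male (matching an infertility cohort).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 3)
    truth_by_key = {tr.variant_key: tr for tr in truths}

    def qualifies(v: AnnotatedVariant) -> bool:
        tr = truth_by_key[v.key]
        if not tr.is_splice_altering:
            return False
        if v.consequence_class not in ("intronic", "missense", "synonymous"):
            return False
        if not ((v.spcards_count or 0) >= 9 or (v.spliceai or 0.0) >= 0.5):
            return False
        return not any(f > 0.01 for f in v.af.values())

    auto_pool = [v for v in variants if qualifies(v) and v.contig not in ("chrX", "X")]
    x_pool = [v for v in variants if qualifies(v) and v.contig in ("chrX", "X")]
    rng.shuffle(auto_pool)
    rng.shuffle(x_pool)
    need_auto = cfg.planted_hom + 2 * cfg.planted_comp_het  # comp-het NCSV + decoy reuse margin
    if len(auto_pool) < need_auto or len(x_pool) < cfg.planted_hemi:
        raise ValueError(
            "not enough qualifying spiked NCSVs to plant the requested cohort; "
            "increase n_variants or spike_fraction"
        )

    patients: list[PatientGenotypes] = []
    cohort_truth: list[TruthRecord] = []
    auto_iter = iter(auto_pool)
    x_iter = iter(x_pool)
    partner_serial = [0]

    def make_partner(v: AnnotatedVariant, klass: str, deleterious: bool = True) -> AnnotatedVariant:
        partner_serial[0] += 1
        t = next(t for t in transcripts if t.transcript_id == v.transcript_id)
        lo, _ = t.span()
        # place in the padding upstream of the transcript: catalog variants
        # all sit inside the span, so these keys can never collide with them
        if partner_serial[0] >= lo:
            raise ValueError("too many synthesized partner variants for the contig padding")
        pos = partner_serial[0]
        ref = genome.contigs[t.contig][pos - 1]
        alt = [b for b in _BASES if b != ref][0]
        p = AnnotatedVariant(contig=t.contig, pos=pos, ref=ref, alt=alt, gene=v.gene, transcript_id=v.transcript_id)
        p.consequence_class = klass
        p.spliceai, p.spcards_count = 0.05, 1
        if klass == "missense":
            if deleterious:
                p.predictor_calls = {"SIFT": "D", "PolyPhen2": "D", "MutationTaster": "D"}
                p.cadd = 28.0
            else:
                p.predictor_calls = {"SIFT": "T", "PolyPhen2": "B", "MutationTaster": "N"}
                p.cadd = 3.0
        return p

    pid = 0

    def new_pid() -> str:
        nonlocal pid
        pid += 1
        return f"P{pid:04d}"

    for _ in range(cfg.planted_hom):
        v = next(auto_iter)
        patients.append(PatientGenotypes(new_pid(), "male", [(v, "hom")]))
        cohort_truth.append(_pattern_truth(truth_by_key[v.key], "homozygous"))
    partner_classes = ["stop_gain", "frameshift", "missense", "canonical_splicing", "stop_loss"]
    for j in range(cfg.planted_comp_het):
        v = next(auto_iter)
        partner = make_partner(v, partner_classes[j % len(partner_classes)])
        pg = PatientGenotypes(new_pid(), "male", [(v, "het"), (partner, "het")])
        pg.phase_info[tuple(sorted((v.key, partner.key)))] = "trans"
        patients.append(pg)
        cohort_truth.append(_pattern_truth(truth_by_key[v.key], "compound_het"))
    for _ in range(cfg.planted_hemi):
        v = next(x_iter)
        patients.append(PatientGenotypes(new_pid(), "male", [(v, "hemi")]))
        cohort_truth.append(_pattern_truth(truth_by_key[v.key], "hemizygous"))

    decoy_kinds = ["lone_het", "cis_pair", "common_hom", "benign_partner"]
    n_decoys = cfg.cohort_size - cfg.planted_hom - cfg.planted_comp_het - cfg.planted_hemi
    for j in range(n_decoys):
        kind = decoy_kinds[j % len(decoy_kinds)]
        v = next(auto_iter, None)
        if v is None:
            break
        if kind == "lone_het":
            pg = PatientGenotypes(new_pid(), "male", [(v, "het")])
        elif kind == "cis_pair":
            partner = make_partner(v, "stop_gain")
            pg = PatientGenotypes(new_pid(), "male", [(v, "het"), (partner, "het")])
            pg.phase_info[tuple(sorted((v.key, partner.key)))] = "cis"
        elif kind == "common_hom":
            # mark the variant itself common so the frequency survives any
            # round trip through the variant table
            v.af = {"gnomAD_EAS": 0.04}
            pg = PatientGenotypes(new_pid(), "male", [(v, "hom")])
        else:
            partner = make_partner(v, "missense", deleterious=False)
            pg = PatientGenotypes(new_pid(), "male", [(v, "het"), (partner, "het")])
        patients.append(pg)
        cohort_truth.append(
            TruthRecord(
                variant_key=v.key,
                transcript_id=v.transcript_id,
                is_splice_altering=True,
                planted_pattern=f"decoy_{kind}",
            )
        )
    return patients, cohort_truth


def _pattern_truth(base: TruthRecord, pattern: str) -> TruthRecord:
    out = TruthRecord(**{**base.__dict__})
    out.planted_pattern = pattern
    return out


# ---------------------------------------------------------------------- #
# reconstruction of printed events (golden fixtures)

_OUTCOME_SKIP = re.compile(r"[Ee]xon\s+(\d+)\s+skipping")
_OUTCOME_RET = re.compile(r"[Ii]ntron\s+(\d+)\s+(?:(\d+)\s*bp\s+)?retention")
_OUTCOME_DEL = re.compile(r"[Ee]xon\s+(\d+)\s+(\d+)\s*bp\s+deletion")

_ALT_DEL = re.compile(r"^p\.([A-Za-z])(\d+)(?:_([A-Za-z])(\d+))?del$")
_ALT_DELINS = re.compile(r"^p\.([A-Za-z])(\d+)(?:_([A-Za-z])(\d+))?delins([A-Z]+)$")
_ALT_INS = re.compile(r"^p\.([A-Za-z])(\d+)_([A-Za-z])(\d+)ins([A-Z]+)$")
_ALT_FS = re.compile(r"^p\.([A-Za-z])(\d+)([A-Z])fs\*(\d+)$")
_ALT_STOP = re.compile(r"^p\.([A-Za-z])(\d+)\*$")


def parse_outcome(outcome: str) -> list[tuple[str, int | None]]:
    """Parse outcome descriptors like 'Exon 14 skipping' or 'Intron 2 6bp retention'."""
    parts = re.split(r"\s+and\s+|;", outcome.strip())
    out = []
    for part in parts:
        part = part.strip()
        if not part:
            continue
        if m := _OUTCOME_DEL.search(part):
            out.append(("partial_exon_deletion", int(m.group(2))))
        elif m := _OUTCOME_RET.search(part):
            out.append(("intron_retention", int(m.group(2)) if m.group(2) else None))
        elif _OUTCOME_SKIP.search(part):
            out.append(("exon_skipping", None))
        else:
            raise ValueError(f"cannot parse outcome descriptor {part!r}")
    return out


def reconstruct_printed_event(
    protein_length: int, outcome: str, alteration: str, seed: int = 0
) -> tuple[GenomeRef, TranscriptModel, list[SpliceEvent]]:
    """Engineer a toy transcript + event reproducing a printed alteration.

    Given a protein length, an outcome descriptor ('Exon 3 skipping',
    'Intron 2 6bp retention', 'Exon 31 133bp deletion', possibly compound)
    and an HGVS p. alteration string, build a plus-strand toy transcript on
    which the event's true consequence — verified against the independent
    oracle — equals the printed string, so the engine can be tested against
    table rows without the real gene sequences.
    """
    rng = np.random.default_rng(seed)
    events_spec = parse_outcome(outcome)
    alteration = alteration.strip().replace("‐", "-")

    for attempt in range(400):
        try:
            built = _try_reconstruct(protein_length, events_spec, alteration, rng)
        except _RetryConstruction:
            continue
        genome, t, events = built
        alt_cds, net = oracle_apply(t, events)
        exp = oracle_consequence(t.protein, alt_cds, net)
        if exp["hgvs_p"] == _normalize_case(alteration):
            return genome, t, events
    raise ValueError(f"could not reconstruct event for {alteration!r} / {outcome!r}")


class _RetryConstruction(Exception):
    pass


def _normalize_case(alteration: str) -> str:
    # printed tables occasionally use a lowercase residue letter (e.g. p.l920…)
    m = re.match(r"^(p\.)([a-z])(.*)$", alteration)
    if m:
        return m.group(1) + m.group(2).upper() + m.group(3)
    return alteration


def _try_reconstruct(L, events_spec, alteration, rng):
    if m := _ALT_DEL.match(alteration):
        a1, p1, a2, p2 = m.groups()
        start, end = int(p1), int(p2 or p1)
        return _build_inframe_skip(L, start, end, a1.upper(), (a2 or a1).upper(), rng)
    if m := _ALT_DELINS.match(alteration):
        a1, p1, a2, p2, ins = m.groups()
        start, end = int(p1), int(p2 or p1)
        bp = next(bp for et, bp in events_spec if et == "partial_exon_deletion")
        return _build_delins_partial(L, start, end, a1.upper(), (a2 or a1).upper(), ins, bp, rng)
    if m := _ALT_INS.match(alteration):
        a1, p1, a2, p2, ins = m.groups()
        return _build_inframe_retention(L, int(p1), a1.upper(), a2.upper(), ins, rng)
    if m := _ALT_FS.match(alteration):
        ref_aa, pos, new_aa, n = m.groups()
        return _build_lof(L, int(pos), ref_aa.upper(), new_aa, int(n), events_spec, rng)
    if m := _ALT_STOP.match(alteration):
        ref_aa, pos = m.groups()
        return _build_lof(L, int(pos), ref_aa.upper(), None, None, events_spec, rng)
    raise ValueError(f"unsupported alteration form {alteration!r}")


def _assemble(cds: str, exon_nt_lens: list[int], rng, intron_override: dict[int, str] | None = None):
    """Lay a CDS across exons on a fresh plus-strand contig and build it.

    ``intron_override`` maps 1-based intron ordinals to required sequences
    (e.g. a retained segment at the donor end); other introns are random.
    """
    if sum(exon_nt_lens) != len(cds):
        raise ValueError("exon lengths do not sum to the CDS length")
    intron_override = intron_override or {}
    pad = _rand_dna(rng, 30)
    seq = pad
    coords = []
    off = 0
    for j, ln in enumerate(exon_nt_lens):
        start = len(seq) + 1
        seq += cds[off : off + ln]
        coords.append((start, len(seq)))
        off += ln
        if j < len(exon_nt_lens) - 1:
            seq += intron_override.get(j + 1, _rand_dna(rng, int(rng.integers(60, 120))))
    seq += _rand_dna(rng, 30)
    genome = GenomeRef({"chrG": seq})
    model = TranscriptModel(
        transcript_id="TX_GOLD",
        gene="GOLD",
        contig="chrG",
        strand="+",
        exons=coords,
        cds_start=coords[0][0],
        cds_end=coords[-1][1],
    )
    return genome, build_transcript(genome, model)


def _pinned_protein(rng, L: int, pins: dict[int, str], avoid: dict[int, set[str]]) -> str:
    """Random protein of length L with 1-based pins and per-position exclusions."""
    prot = list(_rand_protein(rng, L))
    for pos, aa in pins.items():
        prot[pos - 1] = aa
    for pos, banned in avoid.items():
        if pos in pins:
            continue
        if pos == 1:
            continue
        choices = [a for a in AMINO_ACIDS if a not in banned]
        if prot[pos - 1] in banned:
            prot[pos - 1] = str(rng.choice(choices))
    return "".join(prot)


def _build_inframe_skip(L, start, end, a1, a2, rng):
    if not (2 <= start <= end < L):
        raise ValueError(f"deletion {start}-{end} does not fit a protein of {L} residues")
    pins = {start: a1, end: a2}
    avoid = {end + 1: {a1}, start - 1: {a2}}
    prot = _pinned_protein(rng, L, pins, avoid)
    cds = _back_translate(rng, prot) + _rand_stop(rng)
    lens = [3 * (start - 1), 3 * (end - start + 1), len(cds) - 3 * end]
    genome, t = _assemble(cds, lens, rng)
    return genome, t, [SpliceEvent("exon_skipping", 2)]


def _build_delins_partial(L, start, end, a1, a2, ins, bp, rng):
    if len(ins) != 1:
        raise ValueError("only single-residue delins reconstruction is supported")
    if bp != 3 * (end - start + 1) - 3:
        raise ValueError(f"{bp} bp deletion inconsistent with replacing {end - start + 1} residues by 1")
    hybrid_pairs = []
    for c1 in AA_TO_CODONS[a1]:
        for c2 in AA_TO_CODONS[a2]:
            if CODON_TO_AA.get(c1[0] + c2[1:], "*") == ins:
                hybrid_pairs.append((c1, c2, 1))
            if CODON_TO_AA.get(c1[:2] + c2[2], "*") == ins:
                hybrid_pairs.append((c1, c2, 2))
    if not hybrid_pairs:
        raise ValueError(f"no codon pair for {a1}…{a2} gives a {ins} junction residue")
    c1, c2, keep = hybrid_pairs[int(rng.integers(len(hybrid_pairs)))]
    pins = {start: a1, end: a2}
    avoid = {start - 1: {a2, ins}, end + 1: {a1, ins}}
    prot = _pinned_protein(rng, L, pins, avoid)
    codons = [rng.choice(AA_TO_CODONS[aa]) for aa in prot]
    codons[start - 1] = c1
    codons[end - 1] = c2
    cds = "".join(codons) + _rand_stop(rng)
    del_lo = 3 * (start - 1) + keep  # 0-based first deleted nt
    exon1_len = max(3, del_lo - 6)
    lens = [exon1_len, len(cds) - exon1_len]
    genome, t = _assemble(cds, lens, rng)
    sub_start = del_lo - exon1_len + 1  # 1-based within exon 2
    return genome, t, [SpliceEvent("partial_exon_deletion", 2, (sub_start, sub_start + bp - 1))]


def _build_inframe_retention(L, left, a_left, a_right, ins, rng):
    right = left + 1
    if ins[0] == a_right:
        raise ValueError("insertion starting with the downstream residue is not 3'-normalized")
    pins = {left: a_left, right: a_right}
    prot = _pinned_protein(rng, L, pins, {})
    cds = _back_translate(rng, prot) + _rand_stop(rng)
    lens = [3 * left, len(cds) - 3 * left]
    retained = _back_translate(rng, ins)
    genome, t = _assemble(cds, lens, rng, intron_override={1: retained + _rand_dna(rng, 50)})
    return genome, t, [SpliceEvent("intron_retention", 1, (1, len(retained)))]


def _build_lof(L, first, ref_aa, new_aa, n_stop, events_spec, rng):
    """Frameshift (p.Xn Y fs*N) or immediate-stop (p.Xn*) reconstruction.

    Geometry per outcome: exon skipping removes a block of length ≢ 0 mod 3
    starting at the codon-aligned junction after residue ``first − 1``;
    partial deletion removes a printed-length block inside an exon;
    retention inserts a (sub-)intron at the junction. Compound outcomes
    combine a full retention with a deletion at the start of the next exon.
    The nucleotides downstream of the junction are woven so that the shifted
    reading frame yields the printed first altered residue and stop offset
    while the reference frame stays stop-free.
    """
    P = 3 * (first - 1)
    if new_aa is None:  # immediate premature stop
        alt_specs: list[str | None] = ["*"]
    else:
        if n_stop < 2:
            raise ValueError("fs*1 is not representable; an immediate stop is p.Xn*")
        alt_specs = [new_aa] + [None] * (n_stop - 2) + ["*"]
    W = 3 * len(alt_specs)

    types = [et for et, _ in events_spec]
    if len(events_spec) == 1:
        et, bp = events_spec[0]
        if et == "exon_skipping":
            rb, rl, mode = 100, 0, "skip"
        elif et == "partial_exon_deletion":
            rb, rl, mode = bp, 0, "partial"
        else:
            if bp is None:
                rl = W + 1
            else:
                rl = bp
            rb, mode = 0, "retention"
    elif sorted(types) == ["intron_retention", "partial_exon_deletion"]:
        bp = next(b for et, b in events_spec if et == "partial_exon_deletion")
        rb = bp
        rl = next(r for r in (100, 101, 102) if (r - rb) % 3 != 0)
        mode = "compound"
    else:
        raise ValueError(f"unsupported outcome combination {types}")

    net = rl - rb
    if new_aa is not None and net % 3 == 0:
        raise ValueError("event geometry preserves the frame; cannot yield a frameshift")
    if new_aa is None and net % 3 == 0:
        raise ValueError("immediate-stop reconstruction needs a frame-shifting geometry")

    # weave the alt-frame continuation: first rl nts retained intron, rest exon
    DL = max(0, W - rl)
    block_tail = _rand_dna(rng, rb % 3)
    nts: list[str] = []
    for ci, spec in enumerate(alt_specs):
        placed = False
        for _ in range(80):
            if spec == "*":
                codon = _rand_stop(rng)
            elif spec is None:
                codon = _rand_nonstop_codon(rng)
            else:
                codon = str(rng.choice(AA_TO_CODONS[spec]))
            flat = "".join(nts) + codon
            d_part = flat[rl:]
            s = (block_tail if rb else "") + d_part
            ok = True
            for j in range(len(s) // 3):
                rc = s[3 * j : 3 * j + 3]
                if rb == 0 and j == 0:
                    if CODON_TO_AA.get(rc, "*") != ref_aa:
                        ok = False
                        break
                elif CODON_TO_AA.get(rc, "*") == "*":
                    ok = False
                    break
            if ok:
                nts.append(codon)
                placed = True
                break
        if not placed:
            raise _RetryConstruction()
    flat = "".join(nts)
    if rl > len(flat):
        retained = flat + _rand_dna(rng, rl - len(flat))
        d_region = ""
    else:
        retained = flat[:rl]
        d_region = flat[rl:]

    # reference CDS: prefix codons, the removed block, the shared downstream
    prefix_prot = _rand_protein(rng, first - 1)
    prefix = _back_translate(rng, prefix_prot)
    if rb:
        n_full = rb // 3
        if n_full < 1:
            raise ValueError("removed block shorter than one codon is not supported")
        block_codons = [str(rng.choice(AA_TO_CODONS[ref_aa]))] + [
            _rand_nonstop_codon(rng) for _ in range(n_full - 1)
        ]
        block = "".join(block_codons) + block_tail
    else:
        block = ""

    consumed = P + rb + DL
    remaining = 3 * L + 3 - consumed
    if remaining < 6:
        raise ValueError(f"protein of {L} residues too short for this geometry")
    # complete the ref codon spanning the weave boundary, then fill and stop
    partial = (len(block_tail) + DL) % 3
    filler = []
    if partial:
        need = 3 - partial
        lead = (block_tail + d_region)[-partial:]
        for _ in range(40):
            cand = _rand_dna(rng, need)
            if CODON_TO_AA.get(lead + cand, "*") != "*":
                filler.append(cand)
                break
        else:
            raise _RetryConstruction()
        remaining -= need
    if remaining < 3 or remaining % 3:
        raise _RetryConstruction()
    n_mid = remaining // 3 - 1
    mid_codons = [_rand_nonstop_codon(rng) for _ in range(n_mid)]
    if rb == 0 and DL == 0 and not filler:
        # nothing of the reference frame was woven: the codon right after the
        # junction is the first tail codon — pin it to the printed residue
        if n_mid < 1:
            raise _RetryConstruction()
        mid_codons[0] = str(rng.choice(AA_TO_CODONS[ref_aa]))
    tail = "".join(mid_codons) + _rand_stop(rng)
    cds = prefix + block + d_region + "".join(filler) + tail
    if len(cds) != 3 * L + 3:
        raise _RetryConstruction()

    # exon/intron layout + events per mode
    if mode == "skip":
        lens = [P, rb, len(cds) - P - rb]
        genome, t = _assemble(cds, lens, rng)
        return genome, t, [SpliceEvent("exon_skipping", 2)]
    if mode == "partial":
        margin = 6
        exon1 = P - margin
        if exon1 < 3:
            raise ValueError("first altered residue too close to the start for this geometry")
        lens = [exon1, len(cds) - exon1]
        genome, t = _assemble(cds, lens, rng)
        sub_start = margin + 1
        return genome, t, [SpliceEvent("partial_exon_deletion", 2, (sub_start, sub_start + rb - 1))]
    if mode == "retention":
        lens = [P, len(cds) - P]
        full = rl == W + 1 or (len(events_spec) == 1 and events_spec[0][1] is None)
        intron = retained if full else retained + _rand_dna(rng, 50)
        genome, t = _assemble(cds, lens, rng, intron_override={1: intron})
        ev = SpliceEvent("intron_retention", 1, None if full else (1, rl))
        return genome, t, [ev]
    # compound: full retention + deletion at the start of the next exon
    lens = [P, len(cds) - P]
    genome, t = _assemble(cds, lens, rng, intron_override={1: retained})
    return genome, t, [
        SpliceEvent("intron_retention", 1, None),
        SpliceEvent("partial_exon_deletion", 2, (1, rb)),
    ]
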