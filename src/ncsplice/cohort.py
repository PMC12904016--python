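"""Re-analysis triage of an exome cohort for biallelic / X-linked NCSV candidates.

The screen mirrors a rare-disease recessive workflow: common variants
(population allele frequency > 0.01 in any configured source) are excluded,
missense variants need a majority of deleteriousness calls, and candidates
are emitted per patient as homozygous, hemizygous (X in males) or
compound-heterozygous configurations in which one heterozygous allele is a
potential non-canonical splicing variant and the trans partner belongs to an
accepted pathogenic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .annotate import AnnotatedVariant, missense_deleterious

#: partner classes accepted opposite a heterozygous NCSV
TRANS_PARTNER_CLASSES = ("canonical_splicing", "stop_gain", "stop_loss", "frameshift")


@dataclass
class PatientGenotypes:
    """Genotype calls of one patient; optional phase assertions per variant pair."""

    patient_id: str
    sex: str  # male | female
    calls: list[tuple[AnnotatedVariant, str]] = field(default_factory=list)
    #: {(key1, key2): "trans" | "cis"} with keys sorted
    phase_info: dict[tuple[str, str], str] = field(default_factory=dict)

    def phase_of(self, v1: AnnotatedVariant, v2: AnnotatedVariant) -> str | None:
        return self.phase_info.get(tuple(sorted((v1.key, v2.key))))


@dataclass
class CohortCandidate:
    patient_id: str
    pattern: str  # homozygous | compound_het | hemizygous
    gene: str
    variants: list[AnnotatedVariant]
    phase_status: str = "unknown"  # validated_trans | unknown | cis_rejected

    def __post_init__(self) -> None:
        if self.pattern == "compound_het" and len(self.variants) != 2:
            raise ValueError("compound_het candidate needs exactly 2 variants")


@dataclass
class ScreenConfig:
    af_max: float = 0.01
    partner_af_max: float = 0.05
    cadd_min: float = 20.0
    x_contigs: tuple[str, ...] = ("X", "chrX")


def af_filter(v: AnnotatedVariant, af_max: float = 0.01) -> bool:
    """True = keep. Dropped iff any configured AF source exceeds ``af_max`` (strict).

    Missing frequencies keep the variant: absence of evidence of commonness
    is not treated as commonness.
    """
    for freq in v.af.values():
        if freq is not None and freq > af_max:
            return False
    return True


def is_potential_ncsv(v: AnnotatedVariant, spcards_min: int = 9, spliceai_min: float = 0.5) -> bool:
    """Splicing-prioritized and not an established LoF class (see annotate)."""
    if v.consequence_class in ("canonical_splicing", "stop_gain", "stop_loss", "frameshift"):
        return False
    hit = (v.spcards_count is not None and v.spcards_count >= spcards_min) or (
        v.spliceai is not None and v.spliceai >= spliceai_min
    )
    return hit


def _qualifies_as_partner(v: AnnotatedVariant, cfg: ScreenConfig, ncsv_flags: dict[str, bool]) -> bool:
    if not af_filter(v, cfg.partner_af_max):
        return False
    if v.consequence_class in TRANS_PARTNER_CLASSES:
        return True
    if v.consequence_class == "missense" and missense_deleterious(v, cfg.cadd_min)[0]:
        return True
    return bool(ncsv_flags.get(v.key, False))


def inheritance_screen(
    p: PatientGenotypes,
    ncsv_flags: dict[str, bool],
    cfg: ScreenConfig | None = None,
) -> list[CohortCandidate]:
    """Biallelic / X-linked candidate configurations for one patient.

    ``ncsv_flags`` maps variant key → whether the variant is a potential
    NCSV. Emits: homozygous NCSVs; hemizygous NCSVs on X in males;
    compound-het pairs (het NCSV + qualifying het trans partner in the same
    gene). Pairs asserted cis are rejected; pairs without phase evidence are
    emitted with ``phase_status='unknown'`` for downstream confirmation.
    Output order is deterministic and independent of input call order.
    """
    cfg = cfg or ScreenConfig()
    out: list[CohortCandidate] = []

    kept = [(v, z) for v, z in p.calls if z == "het" or af_filter(v, cfg.af_max)]
    # NCSV arm keeps the strict filter even for hets
    by_gene: dict[str, list[tuple[AnnotatedVariant, str]]] = {}
    for v, z in sorted(kept, key=lambda c: (c[0].gene, c[0].key)):
        by_gene.setdefault(v.gene, []).append((v, z))

    for gene, calls in sorted(by_gene.items()):
        for v, z in calls:
            is_ncsv = ncsv_flags.get(v.key, False) and af_filter(v, cfg.af_max)
            if not is_ncsv:
                continue
            if z == "hom":
                out.append(CohortCandidate(p.patient_id, "homozygous", gene, [v], "validated_trans"))
            elif z == "hemi":
                if p.sex != "male" or v.contig not in cfg.x_contigs:
                    raise ValueError(
                        f"hemizygous call for {v.key} in {p.patient_id}: "
                        "hemizygosity is only valid on X in males"
                    )
                out.append(CohortCandidate(p.patient_id, "hemizygous", gene, [v], "validated_trans"))

        hets = [v for v, z in calls if z == "het"]
        for v1, v2 in combinations(hets, 2):
            n1 = ncsv_flags.get(v1.key, False) and af_filter(v1, cfg.af_max)
            n2 = ncsv_flags.get(v2.key, False) and af_filter(v2, cfg.af_max)
            pair_ok = (n1 and _qualifies_as_partner(v2, cfg, ncsv_flags)) or (
                n2 and _qualifies_as_partner(v1, cfg, ncsv_flags)
            )
            if not pair_ok:
                continue
            phase = p.phase_of(v1, v2)
            if phase == "cis":
                continue
            status = "validated_trans" if phase == "trans" else "unknown"
            out.append(CohortCandidate(p.patient_id, "compound_het", gene, [v1, v2], status))
    return out


def screen_cohort(
    patients: list[PatientGenotypes],
    ncsv_flags: dict[str, bool],
    cfg: ScreenConfig | None = None,
) -> list[CohortCandidate]:
    out = []
    for p in sorted(patients, key=lambda q: q.patient_id):
        out.extend(inheritance_screen(p, ncsv_flags, cfg))
    return out


def gene_panel_filter(
    candidates: list[CohortCandidate], panel: set[str]
) -> tuple[list[CohortCandidate], list[str]]:
    """Keep candidates whose gene is on the curated panel.

    An empty panel passes everything through (with the dropped-gene list
    empty); callers should warn in that case. Returns (kept, dropped genes).
    """
    if not panel:
        return list(candidates), []
    kept = [c for c in candidates if c.gene in panel]
    dropped = sorted({c.gene for c in candidates if c.gene not in panel})
    return kept, dropped
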