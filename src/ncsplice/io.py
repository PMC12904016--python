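"""Readers and writers for the pipeline's external formats, plus configuration.

Formats: FASTA genomes (Biopython), GTF transcript models (written directly,
read back through gffutils), TSV variant/event/cohort tables (pandas), an
uncompressed VCF flavour carrying the splicing annotations in INFO fields
(pysam), truth-label JSON, and report JSON/TSV. TSV is the primary
interchange format; the VCF path exists for interoperability with
variant-calling toolchains.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import AnnotatedVariant
from .cohort import PatientGenotypes
from .consequence import SpliceEvent
from .reference import GenomeRef, TranscriptModel


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their standard defaults.

    ``spcards_min``/``spliceai_min`` are the dual prioritization cut-offs;
    ``af_max`` the common-variant exclusion; ``partner_af_max`` the lenient
    frequency bound for trans partners of an NCSV; ``cadd_damaging`` the
    CADD deleteriousness cut-off; ``pvs1_fraction`` the disrupted-protein
    share above which a LoF-type consequence is PVS1_Strong. Consensus
    windows are signed distances around donors/acceptors.
    """

    spcards_min: int = 9
    spliceai_min: float = 0.5
    af_max: float = 0.01
    partner_af_max: float = 0.05
    cadd_damaging: float = 20.0
    pvs1_fraction: float = 0.10
    donor_window: tuple[int, int] = (-3, 8)
    acceptor_window: tuple[int, int] = (-12, 2)
    seed: int = 0

    def validate(self) -> None:
        if self.spcards_min < 0 or not 0 <= self.spliceai_min <= 1:
            raise ValueError("invalid prioritization thresholds")
        if self.af_max <= 0 or self.partner_af_max <= 0:
            raise ValueError("allele-frequency thresholds must be positive")
        for lo, hi in (self.donor_window, self.acceptor_window):
            if lo > hi:
                raise ValueError("consensus window bounds reversed")


# ---------------------------------------------------------------------- #
# FASTA


def write_genome_fasta(genome: GenomeRef, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> GenomeRef:
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return GenomeRef(contigs)


# ---------------------------------------------------------------------- #
# GTF


def write_transcripts_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Exon + CDS features with gene_id/transcript_id attributes (GTF dialect)."""
    lines = []
    for t in transcripts:
        attrs = f'gene_id "{t.gene}"; transcript_id "{t.transcript_id}";'
        for s, e in sorted(t.exons):
            lines.append(f"{t.contig}\tncsplice\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}")
        cds_lo, cds_hi = sorted((t.cds_start, t.cds_end))
        for s, e in sorted(t.exons):
            lo, hi = max(s, cds_lo), min(e, cds_hi)
            if lo <= hi:
                lines.append(f"{t.contig}\tncsplice\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_transcripts_gtf(path: str | Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [None])[0]
        gene = feat.attributes.get("gene_id", [feat.attributes.get("gene_name", ["?"])[0]])[0]
        if tid is None:
            continue
        entry = by_tx.setdefault(
            tid, {"gene": gene, "contig": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        if feat.featuretype == "exon":
            entry["exons"].append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            entry["cds"].append((feat.start, feat.end))
    out = []
    for tid, entry in by_tx.items():
        if not entry["exons"] or not entry["cds"]:
            raise ValueError(f"transcript {tid} lacks exon or CDS features")
        exons = sorted(entry["exons"])
        if entry["strand"] == "-":
            exons = exons[::-1]
        cds_lo = min(s for s, _ in entry["cds"])
        cds_hi = max(e for _, e in entry["cds"])
        cds_start, cds_end = (cds_lo, cds_hi) if entry["strand"] == "+" else (cds_hi, cds_lo)
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene=entry["gene"],
                contig=entry["contig"],
                strand=entry["strand"],
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return sorted(out, key=lambda t: t.transcript_id)


# ---------------------------------------------------------------------- #
# variant tables (TSV)

_VAR_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript_id",
    "hgvs_c",
    "consequence_class",
    "spliceai",
    "spcards",
    "af_1kgp",
    "af_gnomad_eas",
    "sift",
    "polyphen2",
    "mutationtaster",
    "cadd",
    "zygosity",
    "prior_validation",
]


def _opt(x):
    if x is None:
        return "NA"
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return x


def _num(x, cast):
    if x is None or (isinstance(x, float) and math.isnan(x)) or x in ("", "NA", "-", "."):
        return None
    return cast(x)


def write_variant_tsv(variants: list[AnnotatedVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "contig": v.contig,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "transcript_id": v.transcript_id,
                "hgvs_c": v.hgvs_c or "NA",
                "consequence_class": v.consequence_class or "NA",
                "spliceai": _opt(v.spliceai),
                "spcards": _opt(v.spcards_count),
                "af_1kgp": _opt(v.af.get("1KGP")),
                "af_gnomad_eas": _opt(v.af.get("gnomAD_EAS")),
                "sift": _opt(v.predictor_calls.get("SIFT")),
                "polyphen2": _opt(v.predictor_calls.get("PolyPhen2")),
                "mutationtaster": _opt(v.predictor_calls.get("MutationTaster")),
                "cadd": _opt(v.cadd),
                "zygosity": _opt(v.zygosity),
                "prior_validation": v.prior_validation,
            }
        )
    pd.DataFrame(rows, columns=_VAR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("contig", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks required columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            af = {}
            if _num(row.get("af_1kgp"), float) is not None:
                af["1KGP"] = float(row["af_1kgp"])
            if _num(row.get("af_gnomad_eas"), float) is not None:
                af["gnomAD_EAS"] = float(row["af_gnomad_eas"])
            calls = {}
            for tool, col in (("SIFT", "sift"), ("PolyPhen2", "polyphen2"), ("MutationTaster", "mutationtaster")):
                val = row.get(col, "NA")
                if val not in ("", "NA", "-", "."):
                    calls[tool] = val
            v = AnnotatedVariant(
                contig=row["contig"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row.get("gene", ""),
                transcript_id=row.get("transcript_id", ""),
                hgvs_c="" if row.get("hgvs_c", "") in ("", "NA") else row["hgvs_c"],
                consequence_class=None if row.get("consequence_class", "NA") in ("", "NA") else row["consequence_class"],
                spliceai=_num(row.get("spliceai"), float),
                spcards_count=_num(row.get("spcards"), int),
                af=af,
                predictor_calls=calls,
                cadd=_num(row.get("cadd"), float),
                zygosity=None if row.get("zygosity", "NA") in ("", "NA") else row["zygosity"],
                prior_validation=row.get("prior_validation", "none") or "none",
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
        out.append(v)
    return out


# ---------------------------------------------------------------------- #
# VCF flavour (uncompressed, annotations in INFO)

_VCF_INFO = [
    ("GENE", "1", "String", "Gene symbol"),
    ("TRANSCRIPT", "1", "String", "Transcript identifier"),
    ("HGVSC", "1", "String", "HGVS c. description"),
    ("CLASS", "1", "String", "Consequence class"),
    ("SPLICEAI", "1", "Float", "SpliceAI delta score"),
    ("SPCARDS", "1", "Integer", "Number of splicing predictors calling splice-altering"),
    ("AF1KGP", "1", "Float", "1KGP allele frequency"),
    ("AFGNOMADEAS", "1", "Float", "gnomAD EAS allele frequency"),
]


def write_variant_vcf(variants: list[AnnotatedVariant], path: str | Path, genome: GenomeRef) -> None:
    import pysam

    header = pysam.VariantHeader()
    for name, seq in genome.contigs.items():
        header.contigs.add(name, length=len(seq))
    for vid, number, vtype, desc in _VCF_INFO:
        header.info.add(vid, number, vtype, desc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.contig, x.pos)):
            rec = out.new_record(contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt))
            rec.info["GENE"] = v.gene or "."
            rec.info["TRANSCRIPT"] = v.transcript_id or "."
            if v.hgvs_c:
                rec.info["HGVSC"] = v.hgvs_c
            if v.consequence_class:
                rec.info["CLASS"] = v.consequence_class
            if v.spliceai is not None:
                rec.info["SPLICEAI"] = v.spliceai
            if v.spcards_count is not None:
                rec.info["SPCARDS"] = v.spcards_count
            if "1KGP" in v.af:
                rec.info["AF1KGP"] = v.af["1KGP"]
            if "gnomAD_EAS" in v.af:
                rec.info["AFGNOMADEAS"] = v.af["gnomAD_EAS"]
            out.write(rec)


def read_variant_vcf(path: str | Path) -> list[AnnotatedVariant]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            af = {}
            if "AF1KGP" in info:
                af["1KGP"] = float(info["AF1KGP"])
            if "AFGNOMADEAS" in info:
                af["gnomAD_EAS"] = float(info["AFGNOMADEAS"])
            out.append(
                AnnotatedVariant(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=str(info.get("GENE", "")).replace(".", ""),
                    transcript_id=str(info.get("TRANSCRIPT", "")).replace(".", ""),
                    hgvs_c=str(info["HGVSC"]) if "HGVSC" in info else "",
                    consequence_class=str(info["CLASS"]) if "CLASS" in info else None,
                    spliceai=float(info["SPLICEAI"]) if "SPLICEAI" in info else None,
                    spcards_count=int(info["SPCARDS"]) if "SPCARDS" in info else None,
                    af=af,
                )
            )
    return out


# ---------------------------------------------------------------------- #
# events / cohort / truth


def write_events_tsv(events: dict[str, list[SpliceEvent]], path: str | Path) -> None:
    rows = []
    for key, evs in events.items():
        for e in evs:
            rows.append(
                {
                    "variant_key": key,
                    "event_type": e.event_type,
                    "element_index": e.element_index,
                    "sub_start": e.sub_interval[0] if e.sub_interval else "NA",
                    "sub_end": e.sub_interval[1] if e.sub_interval else "NA",
                }
            )
    pd.DataFrame(rows, columns=["variant_key", "event_type", "element_index", "sub_start", "sub_end"]).to_csv(
        path, sep="\t", index=False
    )


def read_events_tsv(path: str | Path) -> dict[str, list[SpliceEvent]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[SpliceEvent]] = {}
    for i, row in df.iterrows():
        try:
            sub = None
            if row["sub_start"] not in ("", "NA"):
                sub = (int(row["sub_start"]), int(row["sub_end"]))
            ev = SpliceEvent(row["event_type"], int(row["element_index"]), sub)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
        out.setdefault(row["variant_key"], []).append(ev)
    return out


def write_cohort_tsv(patients: list[PatientGenotypes], path: str | Path) -> None:
    rows = []
    for p in patients:
        phase_by_key: dict[str, str] = {}
        for (k1, k2), rel in p.phase_info.items():
            phase_by_key[k1] = f"{rel}:{k2}"
            phase_by_key[k2] = f"{rel}:{k1}"
        for v, z in p.calls:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "sex": p.sex,
                    "variant_key": v.key,
                    "zygosity": z,
                    "phase": phase_by_key.get(v.key, "NA"),
                }
            )
    pd.DataFrame(rows, columns=["patient_id", "sex", "variant_key", "zygosity", "phase"]).to_csv(
        path, sep="\t", index=False
    )


def read_cohort_tsv(path: str | Path, variants_by_key: dict[str, AnnotatedVariant]) -> list[PatientGenotypes]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    patients: dict[str, PatientGenotypes] = {}
    for i, row in df.iterrows():
        pid = row["patient_id"]
        p = patients.setdefault(pid, PatientGenotypes(pid, row["sex"]))
        key = row["variant_key"]
        if key not in variants_by_key:
            raise ValueError(f"{path}, line {i + 2}: unknown variant key {key}")
        p.calls.append((variants_by_key[key], row["zygosity"]))
        if row.get("phase", "NA") not in ("", "NA"):
            rel, other = row["phase"].split(":", 1)
            p.phase_info[tuple(sorted((key, other)))] = rel
    return list(patients.values())


def write_truth_json(truths, path: str | Path) -> None:
    payload = []
    for tr in truths:
        d = dict(tr.__dict__)
        d["events"] = [
            {"event_type": e.event_type, "element_index": e.element_index, "sub_interval": e.sub_interval}
            for e in d.get("events", [])
        ]
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path):
    from .simulate import TruthRecord

    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        evs = [
            SpliceEvent(e["event_type"], e["element_index"], tuple(e["sub_interval"]) if e["sub_interval"] else None)
            for e in d.pop("events", [])
        ]
        out.append(TruthRecord(events=evs, **d))
    return out


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=str))
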