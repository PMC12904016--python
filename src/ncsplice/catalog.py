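"""Packaged curated-catalog fixtures and the headline fractions derived from them.

The package ships a factual transcription of the curated positive-NCSV
tables (protein alterations, disrupted fractions, distances and scores), the
study-level bookkeeping counts, and the biallelic/X-linked cohort genotype
table, so the full reporting layer can be exercised without downloads.
Rows whose printed numbers are internally inconsistent carry ``golden = 0``
and a note describing the discrepancy; they are kept as data but excluded
from exact-match checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotate import JunctionContext
from .stats import SummaryReport, rate


def _data_path(name: str):
    return resources.files("ncsplice").joinpath("data", name)


def load_catalog() -> pd.DataFrame:
    """The 41 positive NCSVs with outcome, alteration and fraction columns."""
    with resources.as_file(_data_path("curated_catalog.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"distance": "Int64", "golden": "Int64"})
    return df


def load_study_counts() -> dict[str, int]:
    with resources.as_file(_data_path("study_counts.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["name"], df["value"].astype(int)))


def load_cohort_table() -> pd.DataFrame:
    """Biallelic / X-linked candidate genotypes of the re-analysis cohort."""
    with resources.as_file(_data_path("cohort_table.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def golden_rows(df: pd.DataFrame | None = None) -> pd.DataFrame:
    df = load_catalog() if df is None else df
    return df[df["golden"] == 1].reset_index(drop=True)


def junction_side(var_type: str, distance: int) -> str:
    """Donor/acceptor side from the variant class and the signed distance.

    Intronic variants past a donor have positive distances and those ahead
    of an acceptor negative ones; for exonic variants the signs flip (the
    base just 5' of a donor is −1, the base k past an acceptor +k).
    """
    intronic = var_type.strip().lower().startswith("intron")
    if intronic:
        return "donor" if distance > 0 else "acceptor"
    return "donor" if distance < 0 else "acceptor"


def catalog_contexts(df: pd.DataFrame | None = None) -> list[JunctionContext]:
    """Junction contexts of all catalog positives, from type + distance."""
    df = load_catalog() if df is None else df
    out = []
    for _, row in df.iterrows():
        d = int(row["distance"])
        side = junction_side(row["var_type"], d)
        region = "intronic" if str(row["var_type"]).lower().startswith("intron") else "exonic"
        out.append(JunctionContext(side, d, region, JunctionContext.consensus(side, d)))
    return out


def headline_report() -> SummaryReport:
    """The study's headline fractions, re-derived from the packaged counts.

    Every percentage keeps its numerator/denominator; nothing is stored
    pre-computed.
    """
    c = load_study_counts()
    rep = SummaryReport()
    positives_all = c["prior_ncsv_validated"] + c["positive_reported_new"]
    splicing_all = c["class_canonical_splicing"] + positives_all
    rep.add_rate("ncsv_share_of_splicing", positives_all, splicing_all)
    rep.add_rate(
        "ncsv_expansion",
        c["positive_reported_new"] - c["prior_ncsv_predicted"],
        c["prior_ncsv_total"],
    )
    rep.add_rate("reported_validation_rate", c["positive_reported_total"], c["minigene_tested_reported"])
    rep.add_rate(
        "overall_validation_rate",
        c["positives_total"],
        c["minigene_tested_reported"] + c["cohort_potential_ncsv"],
    )
    rep.add_rate("cohort_prevalence", c["cohort_positive_patients"], c["cohort_size"])
    rep.add_rate("both_arm_share", c["prioritized_both_arms"], c["prioritized_total"])
    rep.add_rate("inheritance_confirmed_rate", c["cohort_inheritance_confirmed"], c["cohort_sanger_patients"])
    return rep
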