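"""Rates, tallies, consensus shares, exact 2×2 inference and correlations."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from ncsplice.catalog import catalog_contexts, headline_report, load_catalog, load_study_counts
from ncsplice.stats import (
    ContingencyTable2x2,
    SummaryReport,
    consensus_share,
    fisher_exact,
    rate,
    score_correlation,
    tally_classes,
)


class TestRate:
    @pytest.mark.parametrize(
        "num,den,pct",
        [(49, 169, 28.99), (17, 32, 53.13), (28, 48, 58.33), (41, 66, 62.12), (12, 718, 1.67), (0, 5, 0.0)],
    )
    def test_half_up_two_decimals(self, num, den, pct):
        assert rate(num, den) == pct

    def test_half_up_boundary(self):
        assert rate(1, 8) == 12.5
        assert rate(1, 16) == 6.25
        assert rate(125, 1000) == 12.5
        assert rate(1125, 10000) == 11.25
        assert rate(49999, 1000000) == 5.0  # 4.9999 -> 5.00

    def test_random_pairs_match_exact_rational_oracle(self):
        from fractions import Fraction

        rng = np.random.default_rng(11)
        for _ in range(300):
            num = int(rng.integers(0, 5000))
            den = int(rng.integers(1, 5000))
            exact = Fraction(100 * num, den)
            # half-up at 2 dp via integer arithmetic
            scaled = exact * 100
            floor = scaled.numerator // scaled.denominator
            rem = scaled - floor
            expected = (floor + (1 if rem >= Fraction(1, 2) else 0)) / 100
            assert rate(num, den) == pytest.approx(float(expected), abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rate(1, 0)


class TestTally:
    def test_replica_class_counts_report_discrepancy(self):
        counts = load_study_counts()
        classes = {k.removeprefix("class_"): v for k, v in counts.items() if k.startswith("class_")}
        catalog = [cls for cls, n in classes.items() for _ in range(n)]
        out = tally_classes(catalog, expected_total=counts["curated_total"])
        assert out["sum"] == 2403
        assert out["discrepancy"] == 1  # the curated total is one more than the class sum
        assert out["counts"]["missense"] == 1486


class TestConsensusShare:
    def test_catalog_positives_share(self):
        ctxs = catalog_contexts()
        pct, n_in, n_all = consensus_share(ctxs)
        assert (n_in, n_all) == (29, 41)
        assert pct == 70.73

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            consensus_share([])

    def test_fuzzed_distances_match_window_oracle(self):
        from ncsplice.annotate import JunctionContext

        rng = np.random.default_rng(3)
        ctxs = []
        expected = 0
        for _ in range(500):
            side = "donor" if rng.random() < 0.5 else "acceptor"
            d = int(rng.integers(-30, 31)) or 1
            lo, hi = (-3, 8) if side == "donor" else (-12, 2)
            expected += lo <= d <= hi
            ctxs.append(JunctionContext(side, d, "exonic", JunctionContext.consensus(side, d)))
        _, n_in, _ = consensus_share(ctxs)
        assert n_in == expected


def _enumeration_pvalue(a, b, c, d):
    """Probability-mass two-sided p by full fixed-margin enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


class TestFisher:
    def test_symmetric_table(self):
        r = fisher_exact(ContingencyTable2x2(1, 1, 1, 1))
        assert r.p_value == pytest.approx(1.0)
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_small_table_vs_enumeration(self):
        r = fisher_exact(ContingencyTable2x2(3, 1, 1, 3))
        assert r.p_value == pytest.approx(_enumeration_pvalue(3, 1, 1, 3), abs=1e-12)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(250):
            n = int(rng.integers(1, 61))
            a_, b_, c_ = sorted(rng.integers(0, n + 1, size=3))
            a, b, c, d = a_, b_ - a_, c_ - b_, n - c_
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            r = fisher_exact(t)
            assert r.p_value == pytest.approx(_enumeration_pvalue(a, b, c, d), abs=1e-12)

    def test_degenerate_margin(self):
        r = fisher_exact(ContingencyTable2x2(0, 0, 3, 5))
        assert r.p_value == 1.0 and r.odds_ratio is None

    def test_or_and_ci_match_conditional_mle_reference(self):
        """Frozen against R's fisher.test (conditional MLE + exact CI)."""
        r = fisher_exact(ContingencyTable2x2(24, 3, 12, 2))
        assert r.odds_ratio == pytest.approx(1.323656, abs=1e-4)
        assert r.ci_low == pytest.approx(0.09815381, abs=1e-4)
        assert r.ci_high == pytest.approx(13.26186, rel=1e-3)
        r2 = fisher_exact(ContingencyTable2x2(0, 5, 7, 2))
        assert r2.p_value == pytest.approx(0.02097902, abs=1e-9)
        assert r2.odds_ratio == 0.0 and r2.ci_low == 0.0
        assert r2.ci_high == pytest.approx(0.6899019, abs=1e-4)

    def test_cross_product_option(self):
        r = fisher_exact(ContingencyTable2x2(24, 3, 12, 2), or_method="cross")
        assert r.odds_ratio == pytest.approx((24 * 2) / (3 * 12))


class TestCorrelation:
    def test_perfectly_linear(self):
        x = list(range(10))
        y = [2 * v + 1 for v in x]
        res = score_correlation(x, y)
        assert res["r"] == pytest.approx(1.0)

    def test_constant_column_undefined(self):
        res = score_correlation([1, 1, 1, 1], [0.1, 0.4, 0.2, 0.9])
        assert res["undefined"] is True

    def test_pairwise_missing_excluded(self):
        res = score_correlation([1, 2, None, 4, 5], [0.1, 0.2, 0.3, None, 0.5])
        assert res["n"] == 3


class TestHeadlines:
    def test_fractions_carry_numerators(self):
        rep = headline_report()
        f = rep.fractions
        assert f["ncsv_share_of_splicing"]["numerator"] == 49
        assert f["ncsv_share_of_splicing"]["denominator"] == 169
        assert all("numerator" in v and "denominator" in v for v in f.values())

    def test_catalog_region_tallies(self):
        df = load_catalog()
        intronic = (df["var_type"].str.lower().str.startswith("intron")).sum()
        assert intronic + (len(df) - intronic) == 41
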