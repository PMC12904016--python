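"""Catalog and cohort summary statistics.

Percentages are rounded half-up at two decimals, matching the convention of
printed clinical-genetics tables. The 2×2 exact test uses the
probability-mass definition of the two-sided p (sum of fixed-margin tables
as or less probable than the observed one), a conditional
maximum-likelihood odds ratio, and an exact conditional confidence
interval, so zero cells need no continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import optimize, stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = groups (e.g. exonic/intronic), cols = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float | None  # None when undefined (degenerate margin)
    ci_low: float | None
    ci_high: float | None
    method: str


def rate(numerator: int, denominator: int) -> float:
    """Percentage at 2 decimal places, half-up (printed-table style)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def tally_classes(catalog, expected_total: int | None = None) -> dict:
    """Count variants per consequence class; report any total mismatch.

    ``catalog`` is an iterable of objects with a ``consequence_class``
    attribute (or plain class-name strings). The returned dict carries the
    per-class counts, their sum, and — when ``expected_total`` is given — the
    discrepancy between the two rather than forcing agreement.
    """
    counts: dict[str, int] = {}
    for v in catalog:
        cls = v if isinstance(v, str) else v.consequence_class
        counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    out = {"counts": counts, "sum": total}
    if expected_total is not None:
        out["expected_total"] = expected_total
        out["discrepancy"] = expected_total - total
    return out


def consensus_share(contexts) -> tuple[float, int, int]:
    """Share of junction contexts inside a splicing consensus window.

    Returns (percentage at 2 dp, in-consensus count, total).
    """
    ctxs = list(contexts)
    if not ctxs:
        raise ValueError("no junction contexts supplied")
    n_in = sum(1 for c in ctxs if c.in_consensus)
    return rate(n_in, len(ctxs)), n_in, len(ctxs)


# ---------------------------------------------------------------------- #
# exact 2x2 inference


def _support(t: ContingencyTable2x2) -> tuple[int, int, np.ndarray]:
    r1, c1, n = t.a + t.b, t.a + t.c, t.total
    lo = max(0, c1 - (t.c + t.d))
    hi = min(r1, c1)
    return lo, hi, np.arange(lo, hi + 1)


def fisher_exact(t: ContingencyTable2x2, or_method: str = "cmle", alpha: float = 0.05) -> FisherResult:
    """Exact test of association for a 2×2 table.

    p: two-sided by hypergeometric probability mass. OR: conditional MLE
    (``or_method='cmle'``) or sample cross-product (``'cross'``). CI: exact
    conditional (tail inversion of Fisher's noncentral hypergeometric).
    Degenerate margins give p = 1 with an undefined OR.
    """
    r1, c1, n = t.a + t.b, t.a + t.c, t.total
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return FisherResult(1.0, None, None, None, "degenerate-margin")

    lo, hi, ks = _support(t)
    pmf = sps.hypergeom.pmf(ks, n, r1, c1)
    p_obs = sps.hypergeom.pmf(t.a, n, r1, c1)
    p_value = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))

    if or_method == "cross":
        if t.b * t.c == 0:
            or_hat = math.inf if t.a * t.d > 0 else (0.0 if t.a == 0 or t.d == 0 else None)
        else:
            or_hat = (t.a * t.d) / (t.b * t.c)
    elif or_method == "cmle":
        or_hat = _cmle_or(t.a, n, r1, c1, lo, hi)
    else:
        raise ValueError(f"unknown or_method {or_method!r}")

    ci_low, ci_high = _exact_ci(t.a, n, r1, c1, lo, hi, alpha)
    return FisherResult(p_value, or_hat, ci_low, ci_high, f"exact-{or_method}")


def _log_comb(n, k):
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _cond_dist(n, r1, c1, ks, log_psi: float) -> np.ndarray:
    """Fisher noncentral hypergeometric pmf over the support at odds exp(log_psi)."""
    r2 = n - r1
    logw = _log_comb(r1, ks) + _log_comb(r2, c1 - ks) + ks * log_psi
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _cmle_or(a, n, r1, c1, lo, hi) -> float:
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf
    ks = np.arange(lo, hi + 1)

    def score(log_psi):
        d = _cond_dist(n, r1, c1, ks, log_psi)
        return float((ks * d).sum() - a)  # E[X|psi] − a; monotone increasing

    root = optimize.brentq(score, -50, 50, xtol=1e-12)
    return float(math.exp(root))


def _exact_ci(a, n, r1, c1, lo, hi, alpha) -> tuple[float, float]:
    ks = np.arange(lo, hi + 1)

    def upper_tail(log_psi):  # P(X >= a | psi)
        d = _cond_dist(n, r1, c1, ks, log_psi)
        return float(d[ks >= a].sum())

    def lower_tail(log_psi):  # P(X <= a | psi)
        d = _cond_dist(n, r1, c1, ks, log_psi)
        return float(d[ks <= a].sum())

    if a == lo:
        ci_low = 0.0
    else:
        ci_low = math.exp(optimize.brentq(lambda lp: upper_tail(lp) - alpha / 2, -60, 60, xtol=1e-10))
    if a == hi:
        ci_high = math.inf
    else:
        ci_high = math.exp(optimize.brentq(lambda lp: lower_tail(lp) - alpha / 2, -60, 60, xtol=1e-10))
    return ci_low, ci_high


def score_correlation(spcards, spliceai) -> dict:
    """Pearson correlation between the two splicing scores, pairwise-complete.

    Rows with a missing value on either side are excluded. A constant column
    (or fewer than 3 complete pairs) yields ``undefined=True``.
    """
    x = np.asarray([np.nan if v is None else float(v) for v in spcards])
    y = np.asarray([np.nan if v is None else float(v) for v in spliceai])
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": None, "p": None, "n": int(len(x)), "undefined": True}
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x)), "undefined": False}


# ---------------------------------------------------------------------- #
# report assembly


@dataclass
class SummaryReport:
    """Headline fractions of an NCSV analysis, each with its n/d retained."""

    fractions: dict[str, dict] = field(default_factory=dict)
    class_tallies: dict | None = None
    fisher: FisherResult | None = None
    correlation: dict | None = None

    def add_rate(self, name: str, numerator: int, denominator: int) -> float:
        pct = rate(numerator, denominator)
        self.fractions[name] = {"numerator": numerator, "denominator": denominator, "percent": pct}
        return pct

    def as_dict(self) -> dict:
        out = {"fractions": self.fractions}
        if self.class_tallies is not None:
            out["class_tallies"] = self.class_tallies
        if self.fisher is not None:
            out["fisher"] = {
                "p_value": self.fisher.p_value,
                "odds_ratio": self.fisher.odds_ratio,
                "ci": [self.fisher.ci_low, self.fisher.ci_high],
                "method": self.fisher.method,
            }
        if self.correlation is not None:
            out["score_correlation"] = self.correlation
        return out
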