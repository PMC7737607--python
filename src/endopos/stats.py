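"""Statistical comparisons for per-cell and per-endosome measurements.

The conventions mirror common practice in cell-biology figure legends:

* two unpaired groups — two-tailed heteroscedastic (Welch) t-test;
* more than two groups — one-way ANOVA with Bonferroni-corrected post hoc
  pairwise t-tests over the comparisons actually requested;
* distribution-tail contrast — one-sided two-sample Kolmogorov-Smirnov test
  of the alternative that the first sample has the longer right tail
  (is stochastically larger), with the asymptotic one-sided p-value
  ``exp(-2 D+^2 n_x n_y / (n_x + n_y))``;
* dispersion reporting — sample SD (n-1 denominator) and SEM = SD/sqrt(n);
* stars — ns for p > 0.05, then * / ** / *** at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleVector",
    "TestResult",
    "significance_code",
    "welch_t_test",
    "anova_bonferroni",
    "ks_tail_test",
    "describe",
]


@dataclass(frozen=True)
class SampleVector:
    """A labeled group of real-valued measurements."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite values in sample {self.label!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    degrees_of_freedom: float | None = None
    adjusted_p: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significance_code(self) -> str:
        return significance_code(
            self.adjusted_p if self.adjusted_p is not None else self.p_value
        )


def significance_code(p: float) -> str:
    """ns / * / ** / *** at the 0.05 / 0.01 / 0.001 thresholds."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _as_sample(x: SampleVector | Sequence[float], label: str = "") -> SampleVector:
    return x if isinstance(x, SampleVector) else SampleVector(np.asarray(x), label)


def welch_t_test(
    x: SampleVector | Sequence[float], y: SampleVector | Sequence[float]
) -> TestResult:
    """Two-tailed heteroscedastic (Welch) t-test for two unpaired groups.

    Uses the Welch-Satterthwaite degrees of freedom. Two zero-variance
    samples with equal means are degenerate; by convention p = 1 (flagged in
    the result note).
    """
    x, y = _as_sample(x, "x"), _as_sample(y, "y")
    if x.n < 2 or y.n < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.values.var(ddof=1), y.values.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.values.mean() == y.values.mean():
            return TestResult(
                "welch_t", 0.0, 1.0, degrees_of_freedom=float(x.n + y.n - 2),
                note="degenerate: both samples constant and equal; p = 1 by convention",
            )
        return TestResult(
            "welch_t", float("inf"), 0.0, degrees_of_freedom=float(x.n + y.n - 2),
            note="degenerate: both samples constant and different",
        )
    t, p = sps.ttest_ind(x.values, y.values, equal_var=False)
    sx2n, sy2n = vx / x.n, vy / y.n
    df = (sx2n + sy2n) ** 2 / (
        sx2n**2 / (x.n - 1) + sy2n**2 / (y.n - 1)
    )
    return TestResult("welch_t", float(t), float(p), degrees_of_freedom=float(df))


def anova_bonferroni(
    groups: Sequence[SampleVector | Sequence[float]],
    comparisons: Sequence[tuple[int, int]] | None = None,
    posthoc: str = "pooled",
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA with Bonferroni-corrected post hoc pairwise t-tests.

    ``comparisons`` lists the group-index pairs to test post hoc (defaults to
    all pairs); the Bonferroni factor is the number of comparisons actually
    requested, ``adjusted_p = min(1, m * p)``. Pairwise tests use the
    classic pooled-variance t-test by default; ``posthoc="welch"`` switches
    to heteroscedastic pairwise tests.
    """
    samples = [_as_sample(g, f"group{i}") for i, g in enumerate(groups)]
    if len(samples) < 3:
        raise ValueError("ANOVA needs at least 3 groups (use welch_t_test for 2)")
    if any(s.n < 2 for s in samples):
        raise ValueError("each group needs at least 2 values")
    f_stat, p = sps.f_oneway(*[s.values for s in samples])
    k = len(samples)
    n_total = sum(s.n for s in samples)
    omnibus = TestResult(
        "anova_oneway", float(f_stat), float(p),
        degrees_of_freedom=float(n_total - k),
    )
    if comparisons is None:
        comparisons = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(comparisons)
    pairwise = []
    for i, j in comparisons:
        if posthoc == "pooled":
            t, pp = sps.ttest_ind(samples[i].values, samples[j].values, equal_var=True)
            res = TestResult(
                f"bonferroni_t[{samples[i].label or i}-{samples[j].label or j}]",
                float(t), float(pp),
                degrees_of_freedom=float(samples[i].n + samples[j].n - 2),
                adjusted_p=min(1.0, m * float(pp)),
            )
        else:
            base = welch_t_test(samples[i], samples[j])
            res = TestResult(
                f"bonferroni_welch[{samples[i].label or i}-{samples[j].label or j}]",
                base.statistic, base.p_value,
                degrees_of_freedom=base.degrees_of_freedom,
                adjusted_p=min(1.0, m * base.p_value),
            )
        pairwise.append(res)
    return omnibus, pairwise


def ks_tail_test(
    x: SampleVector | Sequence[float], y: SampleVector | Sequence[float]
) -> TestResult:
    """One-sided two-sample KS test: does ``x`` have the longer right tail?

    The statistic is ``D+ = sup_t [ECDF_y(t) - ECDF_x(t)]``, which is large
    when ``x`` is stochastically larger than ``y`` (its ECDF lags below).
    The p-value is the standard one-sided asymptotic bound
    ``exp(-2 D+^2 n_x n_y / (n_x + n_y))`` (exact small-sample p-values are
    out of scope and the approximation is labeled as such).
    """
    x, y = _as_sample(x, "x"), _as_sample(y, "y")
    if x.n < 2 or y.n < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x.values, y.values])
    ecdf_x = np.searchsorted(np.sort(x.values), pooled, side="right") / x.n
    ecdf_y = np.searchsorted(np.sort(y.values), pooled, side="right") / y.n
    d_plus = float(np.max(ecdf_y - ecdf_x))
    d_plus = max(d_plus, 0.0)
    ne = x.n * y.n / (x.n + y.n)
    p = float(np.exp(-2.0 * d_plus**2 * ne))
    return TestResult(
        "ks_one_sided", d_plus, min(p, 1.0),
        note="alternative: x stochastically larger (longer right tail); "
        "asymptotic p-value",
    )


def describe(sample: SampleVector | Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator), and SEM = SD/sqrt(n)."""
    s = _as_sample(sample)
    if s.n < 2:
        raise ValueError("need at least 2 values")
    sd = float(s.values.std(ddof=1))
    return float(s.values.mean()), sd, sd / np.sqrt(s.n)
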