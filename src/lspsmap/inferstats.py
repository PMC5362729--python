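"""Inferential statistics for two-genotype map and excitability comparisons.

Welch's unequal-variance t-test (closed-form t, Welch–Satterthwaite df),
two-sample permutation tests (exhaustive on small samples, seeded Monte
Carlo otherwise), two-way ANOVA via a full-factorial linear model
(statsmodels; Type II sums of squares by default for unbalanced data),
and the Šidák multiple-comparison correction used for per-distance-bin
post-tests.  Sample SDs use ddof = 1 throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "welch_t",
    "permutation_test_2sample",
    "anova_two_way",
    "sidak_adjust",
    "per_bin_welch",
]

#: exhaustive enumeration is used when the number of label arrangements
#: is at most this
EXHAUSTIVE_LIMIT = 20000


@dataclass
class TestResult:
    statistic: float
    df: float | tuple | None
    p: float
    method: str
    n_per_group: tuple

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t-test (two-sided).

    t = (ā − b̄)/√(s_a²/n_a + s_b²/n_b) with Welch–Satterthwaite degrees
    of freedom; p from the t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    sa2, sb2 = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2 ** 2 / (na - 1) + sb2 ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(min(p, 1.0)),
                      method="welch-t", n_per_group=(na, nb))


def permutation_test_2sample(a, b, statistic: str = "mean-difference",
                             n_perm: int = 10000, seed: int = 0) -> TestResult:
    """Two-sided two-sample permutation test on the difference of means.

    Exhaustive over all label arrangements when there are at most
    ``EXHAUSTIVE_LIMIT`` of them, otherwise seeded Monte Carlo with the
    add-one correction p = (1 + #{|T*| >= |T|}) / (1 + n_perm).
    """
    if statistic != "mean-difference":
        raise ValueError(f"unsupported statistic {statistic!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = a.size
    pooled = np.concatenate([a, b])
    n = pooled.size
    if n < 2 or na == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    observed = abs(a.mean() - b.mean())
    tol = 1e-12 * max(1.0, abs(observed))
    n_arrangements = math.comb(n, na)
    if n_arrangements <= EXHAUSTIVE_LIMIT:
        count = 0
        total_sum = pooled.sum()
        for idx in itertools.combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            diff = abs(sa / na - (total_sum - sa) / (n - na))
            if diff >= observed - tol:
                count += 1
        p = count / n_arrangements
        method = "permutation-exhaustive"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        total_sum = pooled.sum()
        for _ in range(n_perm):
            perm = rng.permutation(n)
            sa = pooled[perm[:na]].sum()
            diff = abs(sa / na - (total_sum - sa) / (n - na))
            if diff >= observed - tol:
                count += 1
        p = (1 + count) / (1 + n_perm)
        method = "permutation-montecarlo"
    return TestResult(statistic=float(a.mean() - b.mean()), df=None,
                      p=float(p), method=method, n_per_group=(na, b.size))


def anova_two_way(response, factor_A, factor_B, ss_type: int = 2) -> dict:
    """Two-way factorial ANOVA; F and p for both main effects + interaction.

    Least-squares linear model with full factorial encoding via
    statsmodels; Type II sums of squares by default (configurable; Type
    III uses sum-to-zero contrasts).  Every factor cell must be
    non-empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "A": np.asarray(factor_A).astype(str),
        "B": np.asarray(factor_B).astype(str),
    })
    counts = df.groupby(["A", "B"], sort=True).size()
    n_a, n_b = df["A"].nunique(), df["B"].nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("each factor needs >= 2 levels")
    if len(counts) < n_a * n_b:
        raise ValueError("every factor-level cell must be non-empty")
    contrast = "C(A, Sum)*C(B, Sum)" if ss_type == 3 else "C(A)*C(B)"
    model = smf.ols(f"y ~ {contrast}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    rows = [r for r in table.index if r.strip() != "Residual"]
    df_resid = float(table.loc["Residual", "df"])
    out = {}
    for key, row in zip(("A", "B", "interaction"), rows):
        F = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        if not np.isfinite(F):
            F, p = 0.0, 1.0
        out[key] = TestResult(statistic=F,
                              df=(float(table.loc[row, "df"]), df_resid),
                              p=min(p, 1.0) if np.isfinite(p) else 1.0,
                              method=f"anova-typ{ss_type}",
                              n_per_group=(int(n_a), int(n_b)))
    return out


def sidak_adjust(alpha: float, m: int) -> float:
    """Per-comparison alpha for family-wise level ``alpha`` over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def per_bin_welch(values_a, values_b, alpha: float = 0.05) -> pd.DataFrame:
    """Šidák-corrected Welch comparisons of two cohorts, bin by bin.

    ``values_a``/``values_b`` are (n_cells, n_bins) arrays of per-cell
    per-bin values (NaN where a cell does not contribute).  Bins with
    fewer than 2 finite values in either cohort are skipped; the Šidák
    adjustment uses the number of testable bins.  Returns a tidy frame
    with bin, n_a, n_b, statistic, df, p and significant (at the
    adjusted level).
    """
    va = np.atleast_2d(np.asarray(values_a, dtype=float))
    vb = np.atleast_2d(np.asarray(values_b, dtype=float))
    if va.shape[1] != vb.shape[1]:
        raise ValueError("cohorts must share the bin axis")
    rows = []
    for b in range(va.shape[1]):
        xa = va[:, b][np.isfinite(va[:, b])]
        xb = vb[:, b][np.isfinite(vb[:, b])]
        if xa.size >= 2 and xb.size >= 2 and xa.var(ddof=1) + xb.var(ddof=1) > 0:
            res = welch_t(xa, xb)
            rows.append((b, xa.size, xb.size, res.statistic, res.df, res.p))
    out = pd.DataFrame(rows, columns=["bin", "n_a", "n_b", "statistic", "df", "p"])
    m = max(len(out), 1)
    adjusted = sidak_adjust(alpha, m)
    out["alpha_adjusted"] = adjusted
    out["significant"] = out["p"] < adjusted
    return out
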