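"""Statistical tests and effect sizes used across the analyses.

Two-tailed tests throughout: Welch's and paired t (parametric, effect size
Hedges' g), Brunner–Munzel and Wilcoxon signed-rank (non-parametric,
effect size r = |z| / sqrt(n)), a two-sided variance-ratio F test for
comparing tree-length spread between neuron classes, and Holm's step-down
correction for test families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "StatsError",
    "welch_t",
    "paired_t",
    "brunner_munzel",
    "wilcoxon_signed_rank",
    "variance_ratio_test",
    "hedges_g",
    "effect_size_r",
    "holm_adjust",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class StatResult:
    method: str
    statistic: float
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    n: tuple[int, ...] = ()
    df: float | None = None
    p_adjusted: float | None = None

    def adjusted(self, p_adj: float) -> "StatResult":
        return StatResult(
            self.method, self.statistic, self.p, self.effect_size,
            self.effect_size_name, self.n, self.df, p_adj,
        )


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, float).ravel()
    if a.size == 0:
        raise StatsError("empty sample")
    return a


def hedges_g(a, b, paired: bool = False) -> float:
    """Hedges' g: standardized mean difference with small-sample correction
    J = 1 - 3 / (4 N - 9)."""
    a, b = _as1d(a), _as1d(b)
    if paired:
        if len(a) != len(b):
            raise StatsError("paired samples must have equal length")
        diff = a - b
        sd = diff.std(ddof=1)
        n_total = len(a)
        if sd == 0:
            raise StatsError("zero-variance differences: g undefined")
        d = diff.mean() / sd
    else:
        n1, n2 = len(a), len(b)
        sp = np.sqrt(
            ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        )
        n_total = n1 + n2
        if sp == 0:
            return 0.0
        d = (a.mean() - b.mean()) / sp
    j = 1 - 3 / (4 * n_total - 9)
    return float(d * j)


def effect_size_r(z: float, n: int) -> float:
    """Non-parametric effect size r = |z| / sqrt(n)."""
    return float(abs(z) / np.sqrt(n))


def welch_t(a, b) -> StatResult:
    """Welch's t-test (unequal variances, Welch–Satterthwaite df)."""
    a, b = _as1d(a), _as1d(b)
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(
        method="welch_t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_size=hedges_g(a, b),
        effect_size_name="g",
        n=(len(a), len(b)),
        df=float(res.df),
    )


def paired_t(a, b) -> StatResult:
    a, b = _as1d(a), _as1d(b)
    if len(a) != len(b):
        raise StatsError("paired samples must have equal length")
    if (a - b).std(ddof=1) == 0:
        raise StatsError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(a, b)
    return StatResult(
        method="paired_t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_size=hedges_g(a, b, paired=True),
        effect_size_name="g",
        n=(len(a),),
        df=float(len(a) - 1),
    )


def brunner_munzel(a, b) -> StatResult:
    """Brunner–Munzel test with the t-approximation for df."""
    a, b = _as1d(a), _as1d(b)
    res = sps.brunnermunzel(a, b, distribution="t")
    stat = float(res.statistic)
    n = len(a) + len(b)
    return StatResult(
        method="brunner_munzel",
        statistic=stat,
        p=float(res.pvalue),
        effect_size=effect_size_r(stat, n),
        effect_size_name="r",
        n=(len(a), len(b)),
    )


def wilcoxon_signed_rank(a, b) -> StatResult:
    """Wilcoxon signed-rank test; exact p for n <= 25, else normal approx."""
    a, b = _as1d(a), _as1d(b)
    if len(a) != len(b):
        raise StatsError("paired samples must have equal length")
    n = len(a)
    mode = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(a, b, method=mode)
    # z from the normal approximation drives the effect size
    d = a - b
    d = d[d != 0]
    nz = len(d)
    if nz == 0:
        raise StatsError("all differences zero: test undefined")
    mu = nz * (nz + 1) / 4
    sigma = np.sqrt(nz * (nz + 1) * (2 * nz + 1) / 24)
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    return StatResult(
        method="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_size=effect_size_r(z, n),
        effect_size_name="r",
        n=(n,),
    )


def variance_ratio_test(
    a=None, b=None, *,
    a_sd: float | None = None, n_a: int | None = None,
    b_sd: float | None = None, n_b: int | None = None,
) -> StatResult:
    """Two-sided variance-ratio F test, from raw samples or summary SDs.

    F is the larger sample variance over the smaller, referred to
    F(df_larger, df_smaller); p is the doubled upper tail (capped at 1).
    Symmetric in its arguments.
    """
    if a is not None and b is not None:
        a, b = _as1d(a), _as1d(b)
        a_sd, n_a = float(a.std(ddof=1)), len(a)
        b_sd, n_b = float(b.std(ddof=1)), len(b)
    if None in (a_sd, n_a, b_sd, n_b):
        raise StatsError("provide raw samples or all of a_sd, n_a, b_sd, n_b")
    v1, v2 = a_sd**2, b_sd**2
    if v1 >= v2:
        f, dfn, dfd = (v1 / v2 if v2 > 0 else np.inf), n_a - 1, n_b - 1
    else:
        f, dfn, dfd = v2 / v1, n_b - 1, n_a - 1
    p = min(1.0, 2 * float(sps.f.sf(f, dfn, dfd)))
    return StatResult(
        method="variance_ratio_F",
        statistic=float(f),
        p=p,
        effect_size=float(f),
        effect_size_name="F",
        n=(n_a, n_b),
        df=float(dfn),
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm's step-down adjusted p-values with monotonicity enforcement.

    p_(i) is multiplied by (m - i + 1) in ascending order; running maxima
    keep the adjusted sequence non-decreasing in rank; values cap at 1.
    """
    p = _as1d(pvalues)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * p[i])
        running = max(running, val)
        adj[i] = running
    return adj
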