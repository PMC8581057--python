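"""Two-group statistics: pseudocount fold changes, exact window tests,
a replicate-aware negative-binomial gene test, BH adjustment and the
two-group Student t comparison used for signal intensities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

#: pseudocount added to both group means before taking a ratio, in the
#: normalized unit of the means; avoids division by zero for OFF states
DEFAULT_PSEUDOCOUNT = 0.5

#: relative tolerance for tie detection in the two-sided Fisher p
_FISHER_TIE_RTOL = 1e-12

#: below this table total the Fisher p is computed in exact integer
#: arithmetic; above it, via log-gamma in floating point
_FISHER_EXACT_MAX_N = 500


@dataclass
class DiffResult:
    """Per-feature two-group comparison summary."""

    feature_id: str
    mean_a: float
    mean_b: float
    fc: float
    p: float
    padj: float | None = None


def fold_change(mean_a, mean_b, eps: float = DEFAULT_PSEUDOCOUNT):
    """Pseudocount fold change ``(mean_a + eps) / (mean_b + eps)``."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("means must be non-negative")
    return (a + eps) / (b + eps)


def _fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    # numerator of P(X=k) is C(r1, k) * C(r2, col1 - k); the denominator
    # C(N, col1) is shared, so tables compare by exact integer numerators
    r1, r2 = a + b, c + d
    col1 = a + c
    lo, hi = max(0, col1 - r2), min(col1, r1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(lo, hi + 1):
        num = math.comb(r1, k) * math.comb(r2, col1 - k)
        if num <= obs:
            total += num
    return min(1.0, total / math.comb(r1 + r2, col1))


def _fisher_two_sided_lgamma(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    n = r1 + r2
    col1 = a + c
    lo, hi = max(0, col1 - r2), min(col1, r1)
    k = np.arange(lo, hi + 1)

    def logc(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logp = logc(r1, k) + logc(r2, col1 - k) - logc(n, col1)
    pmf = np.exp(logp)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_RTOL)].sum()))


def fisher_window_test(win_a: int, rest_a: int, win_b: int, rest_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table ``[[win_a, rest_a], [win_b, rest_b]]``.

    The two-sided p sums the probabilities of all tables (at fixed margins)
    whose hypergeometric probability is <= that of the observed table; ties
    are included.  A zero margin makes every table equally likely, so p = 1
    by convention.
    """
    table = (win_a, rest_a, win_b, rest_b)
    if any(x < 0 for x in table):
        raise ValueError("counts must be non-negative")
    a, b, c, d = (int(x) for x in table)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    if a + b + c + d <= _FISHER_EXACT_MAX_N:
        return _fisher_two_sided_exact(a, b, c, d)
    return _fisher_two_sided_lgamma(a, b, c, d)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_gene_test(
    counts_a,
    counts_b,
    sizes_a,
    sizes_b,
    eps: float = DEFAULT_PSEUDOCOUNT,
    fallback_dispersion: float = 0.1,
):
    """Replicate-aware two-group test on negative-binomial counts.

    Counts are scaled to a common depth (the mean library size), a per-gene
    NB dispersion (``var = mu + phi * mu^2``) is estimated by method of
    moments pooled over the two groups and floored at 1e-8, and the log
    fold change is tested with a Wald statistic using the NB variance of
    each group mean.  The statistic is referred to a Student t distribution
    with ``n_a + n_b - 2`` degrees of freedom, which calibrates the test at
    the few-replicate sizes this assay produces.  With a single replicate
    in every group there is no residual degree of freedom and
    ``fallback_dispersion`` is used.

    Accepts 1-D arrays (one gene) or 2-D arrays of shape (genes, replicates);
    returns ``(fc, p)`` with shapes matching the input.
    """
    ca = np.atleast_2d(np.asarray(counts_a, dtype=float))
    cb = np.atleast_2d(np.asarray(counts_b, dtype=float))
    sa = np.asarray(sizes_a, dtype=float)
    sb = np.asarray(sizes_b, dtype=float)
    if ca.shape[1] == 0 or cb.shape[1] == 0:
        raise ValueError("empty replicate group")
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("library sizes must be > 0")
    n_a, n_b = ca.shape[1], cb.shape[1]
    ref = np.concatenate([sa, sb]).mean()
    xa = ca * (ref / sa)
    xb = cb * (ref / sb)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)

    df = n_a + n_b - 2
    if df > 0:
        va = xa.var(axis=1, ddof=1) if n_a > 1 else np.zeros_like(ma)
        vb = xb.var(axis=1, ddof=1) if n_b > 1 else np.zeros_like(mb)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_a = np.where(ma > 0, (va - ma) / np.maximum(ma, 1e-300) ** 2, 0.0)
            phi_b = np.where(mb > 0, (vb - mb) / np.maximum(mb, 1e-300) ** 2, 0.0)
        phi = ((n_a - 1) * phi_a + (n_b - 1) * phi_b) / df
    else:
        phi = np.full_like(ma, fallback_dispersion)
    phi = np.maximum(phi, 1e-8)

    var_ma = (ma + phi * ma**2) / n_a
    var_mb = (mb + phi * mb**2) / n_b
    fc = (ma + eps) / (mb + eps)
    se = np.sqrt(var_ma / (ma + eps) ** 2 + var_mb / (mb + eps) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, np.log(fc) / np.where(se > 0, se, 1.0), 0.0)
    if df > 0:
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    # degenerate: no reads and no variance in either group
    p = np.where((se == 0) & (ma == mb), 1.0, p)
    if np.asarray(counts_a).ndim == 1:
        return float(fc[0]), float(p[0])
    return fc, p


def gene_diff_table(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    eps: float = DEFAULT_PSEUDOCOUNT,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene NB test of ``group_a`` vs ``group_b`` with BH adjustment.

    Samples are depth-normalized with median-of-ratios size factors
    (robust to composition shifts like the transcriptional burst at
    embryonic genome activation; library-size ratios as fallback).
    Returns a DataFrame indexed by feature with ``mean_a``, ``mean_b``
    (normalized means), ``fc``, ``p`` and ``padj``.
    """
    from .quantify import size_factors

    ids_a = matrix.samples_in_group(group_a)
    ids_b = matrix.samples_in_group(group_b)
    sub = matrix.counts[ids_a + ids_b]
    sf = size_factors(
        sub,
        matrix.samples.loc[ids_a + ids_b, "library_size"].to_numpy(float),
    )
    ca = matrix.counts[ids_a].to_numpy(float)
    cb = matrix.counts[ids_b].to_numpy(float)
    sa = sf[: len(ids_a)]
    sb = sf[len(ids_a):]
    fc, p = nb_gene_test(ca, cb, sa, sb, eps=eps)
    ref = np.concatenate([sa, sb]).mean()
    out = pd.DataFrame(
        {
            "mean_a": (ca * (ref / sa)).mean(axis=1),
            "mean_b": (cb * (ref / sb)).mean(axis=1),
            "fc": fc,
            "p": p,
        },
        index=matrix.feature_ids,
    )
    out["padj"] = bh_adjust(out["p"].to_numpy()) if adjust else out["p"]
    return out


def window_diff_table(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    eps: float = DEFAULT_PSEUDOCOUNT,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-window Fisher exact test on replicate-pooled counts.

    Window counts are pooled across replicates within each group and tested
    against the rest of the library (library size minus window count) with
    the two-sided Fisher exact test.  Means and FC are in RPM.  Fisher
    p-values are reported unadjusted by default (BH optional).
    """
    pooled_a, size_a = matrix.pooled(group_a)
    pooled_b, size_b = matrix.pooled(group_b)
    mean_a = pooled_a.to_numpy(float) * 1e6 / size_a
    mean_b = pooled_b.to_numpy(float) * 1e6 / size_b
    p = np.array(
        [
            fisher_window_test(int(wa), int(size_a - wa), int(wb), int(size_b - wb))
            for wa, wb in zip(pooled_a.to_numpy(), pooled_b.to_numpy())
        ]
    )
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fold_change(mean_a, mean_b, eps),
            "p": p,
        },
        index=matrix.feature_ids,
    )
    out["padj"] = bh_adjust(p) if adjust else p
    return out


def two_group_t(values_a, values_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed Student t test (pooled variance by default, Welch optional).

    Degenerate zero-variance input follows the convention: equal means give
    (0, 1); unequal means give (+/-inf, 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (math.inf if a.mean() > b.mean() else -math.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Significance stars at the conventional 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
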