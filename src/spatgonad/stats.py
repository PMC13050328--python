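"""Shared statistical kernels: rank-sum test, BH adjustment, significance stars.

These are the primitives the marker detection and depth-by-stage comparisons
are built on. The rank-sum test is exact (full null enumeration) for small
samples without ties and uses the tie-corrected normal approximation
otherwise; the continuity correction is disabled so that perfectly
exchangeable inputs (x identical to y) yield p = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["RankSumResult", "ranksum", "bh_adjust", "star_annotation"]

#: exact enumeration is used when the pooled sample is at most this large
EXACT_MAX_N = 20


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test result.

    Attributes
    ----------
    u : float
        Mann-Whitney U statistic of the first sample.
    n1, n2 : int
        Group sizes.
    z : float
        Tie-corrected normal deviate (NaN when the exact method was used).
    p_value : float
        Two-sided p-value, in (0, 1].
    method : str
        ``"exact"`` or ``"normal"``.
    """

    u: float
    n1: int
    n2: int
    z: float
    p_value: float
    method: str


def ranksum(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum test of two independent samples.

    Two-sided by default; ``alternative`` may be ``"greater"`` or
    ``"less"`` where a direction is hypothesized. Exact null distribution
    when ``len(x) + len(y) <= 20`` and there are no tied values across the
    pooled sample; tie-corrected normal approximation otherwise.

    Raises
    ------
    ValueError
        If either sample is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ranksum requires non-empty samples in both groups")

    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= EXACT_MAX_N and no_ties:
        res = _sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        z = float("nan")
        method = "exact"
    else:
        res = _sps.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic",
            use_continuity=False,
        )
        n1, n2 = x.size, y.size
        mu = n1 * n2 / 2.0
        # tie-corrected variance, mirroring the asymptotic path
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        z = (float(res.statistic) - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
        method = "normal"
    p = min(float(res.pvalue), 1.0)
    return RankSumResult(
        u=float(res.statistic), n1=int(x.size), n2=int(y.size),
        z=z, p_value=p, method=method,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Standard step-up adjustment with running minimum, clipped at 1.

    Raises
    ------
    ValueError
        If any p lies outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def star_annotation(adjp: float) -> str:
    """Significance tier for an adjusted p-value.

    ``"****"`` below 1e-4, ``"***"`` below 1e-3, ``"**"`` below 1e-2,
    ``"*"`` below 0.05, ``"ns"`` at or above 0.05.
    """
    if not 0 <= adjp <= 1:
        raise ValueError(f"adjusted p-value out of [0, 1]: {adjp}")
    if adjp < 1e-4:
        return "****"
    if adjp < 1e-3:
        return "***"
    if adjp < 1e-2:
        return "**"
    if adjp < 0.05:
        return "*"
    return "ns"
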