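"""Shared statistical primitives with fixed, deterministic policies."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats


def two_sample_rank_test(x: Sequence[float], y: Sequence[float], exact_max_n: int = 50) -> float:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney) p-value.

    Policy: exact null distribution when both groups have at most
    ``exact_max_n`` observations and the pooled sample is tie-free; otherwise
    the continuity-corrected normal approximation with midrank ties.  The
    policy is a function of the data only, so results are deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (max(x.size, y.size) <= exact_max_n) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
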