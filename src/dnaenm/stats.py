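"""Profile correlation with a one-pass outlier-exclusion rule.

Experimental temperature-factor profiles occasionally contain unnaturally
large or small entries.  Before correlating two profiles, entries deviating
from their own series mean by more than ``s`` standard deviations (default
s = 2.5, population normalization) are excluded; the exclusion set is the
union over both series so the profiles stay index-aligned.  The rule is
applied once, without iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .constants import DEFAULT_OUTLIER_SIGMA


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n_used: int
    n_excluded: int
    excluded: tuple[int, ...]


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    return x


def pearson(x, y) -> float:
    """Plain product-moment (Pearson) correlation coefficient."""
    x, y = _as_series(x), _as_series(y)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input series")
    return float(_scipy_stats.pearsonr(x, y).statistic)


def outlier_mask(x, s: float = DEFAULT_OUTLIER_SIGMA) -> np.ndarray:
    """Boolean mask of entries with |x - mean| > s * (population) std."""
    x = np.asarray(x, dtype=float).ravel()
    mu = x.mean()
    sigma = x.std()  # population (1/N) normalization
    if sigma == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - mu) > s * sigma


def robust_pearson(x, y, s: float = DEFAULT_OUTLIER_SIGMA) -> CorrelationResult:
    """Pearson correlation after one-pass union outlier exclusion."""
    x, y = _as_series(x), _as_series(y)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    bad = outlier_mask(x, s) | outlier_mask(y, s)
    keep = ~bad
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points remain after outlier exclusion")
    rho = pearson(x[keep], y[keep])
    return CorrelationResult(
        rho=rho,
        n_used=int(keep.sum()),
        n_excluded=int(bad.sum()),
        excluded=tuple(int(i) for i in np.flatnonzero(bad)),
    )
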