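"""Robust monotonic trend detection for annual city-level series.

Theil-Sen slope (median of all pairwise slopes) quantifies the trend
magnitude; the Mann-Kendall S statistic with tie-corrected variance and
continuity correction gives a two-sided normal p-value. Trends are then
binned into four qualitative classes by sign and significance at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

CLASSES = ("sig_increase", "insig_increase", "insig_decrease", "sig_decrease")


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    mk_s: int
    mk_var: float
    z: float
    p: float
    significant: bool
    klass: str


def theil_sen(years, values) -> tuple[float, float]:
    """Median pairwise slope and the median-residual intercept.

    Even pair counts use the midpoint of the two central order statistics
    (numpy's median). Duplicate years are rejected.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 2:
        raise ValueError("need matching 1-D arrays with at least 2 points")
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate years in series")
    i, j = np.triu_indices(len(t), k=1)
    slopes = (y[j] - y[i]) / (t[j] - t[i])
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * t))
    return slope, intercept


def mann_kendall(
    values, tie_correction: bool = True, continuity: bool = True
) -> tuple[int, float, float, float]:
    """Mann-Kendall test: returns (S, var(S), z, two-sided p).

    S = sum over i < j of sign(y_j - y_i); the variance uses the standard
    tie correction; z applies the +-1 continuity correction (z = 0 when
    S = 0). Requires n >= 4 for the normal approximation.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("Mann-Kendall needs n >= 4")
    i, j = np.triu_indices(n, k=1)
    s = int(np.sign(y[j] - y[i]).sum())
    var = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_correction:
        _, counts = np.unique(y, return_counts=True)
        ties = counts[counts > 1]
        var -= np.sum(ties * (ties - 1) * (2 * ties + 5)) / 18.0
    if var <= 0:  # fully tied series
        return s, 0.0, 0.0, 1.0
    shift = (1.0 if continuity else 0.0) * np.sign(s)
    z = 0.0 if s == 0 else (s - shift) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return s, float(var), float(z), min(p, 1.0)


def classify_trend(slope: float, p: float, alpha: float = 0.05) -> str:
    """Four-level qualitative class; slope 0 goes to the increase branch."""
    sig = p < alpha
    if slope >= 0:
        return "sig_increase" if sig else "insig_increase"
    return "sig_decrease" if sig else "insig_decrease"


def analyze_series(years, values, alpha: float = 0.05) -> TrendResult:
    """Theil-Sen + Mann-Kendall + qualitative class for one annual series."""
    slope, intercept = theil_sen(years, values)
    s, var, z, p = mann_kendall(values)
    return TrendResult(
        slope=slope,
        intercept=intercept,
        mk_s=s,
        mk_var=var,
        z=z,
        p=p,
        significant=p < alpha,
        klass=classify_trend(slope, p, alpha),
    )
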