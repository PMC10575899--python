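"""Population-weighted inequality indices over exposure distributions.

The normative Gini definition is the pairwise form
G = sum_ij w_i w_j |x_i - x_j| / (2 W^2 mu); the implementation uses the
equivalent sorted-Lorenz O(n log n) form. Atkinson is one minus the ratio
of the weighted generalized mean of order 1 - epsilon to the arithmetic
mean (geometric-mean limit at epsilon = 1). Theil is the weighted Theil-T
entropy index, optionally normalized to [0, 1] by ln of the number of
units so it shares the 0-1 range of the other two indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exposure import ExposureDistribution


@dataclass(frozen=True)
class InequalityResult:
    metric: str
    value: float
    params: dict = field(default_factory=dict)


def _unpack(dist) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dist, ExposureDistribution):
        return dist.values, dist.weights
    x, w = dist
    return np.asarray(x, dtype=float), np.asarray(w, dtype=float)


def weighted_gini(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Gini via the sorted-Lorenz form (exact, O(n log n))."""
    order = np.argsort(values, kind="stable")
    x = values[order]
    w = weights[order]
    W = w.sum()
    wx = w * x
    total = wx.sum()
    if total <= 0:
        raise ValueError("Gini undefined: weighted mean is not positive")
    cw = np.cumsum(w) - w  # sum of weights strictly below each rank
    cwx = np.cumsum(wx) - wx
    # sum_{i<j} w_i w_j (x_j - x_i), ascending order
    pair_sum = np.sum(w * (x * cw - cwx))
    return max(float(2.0 * pair_sum / (2.0 * W * total)), 0.0)  # clamp round-off


def gini(dist) -> InequalityResult:
    x, w = _unpack(dist)
    if np.any(x < 0):
        raise ValueError("Gini requires nonnegative values")
    return InequalityResult("gini", weighted_gini(x, w))


def atkinson(dist, epsilon: float = 0.5) -> InequalityResult:
    """Atkinson index with inequality aversion epsilon > 0."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x, w = _unpack(dist)
    W = w.sum()
    mu = (w * x).sum() / W
    if mu <= 0:
        raise ValueError("Atkinson undefined: weighted mean is not positive")
    if epsilon >= 1 and np.any(x <= 0):
        raise ValueError("Atkinson with epsilon >= 1 requires strictly positive values")
    if np.any(x < 0):
        raise ValueError("Atkinson requires nonnegative values")
    p = w / W
    if epsilon == 1.0:
        ede = np.exp(np.sum(p * np.log(x)))
    else:
        e = 1.0 - epsilon
        ede = np.sum(p * x**e) ** (1.0 / e)
    value = max(float(1.0 - ede / mu), 0.0)  # clamp round-off
    return InequalityResult("atkinson", value, {"epsilon": epsilon})


def theil(dist, normalized: bool = True, norm_basis: str = "pixels") -> InequalityResult:
    """Weighted Theil-T index; optionally normalized by ln(number of units).

    ``norm_basis`` chooses the unit count for normalization: "pixels"
    (number of weighted records, default) or "persons" (total weight).
    """
    x, w = _unpack(dist)
    if np.any(x <= 0):
        raise ValueError("Theil requires strictly positive values")
    W = w.sum()
    mu = (w * x).sum() / W
    r = x / mu
    t = float(np.sum((w / W) * r * np.log(r)))
    params = {"normalized": normalized, "norm_basis": norm_basis}
    if not normalized:
        return InequalityResult("theil", t, params)
    n_units = float(len(x)) if norm_basis == "pixels" else float(W)
    if n_units <= 1:
        value = 0.0 if t == 0 else float("nan")
    else:
        value = t / np.log(n_units)
    return InequalityResult("theil", float(value), params)


METRICS = {"gini": gini, "atkinson": atkinson, "theil": theil}


def compute_metric(dist, metric: str, **params) -> InequalityResult:
    try:
        fn = METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown inequality metric '{metric}'") from None
    return fn(dist, **params)
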