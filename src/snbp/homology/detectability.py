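"""Detectability of homologs: exponential bit-score decay with distance.

Mirrors the abSENSE idea: expected bit score a*exp(-b*d), Gaussian
residual spread sigma, and the probability that a true homolog at distance
d scores below the detection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DetectabilityModel:
    a: float  # expected bit score at distance 0 (> 0)
    b: float  # exponential decay rate (>= 0)
    sigma: float  # residual spread (>= 0)
    threshold: float  # detection bit-score threshold

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def predict(self, distance: float) -> float:
        return self.a * np.exp(-self.b * distance)


def fit_detectability(
    pairs: list[tuple[float, float]], threshold: float = 10.0
) -> DetectabilityModel:
    """Fit ln(score) = ln(a) - b*d by least squares; sigma from residuals.

    Requires >= 3 pairs with distinct distances and positive scores. A
    negative fitted decay is clamped to zero with a warning.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 (distance, bitscore) pairs")
    d = np.array([p[0] for p in pairs], dtype=float)
    s = np.array([p[1] for p in pairs], dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct distances")
    if (s <= 0).any():
        raise ValueError("bit scores must be > 0")
    slope, intercept = np.polyfit(d, np.log(s), deg=1)
    b = -float(slope)
    a = float(np.exp(intercept))
    if b < 0:
        warnings.warn("fitted decay rate was negative; clamped to 0")
        b = 0.0
        a = float(np.exp(np.mean(np.log(s))))
    residuals = s - a * np.exp(-b * d)
    sigma = float(np.sqrt(np.mean(residuals**2)))
    return DetectabilityModel(a=a, b=b, sigma=sigma, threshold=threshold)


def prob_undetected(model: DetectabilityModel, distance: float) -> float:
    """P(bit score < threshold) at ``distance``; non-decreasing in distance."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    predicted = model.predict(distance)
    if model.sigma == 0:
        return 0.0 if predicted > model.threshold else 1.0
    p = stats.norm.cdf((model.threshold - predicted) / model.sigma)
    return float(min(max(p, 0.0), 1.0))
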