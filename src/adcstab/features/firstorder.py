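"""First-order (intensity histogram) features.

All 18 features follow the standard reference definitions: population
(1/n) moments, non-excess kurtosis, and histogram entropy/uniformity on the
fixed-bin-width discretized values.
"""

from __future__ import annotations

import numpy as np

from .config import ExtractionConfig, discretize

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order(
    values: np.ndarray,
    pixel_area: float,
    config: ExtractionConfig,
) -> dict[str, float]:
    """Compute the 18 first-order features of a 1D intensity sample.

    ``pixel_area`` (mm^2) enters only TotalEnergy.  Skewness and Kurtosis of
    a zero-variance sample are undefined and returned as NaN.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("first_order requires at least one value")

    levels = discretize(x, config)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / x.size

    mean = x.mean()
    m2 = np.mean((x - mean) ** 2)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else np.nan

    if m2 > 0:
        skewness = np.mean((x - mean) ** 3) / m2**1.5
        kurtosis = np.mean((x - mean) ** 4) / m2**2
    else:
        skewness = np.nan
        kurtosis = np.nan

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": pixel_area * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skewness),
        "Kurtosis": float(kurtosis),
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
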