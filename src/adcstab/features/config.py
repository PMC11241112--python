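"""Extraction settings and gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..adc import DEFAULT_ADC_RANGE


@dataclass
class ExtractionConfig:
    """Settings for radiomic feature extraction from an ADC map.

    ``bin_width`` (um^2/ms) controls fixed-bin-width discretization anchored
    at ``bin_anchor``; the default 0.025 yields roughly 40-140 gray levels on
    breast ADC values, within the commonly recommended range.  Texture
    matrices use in-plane distance ``glcm_distance`` and, where directional,
    features are computed per angle and averaged.
    """

    bin_width: float = 0.025
    bin_anchor: float = 0.0
    glcm_distance: int = 1
    average_per_angle: bool = True
    adc_range: tuple[float, float] = DEFAULT_ADC_RANGE
    gldm_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")


def discretize(values: np.ndarray, config: ExtractionConfig) -> np.ndarray:
    """Map ADC values to integer gray levels >= 1.

    level = floor((v - anchor) / bin_width) + 1.  With the default anchor 0
    this ties level boundaries to absolute ADC values, so the same ADC always
    lands in the same bin regardless of the segmentation under study.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty sample")
    levels = np.floor((values - config.bin_anchor) / config.bin_width).astype(np.int64) + 1
    if (levels < 1).any():
        raise ValueError("values below the bin anchor cannot be discretized")
    return levels
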