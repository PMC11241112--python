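"""Apparent diffusion coefficient (ADC) mapping from a pair of b-value images.

The ADC map is computed from the mono-exponential decay between two
diffusion weightings (here b=50 and b=750 s/mm^2).  Internally ADC is
carried in um^2/ms (= 1e-3 mm^2/s), the unit in which breast-tissue values
and the fit-outlier cutoff of 3.5 um^2/ms are conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default fit-outlier range in um^2/ms; the upper bound sits just above the
#: ADC of free water at body temperature (~3.25 um^2/ms).
DEFAULT_ADC_RANGE = (0.0, 3.5)


@dataclass
class ADCMap:
    """A 2D ADC map with a per-pixel validity mask.

    ``values`` holds ADC in um^2/ms; pixels where the fit is undefined
    (non-positive signal) or outside the accepted physiological range carry
    ``valid == False``.  Values are never modified by filtering, only the
    validity mask changes.
    """

    values: np.ndarray
    valid: np.ndarray
    b_pair: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")


def compute_adc(
    img_low: np.ndarray,
    b_low: float,
    img_high: np.ndarray,
    b_high: float,
) -> ADCMap:
    """Fit the two-point mono-exponential ADC per pixel.

    ADC = ln(S_low / S_high) / (b_high - b_low), converted to um^2/ms.
    Pixels with non-positive signal in either image are marked invalid and
    set to NaN; all other pixels are valid at this stage (range filtering is
    a separate step).
    """
    img_low = np.asarray(img_low, dtype=float)
    img_high = np.asarray(img_high, dtype=float)
    if img_low.shape != img_high.shape:
        raise ValueError("b-value images must have the same shape")
    if not b_high > b_low >= 0:
        raise ValueError("require b_high > b_low >= 0")

    valid = (img_low > 0) & (img_high > 0)
    values = np.full(img_low.shape, np.nan, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(img_low[valid] / img_high[valid])
    # mm^2/s -> um^2/ms is a factor 1e3
    values[valid] = ratio / (b_high - b_low) * 1e3
    valid = valid & np.isfinite(values)
    return ADCMap(values=values, valid=valid, b_pair=(float(b_low), float(b_high)))


def apply_range_filter(
    adc: ADCMap,
    low: float = DEFAULT_ADC_RANGE[0],
    high: float = DEFAULT_ADC_RANGE[1],
) -> ADCMap:
    """Invalidate fit outliers outside [low, high] um^2/ms (bounds inclusive).

    Idempotent; returns a new map sharing the value array.
    """
    if not low < high:
        raise ValueError("require low < high")
    in_range = (adc.values >= low) & (adc.values <= high)
    # NaN compares False, so undefined pixels stay invalid
    return ADCMap(values=adc.values, valid=adc.valid & in_range, b_pair=adc.b_pair)
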