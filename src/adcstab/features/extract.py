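"""Full feature extraction for one lesion/segmentation combination."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..adc import ADCMap
from ..segmentation import SegmentationMask
from .config import ExtractionConfig, discretize
from .firstorder import FIRSTORDER_NAMES, first_order
from .shape2d import SHAPE2D_NAMES, shape2d
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "shape2D": SHAPE2D_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

#: all 102 feature names in canonical order, as "<class>_<name>"
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{cls}_{name}" for cls, names in FEATURE_CLASSES.items() for name in names
)

N_FEATURES = len(FEATURE_NAMES)  # 102


class ExtractionError(ValueError):
    """Raised when a lesion/variant yields no extractable pixels."""


@dataclass
class FeatureVector:
    """The 102 features of one lesion under one segmentation variant.

    ``values`` is keyed by ``<class>_<name>``; degenerate (undefined)
    features hold NaN and are listed in ``degenerate``.
    """

    values: dict[str, float]
    case_id: str = ""
    variant_label: str = ""
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError(
                f"feature vector must hold exactly the {N_FEATURES} canonical features"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def extract_all(
    adc: ADCMap,
    mask: SegmentationMask,
    pixel_spacing: float,
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Extract all 102 features from an ADC map restricted to a mask.

    The mask is first intersected with the ADC validity mask and the
    accepted ADC range (fit-outlier removal), so shape features too are
    measured on the pixels that actually enter the intensity statistics.
    """
    config = config or ExtractionConfig()
    lo, hi = config.adc_range
    with np.errstate(invalid="ignore"):
        in_range = (adc.values >= lo) & (adc.values <= hi)
    eff = mask.mask & adc.valid & in_range
    if not eff.any():
        raise ExtractionError(
            f"no valid ADC pixels in mask (case {mask.case_id!r}, "
            f"variant {mask.variant_label!r})"
        )

    values = adc.values[eff]
    levels_img = np.zeros(eff.shape, dtype=np.int64)
    levels_img[eff] = discretize(values, config)

    pixel_area = pixel_spacing**2
    out: dict[str, float] = {}
    for name, v in first_order(values, pixel_area, config).items():
        out[f"firstorder_{name}"] = v
    for name, v in shape2d(eff, pixel_spacing).items():
        out[f"shape2D_{name}"] = v
    for cls, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("gldm", gldm_features),
        ("ngtdm", ngtdm_features),
    ):
        for name, v in fn(levels_img, config).items():
            out[f"{cls}_{name}"] = v

    ordered = {name: out[name] for name in FEATURE_NAMES}
    degenerate = tuple(
        name for name, v in ordered.items() if not math.isfinite(v)
    )
    return FeatureVector(
        values=ordered,
        case_id=mask.case_id,
        variant_label=mask.variant_label,
        degenerate=degenerate,
    )


def feature_class(full_name: str) -> str:
    return full_name.split("_", 1)[0]


def vectors_to_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Long-format feature table: case_id, variant_label, class, feature, value."""
    records = []
    for fv in vectors:
        for name, value in fv.values.items():
            cls, short = name.split("_", 1)
            records.append(
                {
                    "case_id": fv.case_id,
                    "variant_label": fv.variant_label,
                    "class": cls,
                    "feature": name,
                    "value": value,
                }
            )
    return pd.DataFrame.from_records(records)
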