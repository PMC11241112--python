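"""Otsu-threshold lesion segmentation and the nine-variant perturbation engine.

A lesion is segmented inside a rough manual delineation by thresholding the
high-b-value image at Otsu's discriminant-criterion optimum.  Two families
of perturbed segmentations probe feature stability:

* resizing — the threshold is scaled to 80/90/110/120 % of the Otsu value,
  growing or shrinking the mask;
* shifting — the original mask is translated by one pixel in each in-plane
  direction.

Together with the original this yields nine segmentations per lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RESIZE_FACTORS = (0.8, 0.9, 1.1, 1.2)

#: canonical variant labels, in canonical order
VARIANT_LABELS = (
    "original",
    "th80",
    "th90",
    "th110",
    "th120",
    "shift+x",
    "shift-x",
    "shift+y",
    "shift-y",
)
RESIZE_LABELS = ("original", "th80", "th90", "th110", "th120")
SHIFT_LABELS = ("original", "shift+x", "shift-x", "shift+y", "shift-y")

# x runs along columns (axis 1), y along rows (axis 0)
_SHIFT_OFFSETS = {
    "shift+x": (0, 1),
    "shift-x": (0, -1),
    "shift+y": (1, 0),
    "shift-y": (-1, 0),
}


class SegmentationError(ValueError):
    """Raised when a lesion cannot be segmented (empty mask, off-image shift...)."""


@dataclass
class SegmentationMask:
    mask: np.ndarray
    variant_label: str
    source_threshold: float
    case_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 1:
            raise SegmentationError(
                f"empty segmentation mask (variant {self.variant_label!r})"
            )

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentationVariantSet:
    variants: dict[str, SegmentationMask] = field(default_factory=dict)
    case_id: str = ""

    def __post_init__(self) -> None:
        missing = set(VARIANT_LABELS) - set(self.variants)
        extra = set(self.variants) - set(VARIANT_LABELS)
        if missing or extra:
            raise ValueError(f"variant set must hold exactly {VARIANT_LABELS}")

    def __getitem__(self, label: str) -> SegmentationMask:
        return self.variants[label]


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's discriminant-criterion threshold for a 1D intensity sample.

    Candidate thresholds are the interior edges of an ``nbins``-bin histogram
    spanning [min, max] of the sample.  For each candidate t the sample is
    split into classes {v <= t} and {v > t} and the between-class variance
    w0*w1*(mu0 - mu1)^2 is evaluated on the actual values; the lowest
    maximizing edge is returned (deterministic tie-break).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.all(values == values[0]):
        raise SegmentationError("Otsu threshold undefined: no separable classes")
    lo, hi = float(values.min()), float(values.max())
    edges = np.linspace(lo, hi, nbins + 1)[1:-1]

    order = np.sort(values)
    n = order.size
    csum = np.cumsum(order)
    # n0[t] = number of values <= edge t
    n0 = np.searchsorted(order, edges, side="right")
    keep = (n0 > 0) & (n0 < n)
    if not keep.any():  # pragma: no cover - excluded by the distinctness check
        raise SegmentationError("Otsu threshold undefined: no separable classes")
    n0 = n0[keep]
    edges = edges[keep]
    mu0 = csum[n0 - 1] / n0
    mu1 = (csum[-1] - csum[n0 - 1]) / (n - n0)
    w0 = n0 / n
    sigma_b = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    return float(edges[int(np.argmax(sigma_b))])


def segment(
    image: np.ndarray,
    delineation: np.ndarray,
    threshold: float,
    variant_label: str = "original",
    case_id: str = "",
) -> SegmentationMask:
    """Keep all delineated pixels strictly above the threshold.

    Pixels equal to the threshold are excluded.  No connected-component
    filtering is applied.  An empty result raises :class:`SegmentationError`.
    """
    image = np.asarray(image, dtype=float)
    delineation = np.asarray(delineation, dtype=bool)
    if not delineation.any():
        raise SegmentationError("empty delineation")
    mask = (image > threshold) & delineation
    if not mask.any():
        raise SegmentationError(
            f"threshold {threshold:g} leaves no pixels (variant {variant_label!r})"
        )
    return SegmentationMask(mask, variant_label, float(threshold), case_id)


def resize_variants(
    image: np.ndarray,
    delineation: np.ndarray,
    base_threshold: float,
    factors: tuple[float, ...] = RESIZE_FACTORS,
    case_id: str = "",
) -> list[SegmentationMask]:
    """Re-segment at scaled thresholds; lower factors give superset masks."""
    if any(f <= 0 for f in factors):
        raise ValueError("resize factors must be positive")
    out = []
    for f in factors:
        label = f"th{round(f * 100):d}"
        out.append(segment(image, delineation, f * base_threshold, label, case_id))
    return out


def shift_variants(mask: SegmentationMask) -> list[SegmentationMask]:
    """Translate the mask by one pixel along +-x and +-y.

    Pure translations: pixel count is preserved exactly.  If the foreground
    touches any image border the lesion cannot be shifted without losing
    pixels and a :class:`SegmentationError` is raised.
    """
    m = mask.mask
    if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
        raise SegmentationError("mask touches image border; cannot shift")
    out = []
    for label, (dr, dc) in _SHIFT_OFFSETS.items():
        shifted = np.roll(m, shift=(dr, dc), axis=(0, 1))
        out.append(
            SegmentationMask(shifted, label, mask.source_threshold, mask.case_id)
        )
    return out


def make_variant_set(
    image: np.ndarray,
    delineation: np.ndarray,
    case_id: str = "",
) -> SegmentationVariantSet:
    """Build the nine segmentations of one lesion.

    The Otsu threshold is computed from the intensity histogram of the
    delineated region only, then: original (100 %), four resized variants
    (80/90/110/120 % threshold) and four one-pixel shifts of the original.
    """
    delineation = np.asarray(delineation, dtype=bool)
    threshold = otsu_threshold(np.asarray(image, dtype=float)[delineation])
    original = segment(image, delineation, threshold, "original", case_id)
    variants = {"original": original}
    for v in resize_variants(image, delineation, threshold, case_id=case_id):
        variants[v.variant_label] = v
    for v in shift_variants(original):
        variants[v.variant_label] = v
    return SegmentationVariantSet(variants=variants, case_id=case_id)


def dice(a: SegmentationMask | np.ndarray, b: SegmentationMask | np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) between two masks."""
    ma = a.mask if isinstance(a, SegmentationMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, SegmentationMask) else np.asarray(b, dtype=bool)
    denom = ma.sum() + mb.sum()
    return 2.0 * np.logical_and(ma, mb).sum() / denom if denom else 0.0
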