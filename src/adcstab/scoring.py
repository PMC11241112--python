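"""Point classification of OCCC/DR, the stability score, and ranking.

Each statistic maps to 0-4 points on fixed breakpoints (identical for OCCC
and DR); a feature's per-category score is the sum of its OCCC and DR
points (max 8 = 4 + 4).  Features are ranked by their distance to the
optimal (8, 8) point of the (shifting score, resizing score) plane; shape
features, which are blind to shifts, are ranked on the resizing axis alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScoreThresholds:
    """Left-closed/right-open intervals; the top interval is '>= last'."""

    breakpoints: tuple[float, ...] = (0.75, 0.85, 0.90, 0.95)

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")


DEFAULT_THRESHOLDS = ScoreThresholds()

MAX_POINTS = 4
MAX_SCORE = 2 * MAX_POINTS  # 8 per category


def points(value: float, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS) -> int:
    """Classify one OCCC or DR value into 0-4 points.

    Degenerate (NaN) statistics score 0: a feature whose stability cannot be
    established gets no credit.
    """
    if value is None or not math.isfinite(value):
        return 0
    return int(np.searchsorted(thresholds.breakpoints, value, side="right"))


def stability_score(occc_points: int, dr_points: int) -> int:
    """Per-category score: sum of the two point classifications (0-8)."""
    for p in (occc_points, dr_points):
        if not 0 <= p <= MAX_POINTS:
            raise ValueError("points must lie in 0..4")
    return occc_points + dr_points


@dataclass
class StabilityRecord:
    """Stability summary of one feature (both categories for non-shape)."""

    feature_name: str
    feature_class: str
    categories: dict[str, dict[str, float]] = field(default_factory=dict)
    distance_to_optimum: float = math.nan
    rank: int = 0

    @property
    def is_shape(self) -> bool:
        return self.feature_class == "shape2D"

    def category_score(self, category: str) -> int:
        c = self.categories[category]
        return stability_score(int(c["occc_points"]), int(c["dr_points"]))


def score_record(
    feature_name: str,
    feature_class: str,
    category_stats: dict[str, dict[str, float]],
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> StabilityRecord:
    """Attach point classifications and the per-category score to raw stats."""
    categories = {}
    for cat, stats in category_stats.items():
        s = dict(stats)
        s["occc_points"] = points(s.get("occc", math.nan), thresholds)
        s["dr_points"] = points(s.get("dr", math.nan), thresholds)
        s["score"] = s["occc_points"] + s["dr_points"]
        categories[cat] = s
    return StabilityRecord(feature_name, feature_class, categories)


def rank_features(
    records: list[StabilityRecord],
    metric: str = "euclidean",
) -> list[StabilityRecord]:
    """Rank by distance to the optimum; dense ranking, ties share a rank.

    Non-shape features use the Euclidean distance of their (shifting,
    resizing) scores to (8, 8) (Manhattan/Chebyshev selectable); shape
    features are ranked separately on 8 - resizing score.  The returned
    list holds the non-shape ranking first, then the shape ranking, each
    sorted ascending by distance.
    """
    norm = {
        "euclidean": lambda d: math.hypot(*d),
        "manhattan": lambda d: sum(abs(x) for x in d),
        "chebyshev": lambda d: max(abs(x) for x in d),
    }[metric]

    non_shape = [r for r in records if not r.is_shape]
    shape = [r for r in records if r.is_shape]

    for r in non_shape:
        r.distance_to_optimum = norm(
            (
                MAX_SCORE - r.category_score("shifting"),
                MAX_SCORE - r.category_score("resizing"),
            )
        )
    for r in shape:
        r.distance_to_optimum = float(MAX_SCORE - r.category_score("resizing"))

    out: list[StabilityRecord] = []
    for group in (non_shape, shape):
        group.sort(key=lambda r: (r.distance_to_optimum, r.feature_name))
        distances = sorted({r.distance_to_optimum for r in group})
        rank_of = {d: i + 1 for i, d in enumerate(distances)}
        for r in group:
            r.rank = rank_of[r.distance_to_optimum]
        out.extend(group)
    return out


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    """Flatten StabilityRecords to a tidy frame (one row per feature)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "feature": r.feature_name,
            "class": r.feature_class,
            "distance": r.distance_to_optimum,
            "rank": r.rank,
        }
        for cat, s in r.categories.items():
            for key in (
                "occc", "occc_lo", "occc_hi", "occc_points",
                "dr", "dr_lo", "dr_hi", "dr_points", "score",
                "n_lesions", "n_dropped",
            ):
                if key in s:
                    row[f"{cat}_{key}"] = s[key]
        rows.append(row)
    return pd.DataFrame(rows)
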