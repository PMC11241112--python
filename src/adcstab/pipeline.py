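"""End-to-end stability pipeline on a synthetic lesion cohort.

Stages: phantom cohort -> ADC maps (b50/b750 fit, [0, 3.5] um^2/ms outlier
filter) -> nine segmentation variants per lesion (Otsu on the b1500 image)
-> 102 features per lesion/variant -> OCCC and DR per feature per
perturbation category with bootstrap CIs -> point scores and ranking ->
paired threshold significance tests.  Per-lesion failures (e.g. a lesion
that empties at the 120 % threshold) are logged and skipped; they never
abort the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nifti_io
from .adc import ADCMap, apply_range_filter, compute_adc
from .features import (
    ExtractionConfig,
    FEATURE_NAMES,
    ExtractionError,
    extract_all,
    vectors_to_table,
)
from .scoring import (
    DEFAULT_THRESHOLDS,
    ScoreThresholds,
    StabilityRecord,
    rank_features,
    records_to_frame,
    score_record,
)
from .segmentation import (
    RESIZE_LABELS,
    SHIFT_LABELS,
    VARIANT_LABELS,
    SegmentationError,
    dice,
    make_variant_set,
)
from .stability import category_stability
from .stats_tests import results_to_frame, threshold_pair_tests
from .synthetic import PhantomCase, PhantomConfig, generate_cohort

logger = logging.getLogger(__name__)

CATEGORY_LABELS = {"resizing": RESIZE_LABELS, "shifting": SHIFT_LABELS}


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    n_lesions: int = 30
    cohort_seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    thresholds: ScoreThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    bootstrap_B: int = 1000
    bootstrap_seed: int = 0
    rank_metric: str = "euclidean"
    boxplot_feature: str = "firstorder_Skewness"
    group_labels: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            for key in ("b_values", "lesion_radius_range", "lesion_adc_range"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "extraction" in kwargs:
            ex = dict(kwargs["extraction"])
            if "adc_range" in ex:
                ex["adc_range"] = tuple(ex["adc_range"])
            kwargs["extraction"] = ExtractionConfig(**ex)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = ScoreThresholds(tuple(kwargs["thresholds"]))
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(self), fh, sort_keys=False)


def case_adc(case: PhantomCase, adc_range=(0.0, 3.5)) -> ADCMap:
    """Two-point ADC fit from the two lowest b-values, range-filtered."""
    bs = sorted(case.images)
    adc = compute_adc(case.images[bs[0]], bs[0], case.images[bs[1]], bs[1])
    return apply_range_filter(adc, *adc_range)


def segmentation_image(case: PhantomCase) -> np.ndarray:
    """Image used for delineation/thresholding: the highest b-value."""
    return case.images[max(case.images)]


def extract_cohort(
    cases: list[PhantomCase],
    config: ExtractionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Extract all features for all lesions and variants.

    Returns (long-format feature table, per-variant Dice/size summary,
    exclusion log).  Lesions failing segmentation or extraction for any
    variant are excluded entirely, keeping the table complete per lesion.
    """
    config = config or ExtractionConfig()
    vectors = []
    dice_rows = []
    exclusions: list[dict] = []
    for case in cases:
        try:
            adc = case_adc(case, config.adc_range)
            variants = make_variant_set(
                segmentation_image(case), case.delineation, case.case_id
            )
            case_vectors = [
                extract_all(adc, variants[label], case.pixel_spacing, config)
                for label in VARIANT_LABELS
            ]
        except (SegmentationError, ExtractionError) as err:
            logger.warning("excluding lesion %s: %s", case.case_id, err)
            exclusions.append({"case_id": case.case_id, "reason": str(err)})
            continue
        vectors.extend(case_vectors)
        original = variants["original"]
        for label in VARIANT_LABELS:
            v = variants[label]
            dice_rows.append(
                {
                    "case_id": case.case_id,
                    "variant_label": label,
                    "n_pixels": v.size,
                    "dice_vs_original": dice(original, v),
                    "size_change_pct": 100.0 * (v.size - original.size) / original.size,
                }
            )
    table = vectors_to_table(vectors)
    return table, pd.DataFrame(dice_rows), exclusions


def feature_matrix(
    table: pd.DataFrame, feature: str, labels: tuple[str, ...]
) -> np.ndarray:
    """Pivot the long table to lesions x variants for one feature."""
    sub = table[(table["feature"] == feature) & table["variant_label"].isin(labels)]
    wide = sub.pivot(index="case_id", columns="variant_label", values="value")
    return wide.reindex(columns=list(labels)).to_numpy()


def stability_analysis(
    table: pd.DataFrame,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    rank_metric: str = "euclidean",
) -> list[StabilityRecord]:
    """Per-feature OCCC/DR (+CIs), points, scores, and ranks.

    Shape features carry only the resizing category (shifts are pure
    translations and cannot change shape).
    """
    records = []
    for feature in FEATURE_NAMES:
        cls = feature.split("_", 1)[0]
        cats = ("resizing",) if cls == "shape2D" else ("resizing", "shifting")
        stats = {}
        for cat in cats:
            values = feature_matrix(table, feature, CATEGORY_LABELS[cat])
            stats[cat] = category_stability(values, B=B, level=level, seed=seed)
        records.append(score_record(feature, cls, stats, thresholds))
    return rank_features(records, metric=rank_metric)


def summarize_top(records: list[StabilityRecord], k: int = 18) -> pd.DataFrame:
    """Top-k non-shape features by rank, with per-class counts attached."""
    non_shape = [r for r in records if not r.is_shape]
    if k > len(non_shape):
        logger.warning("requested top %d of %d features; truncating", k, len(non_shape))
        k = len(non_shape)
    frame = records_to_frame(sorted(non_shape, key=lambda r: (r.rank, r.feature_name))[:k])
    if not frame.empty:
        frame["class_count"] = frame["class"].map(frame["class"].value_counts())
    return frame


def write_cohort(cases: list[PhantomCase], out_dir: str | Path) -> pd.DataFrame:
    """Write each case as NIfTI files plus a cohort manifest CSV."""
    out_dir = Path(out_dir)
    rows = []
    for case in cases:
        case_dir = out_dir / case.case_id
        paths = {}
        for b, img in case.images.items():
            paths[f"b{b:g}"] = nifti_io.write_nifti(
                case_dir / f"{case.case_id}__b{b:g}.nii.gz", img, case.pixel_spacing
            )
        paths["delineation"] = nifti_io.write_nifti(
            case_dir / f"{case.case_id}__delineation.nii.gz",
            case.delineation,
            case.pixel_spacing,
        )
        rows.append(
            {
                "case_id": case.case_id,
                "pixel_spacing": case.pixel_spacing,
                "seed": case.config.seed if case.config else -1,
                **{k: str(p) for k, p in paths.items()},
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def write_masks(cases: list[PhantomCase], out_dir: str | Path) -> int:
    """Write the nine variant masks per lesion; returns files written."""
    out_dir = Path(out_dir)
    n = 0
    for case in cases:
        variants = make_variant_set(
            segmentation_image(case), case.delineation, case.case_id
        )
        for label in VARIANT_LABELS:
            safe = label.replace("+", "p").replace("-", "m")
            nifti_io.write_nifti(
                out_dir / case.case_id / f"{case.case_id}__{safe}.nii.gz",
                variants[label].mask,
                case.pixel_spacing,
            )
            n += 1
    return n


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns a result bundle of dataframes.

    With ``output_dir`` set, all tables are written as CSV, the cohort and
    masks as NIfTI, and a JSON run report records exclusions and degenerate
    feature counts.
    """
    cases = generate_cohort(config.n_lesions, config.phantom, config.cohort_seed)
    table, dice_summary, exclusions = extract_cohort(cases, config.extraction)
    if table.empty:
        raise RuntimeError("every lesion was excluded; nothing to analyze")
    records = stability_analysis(
        table,
        B=config.bootstrap_B,
        seed=config.bootstrap_seed,
        thresholds=config.thresholds,
        rank_metric=config.rank_metric,
    )
    stability_frame = records_to_frame(records)
    top = summarize_top(records)

    pair_results = pd.DataFrame()
    if config.boxplot_feature in set(table["feature"]):
        values = feature_matrix(table, config.boxplot_feature, RESIZE_LABELS)
        complete = values[np.isfinite(values).all(axis=1)]
        if complete.shape[0] >= 8:
            pair_results = results_to_frame(
                threshold_pair_tests(
                    complete,
                    config.boxplot_feature,
                    threshold_labels=RESIZE_LABELS,
                )
            )

    degenerate_counts = (
        table[~np.isfinite(table["value"])].groupby("feature").size().to_dict()
    )
    report = {
        "n_lesions_requested": config.n_lesions,
        "n_lesions_analyzed": int(table["case_id"].nunique()),
        "exclusions": exclusions,
        "degenerate_feature_counts": degenerate_counts,
    }
    bundle = {
        "cases": cases,
        "feature_table": table,
        "dice_summary": dice_summary,
        "stability": stability_frame,
        "records": records,
        "top": top,
        "pairwise_tests": pair_results,
        "report": report,
    }

    if config.group_labels:
        groups = {}
        for label in sorted(set(config.group_labels.values())):
            ids = {c for c, g in config.group_labels.items() if g == label}
            sub = table[table["case_id"].isin(ids) & (table["class"] == "firstorder")]
            if sub["case_id"].nunique() >= 3:
                g_records = []
                for feature in sorted(set(sub["feature"])):
                    stats = {
                        cat: category_stability(
                            feature_matrix(sub, feature, CATEGORY_LABELS[cat]),
                            B=config.bootstrap_B,
                            seed=config.bootstrap_seed,
                        )
                        for cat in ("resizing", "shifting")
                    }
                    g_records.append(
                        score_record(feature, "firstorder", stats, config.thresholds)
                    )
                groups[label] = records_to_frame(rank_features(g_records))
        bundle["group_stability"] = groups

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cases, out / "cohort")
        write_masks(cases, out / "masks")
        table.to_csv(out / "feature_table.csv", index=False)
        config.extraction and config.to_yaml(out / "run_config.yaml")
        dice_summary.to_csv(out / "dice_summary.csv", index=False)
        stability_frame.to_csv(out / "stability.csv", index=False)
        top.to_csv(out / "top_features.csv", index=False)
        pair_results.to_csv(out / "pairwise_tests.csv", index=False)
        for label, frame in bundle.get("group_stability", {}).items():
            frame.to_csv(out / f"stability_{label}.csv", index=False)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return bundle
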