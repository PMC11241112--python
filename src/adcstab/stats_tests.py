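"""Normality-gated paired significance tests between resizing thresholds.

For one feature measured at the five segmentation thresholds (80, 90, 100,
110, 120 % of the Otsu value), all C(5,2) = 10 threshold pairs are compared
on paired per-lesion differences: Shapiro-Wilk decides between the paired
two-sided t-test (normal differences) and the Wilcoxon signed-rank test
(non-normal); Bonferroni correction over the 10 pairs sets the significance
cutoff at 0.05 / 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
SHAPIRO_ALPHA = 0.05


@dataclass
class PairwiseTestResult:
    feature_name: str
    threshold_pair: tuple[str, str]
    test_used: str  # "paired-t" | "wilcoxon-signed-rank" | "skipped"
    p_value: float
    alpha_corrected: float
    significant: bool


def threshold_pair_tests(
    values: np.ndarray,
    feature_name: str = "",
    threshold_labels: tuple[str, ...] = ("th80", "th90", "original", "th110", "th120"),
    alpha: float = ALPHA,
) -> list[PairwiseTestResult]:
    """Paired tests between all threshold pairs of an n x 5 value matrix.

    Zero-variance difference vectors make both tests undefined; such pairs
    are flagged as skipped and non-significant.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if k != len(threshold_labels):
        raise ValueError("column count must match threshold labels")
    if n < 8:
        raise ValueError("need at least 8 lesions for valid paired tests")

    pairs = list(combinations(range(k), 2))
    alpha_corrected = alpha / len(pairs)
    results = []
    for a, b in pairs:
        diffs = values[:, a] - values[:, b]
        pair = (threshold_labels[a], threshold_labels[b])
        if np.ptp(diffs) == 0:
            results.append(
                PairwiseTestResult(
                    feature_name, pair, "skipped", np.nan, alpha_corrected, False
                )
            )
            continue
        normal = stats.shapiro(diffs).pvalue >= SHAPIRO_ALPHA
        if normal:
            p = stats.ttest_rel(values[:, a], values[:, b]).pvalue
            used = "paired-t"
        else:
            p = stats.wilcoxon(diffs).pvalue
            used = "wilcoxon-signed-rank"
        results.append(
            PairwiseTestResult(
                feature_name, pair, used, float(p), alpha_corrected,
                bool(p < alpha_corrected),
            )
        )
    return results


def results_to_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": r.feature_name,
            "threshold_a": r.threshold_pair[0],
            "threshold_b": r.threshold_pair[1],
            "test_used": r.test_used,
            "p_value": r.p_value,
            "alpha_corrected": r.alpha_corrected,
            "significant": r.significant,
        }
        for r in results
    )
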