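"""Feature-stability statistics: OCCC, Dynamic Range, and bootstrap CIs.

The Overall Concordance Correlation Coefficient (OCCC) generalizes Lin's
two-rater CCC to J segmentations.  With column means mu_j and population
(1/n) variances sigma_j^2 and covariances sigma_jk over lesions,

    OCCC = 2 * sum_{j<k} sigma_jk
           / [ (J-1) * sum_j sigma_j^2 + sum_{j<k} (mu_j - mu_k)^2 ]

lying in [-1, 1]; 1 is perfect agreement across all segmentations.

The Dynamic Range (DR) relates test-retest differences to the natural
between-lesion spread of a feature.  For retest r,

    DR_r = 1 - mean_i |f(Test(i)) - f(Retest_r(i))| / (Max - Min)

with Max/Min the extreme feature values of the original segmentation over
all lesions; DR is the average over the four retests.  DR near 1 means the
perturbation effect is small against the inter-patient range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class DegenerateStatisticError(ValueError):
    """Statistic undefined on this input (e.g. all-constant columns)."""


@dataclass
class CategoryMatrix:
    """Lesions x segmentation-variants values of one feature, original first."""

    values: np.ndarray
    feature_name: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("CategoryMatrix values must be 2D (lesions x variants)")

    def complete_rows(self) -> tuple[np.ndarray, int]:
        """Drop rows with any missing value; return (kept rows, n dropped)."""
        keep = np.isfinite(self.values).all(axis=1)
        return self.values[keep], int((~keep).sum())


@dataclass
class DRInputs:
    """Original-segmentation vector, the retest vectors, and the range."""

    test: np.ndarray
    retests: np.ndarray  # (n_retests, n_lesions)
    max_val: float
    min_val: float

    @classmethod
    def from_vectors(cls, test: np.ndarray, retests: np.ndarray) -> "DRInputs":
        test = np.asarray(test, dtype=float)
        retests = np.atleast_2d(np.asarray(retests, dtype=float))
        return cls(
            test=test,
            retests=retests,
            max_val=float(np.max(test)),
            min_val=float(np.min(test)),
        )


def occc(m: CategoryMatrix | np.ndarray) -> float:
    """Overall Concordance Correlation Coefficient of an n x J matrix."""
    values = m.values if isinstance(m, CategoryMatrix) else np.asarray(m, dtype=float)
    if isinstance(m, CategoryMatrix):
        values, _ = m.complete_rows()
    n, J = values.shape
    if n < 3:
        raise ValueError("OCCC requires at least 3 complete lesions")
    return float(_occc_batch(values[None, :, :])[0])


def _occc_batch(values: np.ndarray) -> np.ndarray:
    """Vectorized OCCC over a (B, n, J) stack; NaN where undefined."""
    B, n, J = values.shape
    mu = values.mean(axis=1)  # (B, J)
    centered = values - mu[:, None, :]
    cov = np.einsum("bnj,bnk->bjk", centered, centered) / n  # population
    var_sum = np.einsum("bjj->b", cov)
    cov_sum = (cov.sum(axis=(1, 2)) - var_sum) / 2.0  # sum over j<k
    mu_diff = mu[:, :, None] - mu[:, None, :]
    mean_term = (mu_diff**2).sum(axis=(1, 2)) / 2.0
    denom = (J - 1) * var_sum + mean_term
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * cov_sum / denom
    out[denom == 0] = np.nan
    return out


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's two-rater concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.var()
    sy = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * sxy / (sx + sy + (x.mean() - y.mean()) ** 2))


def dynamic_range(d: DRInputs) -> float:
    """Mean DR over the retest segmentations; NaN if the feature has no
    between-lesion range (Max == Min)."""
    rng = d.max_val - d.min_val
    if rng <= 0:
        return np.nan
    dr_per_retest = 1.0 - np.mean(np.abs(d.test[None, :] - d.retests), axis=1) / rng
    value = float(np.mean(dr_per_retest))
    if value < 0:
        warnings.warn(
            "DR below 0: test-retest differences exceed the feature range",
            stacklevel=2,
        )
    return value


def _dr_batch(test: np.ndarray, retests: np.ndarray) -> np.ndarray:
    """DR over a bootstrap stack: test (B, n), retests (B, R, n)."""
    max_val = test.max(axis=1)
    min_val = test.min(axis=1)
    rng = max_val - min_val
    diffs = np.abs(test[:, None, :] - retests).mean(axis=2)  # (B, R)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (1.0 - diffs / rng[:, None]).mean(axis=1)
    out[rng <= 0] = np.nan
    return out


def bootstrap_ci(
    statistic: str,
    data: CategoryMatrix | np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``statistic`` in {"occc", "dr"}.

    Lesions (rows of the n x J matrix, original segmentation first) are
    resampled with replacement B times.  Resamples on which the statistic is
    undefined (constant columns / zero range) are skipped.
    """
    values = (
        data.values if isinstance(data, CategoryMatrix) else np.asarray(data, float)
    )
    if isinstance(data, CategoryMatrix):
        values, _ = data.complete_rows()
    n = values.shape[0]
    if n < 3:
        raise ValueError("bootstrap requires at least 3 complete lesions")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    samples = values[idx]  # (B, n, J)
    if statistic == "occc":
        stats = _occc_batch(samples)
    elif statistic == "dr":
        stats = _dr_batch(samples[:, :, 0], samples.transpose(0, 2, 1)[:, 1:, :])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        raise DegenerateStatisticError("statistic undefined on every resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def category_stability(
    values: np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
) -> dict[str, float]:
    """OCCC and DR (with CIs) of one feature in one perturbation category.

    ``values`` is n lesions x J variants with the original segmentation in
    column 0.  Undefined statistics come back NaN with zeroed CIs handled by
    the caller's scoring (degenerate -> 0 points).
    """
    m = CategoryMatrix(values)
    complete, n_dropped = m.complete_rows()
    out: dict[str, float] = {"n_lesions": complete.shape[0], "n_dropped": n_dropped}
    if complete.shape[0] < 3:
        out.update(
            occc=np.nan, occc_lo=np.nan, occc_hi=np.nan,
            dr=np.nan, dr_lo=np.nan, dr_hi=np.nan,
        )
        return out
    out["occc"] = float(_occc_batch(complete[None])[0])
    out["dr"] = dynamic_range(
        DRInputs.from_vectors(complete[:, 0], complete[:, 1:].T)
    )
    for stat in ("occc", "dr"):
        if np.isfinite(out[stat]):
            try:
                lo, hi = bootstrap_ci(stat, complete, B=B, level=level, seed=seed)
            except DegenerateStatisticError:
                lo = hi = np.nan
        else:
            lo = hi = np.nan
        out[f"{stat}_lo"], out[f"{stat}_hi"] = lo, hi
    return out
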