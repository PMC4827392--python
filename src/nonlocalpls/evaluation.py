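"""Predictive-accuracy and group-separation summaries.

Given predicted and observed target volumes, this module produces the
standard comparison battery: per-group mean absolute error maps, per-subject
regional mean tables over an atlas, Pearson correlation against reference
regional values (with a Fisher-z confidence interval), standardized
between-group mean differences (Cohen's d with pooled SD), and paired
t-tests of per-subject errors between two prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "absolute_error_map",
    "regional_means",
    "regional_table",
    "regional_absolute_error",
    "correlation_with_reference",
    "effect_size",
    "paired_error_test",
]


@dataclass
class EvaluationReport:
    """Bundle of evaluation outputs for one method on one test set."""

    per_voxel_mae: dict[str, np.ndarray]
    regional: pd.DataFrame
    correlation: tuple[float, tuple[float, float]] | None = None
    effect_sizes: pd.DataFrame | None = None


def absolute_error_map(
    Y_hat: np.ndarray, Y: np.ndarray, group_labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Voxel-wise mean absolute error within each group.

    Returns a mapping group -> masked-voxel MAE vector (exportable as a
    volume via :func:`nonlocalpls.dataset_io.write_image`).
    """
    Y_hat, Y = np.asarray(Y_hat), np.asarray(Y)
    if Y_hat.shape != Y.shape:
        raise ValueError(f"shape mismatch: {Y_hat.shape} vs {Y.shape}")
    err = np.abs(Y_hat - Y)
    labels = np.asarray(group_labels)
    return {g: err[labels == g].mean(axis=0) for g in pd.unique(labels)}


def regional_means(values: np.ndarray, atlas: np.ndarray, mask: np.ndarray) -> pd.Series:
    """Arithmetic mean of masked voxels per foreground atlas label.

    ``values`` is a masked voxel vector; ``atlas`` a label volume aligned to
    the data grid (0 = background).
    """
    values = np.asarray(values)
    atlas_m = np.asarray(atlas)[np.asarray(mask, dtype=bool)]
    labels = np.unique(atlas_m[atlas_m > 0])
    if labels.size == 0:
        raise ValueError("atlas has no foreground labels inside the mask")
    return pd.Series(
        {int(lab): float(values[atlas_m == lab].mean()) for lab in labels},
        name="regional_mean",
    )


def regional_table(
    rows: np.ndarray, atlas: np.ndarray, mask: np.ndarray, value_name: str = "value"
) -> pd.DataFrame:
    """Tidy per-subject, per-region mean table for a matrix of voxel rows."""
    rows = np.atleast_2d(rows)
    atlas_m = np.asarray(atlas)[np.asarray(mask, dtype=bool)]
    labels = np.unique(atlas_m[atlas_m > 0])
    if labels.size == 0:
        raise ValueError("atlas has no foreground labels inside the mask")
    records = []
    for lab in labels:
        sel = atlas_m == lab
        means = rows[:, sel].mean(axis=1)
        records.extend((k, int(lab), float(v)) for k, v in enumerate(means))
    return pd.DataFrame(records, columns=["subject", "region", value_name])


def regional_absolute_error(
    Y_hat: np.ndarray, Y: np.ndarray, atlas: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Per-subject regional MAE: mean over regions of the within-region
    mean absolute voxel error."""
    Y_hat, Y = np.atleast_2d(Y_hat), np.atleast_2d(Y)
    if Y_hat.shape != Y.shape:
        raise ValueError(f"shape mismatch: {Y_hat.shape} vs {Y.shape}")
    err = np.abs(Y_hat - Y)
    atlas_m = np.asarray(atlas)[np.asarray(mask, dtype=bool)]
    labels = np.unique(atlas_m[atlas_m > 0])
    per_region = np.stack([err[:, atlas_m == lab].mean(axis=1) for lab in labels], axis=1)
    return per_region.mean(axis=1)


def correlation_with_reference(
    predicted: np.ndarray, reference: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Pearson r with a 95% Fisher-z confidence interval."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.ndim != 1:
        raise ValueError("predicted and reference must be equal-length 1-D vectors")
    n = predicted.size
    if n < 4:
        raise ValueError("need at least 4 paired values for a confidence interval")
    if predicted.std() == 0 or reference.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r = float(np.corrcoef(predicted, reference)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return r, (float(lo), float(hi))


def effect_size(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation; sign is A minus B."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation; effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def paired_error_test(errors_a: np.ndarray, errors_b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject errors of two methods.

    Degenerate zero-variance differences are resolved deterministically:
    identical inputs give the no-difference outcome (statistic 0.0, p-value
    1.0) and a constant non-zero offset gives a signed infinite statistic
    with p-value 0.0.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired error vectors must be equal-length 1-D")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
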