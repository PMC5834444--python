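"""Segmentation quality metrics, volume concordance and feature discrimination.

Segmentation is scored voxelwise (sensitivity, specificity, precision,
accuracy, Dice, Jaccard) with specificity computed over the full scan
field of view.  Automatic-vs-reference volume agreement is an ordinary
least-squares fit of auto on reference.  Per-feature class discrimination
uses two-sample t-tests (Welch by default).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegMetrics:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    dice: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "dice": self.dice,
            "jaccard": self.jaccard,
        }


def _as_bool(x) -> np.ndarray:
    arr = getattr(x, "voxels", x)
    return np.asarray(arr, dtype=bool)


def segmentation_metrics(pred, truth) -> SegMetrics:
    """Voxelwise overlap metrics between a predicted and a reference mask.

    Conventions for degenerate inputs (logged): both masks empty -> all
    metrics 1; empty truth with non-empty prediction -> sensitivity (and the
    overlap scores) 0; empty prediction with non-empty truth -> precision 0.
    """
    p = _as_bool(pred)
    t = _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)

    if tp + fn == 0 and tp + fp == 0:
        logger.info("both masks empty; reporting all metrics as 1 by convention")
        return SegMetrics(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    if tp + fn == 0:
        logger.warning("empty reference mask with non-empty prediction; sensitivity -> 0")
        sensitivity = 0.0
    else:
        sensitivity = tp / (tp + fn)
    if tp + fp == 0:
        logger.warning("empty prediction with non-empty reference; precision -> 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    specificity = tn / (tn + fp) if tn + fp else 1.0
    accuracy = (tp + tn) / p.size
    dice = 2 * tp / (2 * tp + fp + fn)
    jaccard = tp / (tp + fp + fn)
    return SegMetrics(sensitivity, specificity, precision, accuracy, dice, jaccard)


@dataclass(frozen=True)
class ConcordanceFit:
    slope: float
    intercept: float
    r_squared: float


def volume_concordance(auto_ml, ref_ml) -> ConcordanceFit:
    """OLS fit of automatic volumes on reference volumes (both in mL)."""
    auto = np.asarray(auto_ml, dtype=float)
    ref = np.asarray(ref_ml, dtype=float)
    if auto.shape != ref.shape or auto.ndim != 1:
        raise ValueError("auto and reference volume lists must have equal length")
    if auto.size < 3:
        raise ValueError("need at least 3 volume pairs")
    if np.var(ref) == 0:
        raise ValueError("reference volumes have zero variance")
    fit = stats.linregress(ref, auto)
    return ConcordanceFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def feature_discrimination(
    features: pd.DataFrame,
    class_col: str = "tissue",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test of every feature for every class pair.

    Welch (unequal-variance) by default; set ``equal_var=True`` for the pooled
    variant.  Degenerate zero-variance comparisons use the convention p = 0
    when the means differ and p = 1 when they are equal (logged).

    Returns a long table with columns feature, class_a, class_b, t, p.
    """
    if class_col not in features.columns:
        raise ValueError(f"missing class column {class_col!r}")
    classes = sorted(features[class_col].unique())
    feat_cols = [c for c in features.columns if c != class_col]
    grouped = {c: features.loc[features[class_col] == c, feat_cols] for c in classes}
    for c, g in grouped.items():
        if len(g) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    rows = []
    for a, b in itertools.combinations(classes, 2):
        xa = grouped[a].to_numpy(dtype=float)
        xb = grouped[b].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(xa, xb, axis=0, equal_var=equal_var)
        t = np.atleast_1d(t)
        p = np.atleast_1d(p)
        degenerate = ~np.isfinite(p)
        if degenerate.any():
            logger.info(
                "zero-variance t-test for %d feature(s) in %s vs %s; "
                "using p=0 if means differ else p=1",
                int(degenerate.sum()), a, b,
            )
            means_equal = np.isclose(xa.mean(axis=0), xb.mean(axis=0))
            p = np.where(degenerate, np.where(means_equal, 1.0, 0.0), p)
            t = np.where(np.isfinite(t), t, np.where(means_equal, 0.0, np.inf))
        for j, name in enumerate(feat_cols):
            rows.append(
                {"feature": name, "class_a": a, "class_b": b,
                 "t": float(t[j]), "p": float(p[j])}
            )
    return pd.DataFrame(rows)


def top_discriminating(
    features: pd.DataFrame,
    class_col: str = "tissue",
    k: int = 5,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Top-k discriminating features per tissue (one-vs-rest t-tests).

    Emits the ranked table used to summarise which radiomics features carry
    the classification signal for each tissue type.
    """
    classes = sorted(features[class_col].unique())
    feat_cols = [c for c in features.columns if c != class_col]
    rows = []
    for cls in classes:
        xa = features.loc[features[class_col] == cls, feat_cols].to_numpy(dtype=float)
        xb = features.loc[features[class_col] != cls, feat_cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(xa, xb, axis=0, equal_var=equal_var)
        p = np.where(np.isfinite(p), p, 1.0)
        order = np.argsort(p, kind="stable")[:k]
        for rank, j in enumerate(order, start=1):
            rows.append(
                {"tissue": cls, "rank": rank, "feature": feat_cols[j],
                 "t": float(np.atleast_1d(t)[j]), "p": float(np.atleast_1d(p)[j])}
            )
    return pd.DataFrame(rows)
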