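"""End-to-end pipeline: scan -> SUV -> regions -> features -> classification.

Also hosts the two-cohort experiment harness used to reproduce the study
design on synthetic cohorts: train a forest on the regions of one phantom
cohort, test on an independently seeded cohort, and score segmentation
(per-organ Dice), tumor volume concordance and constrained classification
accuracy against the generated ground truth.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .classifier import (
    ConstrainedTissueClassifier,
    evaluate_holdout,
)
from .evaluation import volume_concordance
from .features import CORE28_NAMES, FULL62_NAMES, RadiomicsExtractor
from .phantom import PhantomScan, PhantomSpec, iter_cohort
from .preprocess import (
    DEFAULT_SUV_THRESHOLD,
    DEFAULT_TARGET_MM,
    GaussianKernelSpec,
    preprocess,
)
from .segmentation import (
    DEFAULT_CLOSING_RADIUS,
    DEFAULT_H_MAXIMA,
    DEFAULT_MIN_VOLUME_ML,
    Region,
    segment,
)
from .volumes import PETScan, RegionLabelMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters with their defaults."""

    target_spacing_mm: float = DEFAULT_TARGET_MM
    sigma_vox: float = 1.0
    truncate: float = 4.0
    threshold: float = DEFAULT_SUV_THRESHOLD
    h_maxima: float = DEFAULT_H_MAXIMA
    closing_radius: int = DEFAULT_CLOSING_RADIUS
    min_volume_ml: float = DEFAULT_MIN_VOLUME_ML
    n_bins: int = 16

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def log(self) -> None:
        logger.info("pipeline parameters: %s", asdict(self))


@dataclass(frozen=True)
class ProcessedScan:
    """Intermediate products of the preprocessing + segmentation chain."""

    smoothed: object
    mask: object
    labels: RegionLabelMap
    regions: list[Region]


def process_scan(
    scan: PETScan,
    config: PipelineConfig | None = None,
    manual_labels: RegionLabelMap | None = None,
) -> ProcessedScan:
    """SUV conversion, resampling, smoothing, thresholding and segmentation."""
    config = config or PipelineConfig()
    kernel = GaussianKernelSpec(sigma_vox=config.sigma_vox, truncate=config.truncate)
    smoothed, mask = preprocess(
        scan, target_mm=config.target_spacing_mm, kernel=kernel,
        threshold=config.threshold,
    )
    labels, regions = segment(
        mask, smoothed,
        h=config.h_maxima,
        closing_radius=config.closing_radius,
        min_volume_ml=config.min_volume_ml,
        manual_labels=manual_labels,
    )
    return ProcessedScan(smoothed=smoothed, mask=mask, labels=labels, regions=regions)


def region_table(regions: list[Region]) -> pd.DataFrame:
    """Summary table: id, volume, centroid, mean/max SUV per region."""
    rows = []
    for r in regions:
        c = r.voxel_indices.mean(axis=0)
        rows.append(
            {
                "id": r.id,
                "volume_ml": r.volume_ml,
                "centroid_i": float(c[0]),
                "centroid_j": float(c[1]),
                "centroid_k": float(c[2]),
                "mean_suv": float(r.suv_values.mean()),
                "max_suv": float(r.suv_values.max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "volume_ml", "centroid_i", "centroid_j", "centroid_k",
                 "mean_suv", "max_suv"],
    )


def match_regions_to_truth(
    regions: list[Region],
    truth: RegionLabelMap,
    classes: dict[int, str],
) -> list[tuple[str | None, int, int]]:
    """Majority-overlap truth class per region.

    Returns, per region, ``(truth_class_or_None, truth_label, overlap_voxels)``.
    """
    out = []
    t = truth.voxels
    for r in regions:
        idx = r.voxel_indices
        lab = t[idx[:, 0], idx[:, 1], idx[:, 2]]
        lab = lab[lab > 0]
        if lab.size == 0:
            out.append((None, 0, 0))
            continue
        counts = np.bincount(lab)
        best = int(np.argmax(counts))
        out.append((classes.get(best), best, int(counts[best])))
    return out


def _dice_from_counts(n_region: int, n_truth: int, overlap: int) -> float:
    return 2.0 * overlap / (n_region + n_truth)


@dataclass
class CohortAnalysis:
    """Per-region features with truth labels plus segmentation scores."""

    features: pd.DataFrame
    dice: pd.DataFrame
    tumor_pairs: pd.DataFrame
    regions_per_scan: list[int] = field(default_factory=list)
    unmatched_regions: int = 0
    undetected_tumors: int = 0


def analyze_phantom_scan(
    ph: PhantomScan,
    scan_index: int,
    config: PipelineConfig | None = None,
    feature_set: str = "full62",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, int, int]:
    """Process one phantom scan and score it against its ground truth."""
    config = config or PipelineConfig()
    processed = process_scan(ph.scan, config)
    regions = processed.regions
    extractor = RadiomicsExtractor(feature_set=feature_set, n_bins=config.n_bins).fit([])
    feats = extractor.transform(regions) if regions else pd.DataFrame(
        columns=extractor.feature_names_
    )
    matches = match_regions_to_truth(regions, ph.truth, ph.classes)

    feats.insert(0, "scan", scan_index)
    feats.insert(1, "region_id", [r.id for r in regions])
    feats.insert(2, "tissue", [m[0] for m in matches])

    truth_sizes = np.bincount(ph.truth.voxels.ravel())
    voxel_ml = ph.scan.spacing[0] ** 3 / 1000.0

    # per-truth-region match for Dice / volume concordance: a truth organ's
    # automatic counterpart is the union of all segmented regions whose
    # majority overlap points at it (a heterogeneous tumor may be split by
    # the watershed into more than one region)
    agg: dict[int, list[int, int]] = {}  # truth label -> [voxels, overlap]
    for pos, (cls, t_lab, ov) in enumerate(matches):
        if cls is None:
            continue
        entry = agg.setdefault(t_lab, [0, 0])
        entry[0] += regions[pos].n_voxels
        entry[1] += ov

    dice_rows, tumor_rows = [], []
    undetected_tumors = 0
    for t_lab, cls in ph.classes.items():
        n_truth = int(truth_sizes[t_lab]) if t_lab < truth_sizes.size else 0
        if n_truth == 0:  # absent / fully partial-suppressed organ
            continue
        hit = agg.get(t_lab)
        if hit is None:
            if cls == "tumor":
                undetected_tumors += 1
            else:
                dice_rows.append(
                    {"scan": scan_index, "class": cls, "mode": ph.modes[t_lab],
                     "dice": 0.0, "truth_ml": n_truth * voxel_ml}
                )
            continue
        n_auto, ov = hit
        d = _dice_from_counts(n_auto, n_truth, ov)
        if cls == "tumor":
            tumor_rows.append(
                {"scan": scan_index, "truth_ml": n_truth * voxel_ml,
                 "auto_ml": n_auto * voxel_ml, "dice": d}
            )
        else:
            dice_rows.append(
                {"scan": scan_index, "class": cls, "mode": ph.modes[t_lab],
                 "dice": d, "truth_ml": n_truth * voxel_ml}
            )
    unmatched = sum(1 for cls, _, _ in matches if cls is None)
    return (
        feats,
        pd.DataFrame(dice_rows, columns=["scan", "class", "mode", "dice", "truth_ml"]),
        pd.DataFrame(tumor_rows, columns=["scan", "truth_ml", "auto_ml", "dice"]),
        unmatched,
        undetected_tumors,
    )


def analyze_cohort(
    spec: PhantomSpec,
    n_scans: int,
    master_seed: int,
    config: PipelineConfig | None = None,
    feature_set: str = "full62",
) -> CohortAnalysis:
    """Generate and fully process a phantom cohort, scan by scan."""
    feats, dices, tumors = [], [], []
    per_scan, unmatched, undetected = [], 0, 0
    for i, ph in iter_cohort(spec, n_scans, master_seed):
        f, d, t, um, ud = analyze_phantom_scan(ph, i, config, feature_set)
        feats.append(f)
        dices.append(d)
        tumors.append(t)
        per_scan.append(len(f))
        unmatched += um
        undetected += ud
    def _concat(frames):
        nonempty = [f for f in frames if len(f)]
        return pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]

    return CohortAnalysis(
        features=_concat(feats),
        dice=_concat(dices),
        tumor_pairs=_concat(tumors),
        regions_per_scan=per_scan,
        unmatched_regions=unmatched,
        undetected_tumors=undetected,
    )


def _xy(analysis: CohortAnalysis, names) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    df = analysis.features.dropna(subset=["tissue"])
    return df[list(names)], df["tissue"].to_numpy(), df["scan"].to_numpy()


def two_cohort_experiment(
    seed: int,
    n_train: int = 30,
    n_test: int = 30,
    spec: PhantomSpec | None = None,
    config: PipelineConfig | None = None,
    n_trees: int = 50,
    include_texture_variant: bool = True,
    train_analysis: CohortAnalysis | None = None,
    test_analysis: CohortAnalysis | None = None,
) -> dict:
    """Train-on-cohort-A / test-on-cohort-B harness on independent phantoms.

    Returns a dictionary with the fitted models, hold-out reports for the
    28-feature forest (and the 62-feature double-size forest when requested),
    per-organ Dice of the training cohort, and tumor volume concordance pooled
    over both cohorts.
    """
    spec = spec or PhantomSpec()
    config = config or PipelineConfig()
    state = np.random.SeedSequence(seed).generate_state(4, dtype=np.uint64)
    seed_a, seed_b, seed_f1, seed_f2 = (int(s % (2**31)) for s in state)

    a = train_analysis or analyze_cohort(spec, n_train, seed_a, config)
    b = test_analysis or analyze_cohort(spec, n_test, seed_b, config)

    Xa, ya, _ = _xy(a, CORE28_NAMES)
    Xb, yb, gb = _xy(b, CORE28_NAMES)
    clf = ConstrainedTissueClassifier(n_trees=n_trees, random_state=seed_f1)
    clf.fit(Xa, ya)
    report = evaluate_holdout(clf, Xb, yb, groups=gb)

    out = {
        "model": clf,
        "report": report,
        "oob_error": clf.oob_error_,
        "train_analysis": a,
        "test_analysis": b,
        "dice": a.dice,
        "regions_per_scan": a.regions_per_scan + b.regions_per_scan,
    }

    pairs = pd.concat([a.tumor_pairs, b.tumor_pairs], ignore_index=True)
    out["tumor_pairs"] = pairs
    if len(pairs) >= 3:
        out["concordance"] = volume_concordance(pairs["auto_ml"], pairs["truth_ml"])

    if include_texture_variant:
        Xa2, ya2, _ = _xy(a, FULL62_NAMES)
        Xb2, yb2, gb2 = _xy(b, FULL62_NAMES)
        clf2 = ConstrainedTissueClassifier(n_trees=2 * n_trees, random_state=seed_f2)
        clf2.fit(Xa2, ya2)
        out["model_texture"] = clf2
        out["report_texture"] = evaluate_holdout(clf2, Xb2, yb2, groups=gb2)
        out["oob_error_texture"] = clf2.oob_error_
    return out


def accuracy_from_report(report: pd.DataFrame, tissue: str = "overall") -> float:
    row = report.loc[report["tissue"] == tissue]
    if row.empty:
        raise KeyError(f"no tissue {tissue!r} in report")
    return float(row["accuracy"].iloc[0])
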