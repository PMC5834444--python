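"""Random-forest tissue classification with a per-scan sole-occurrence constraint.

Each segmented region is classified as brain, heart, left/right kidney,
bladder or tumor.  Probabilities are the fraction of trees voting each class
(all features equally weighted, uniform priors, no rebalancing).  Within one
scan each normal-tissue label may be used at most once; tumor may repeat
(primary site plus metastases).  The constrained labelling maximises the
summed log-probability and is solved exactly as a rectangular linear
assignment problem with one column per normal tissue and one tumor column per
region.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

TISSUE_CLASSES = ("bladder", "brain", "heart", "kidney_left", "kidney_right", "tumor")
NORMAL_TISSUES = tuple(c for c in TISSUE_CLASSES if c != "tumor")
TUMOR_CLASS = "tumor"

DEFAULT_N_TREES = 50
PROB_FLOOR = 1e-9


@dataclass(frozen=True)
class TissueAssignment:
    """Constrained labelling of one scan's regions."""

    region_ids: tuple
    classes: tuple
    prob_matrix: np.ndarray
    labels: tuple
    objective: float

    def __post_init__(self):
        p = np.asarray(self.prob_matrix, dtype=float)
        if p.shape != (len(self.region_ids), len(self.classes)):
            raise ValueError("prob_matrix shape does not match regions x classes")
        if p.size and not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        normals = [l for l in self.labels if l != TUMOR_CLASS]
        if len(normals) != len(set(normals)):
            raise ValueError("a normal-tissue label occurs more than once")


def assign_with_uniqueness(
    prob_matrix,
    region_ids=None,
    classes=TISSUE_CLASSES,
    tumor_class: str = TUMOR_CLASS,
    eps: float = PROB_FLOOR,
) -> TissueAssignment:
    """Exact maximum-log-probability labelling under the sole-occurrence rule.

    Builds a cost matrix with one column per normal-tissue class and, when the
    tumor class is available, one tumor column per region, then solves the
    rectangular assignment problem.  The ``eps`` floor keeps zero
    probabilities finite in the log objective.
    """
    p = np.asarray(prob_matrix, dtype=float)
    if p.ndim != 2:
        raise ValueError("prob_matrix must be 2-D (regions x classes)")
    n_regions, n_classes = p.shape
    classes = tuple(classes)
    if n_classes != len(classes):
        raise ValueError("prob_matrix columns must match classes")
    if region_ids is None:
        region_ids = tuple(range(n_regions))
    region_ids = tuple(region_ids)
    if n_regions == 0:
        return TissueAssignment((), classes, p.reshape(0, n_classes), (), 0.0)

    logp = np.log(p + eps)
    has_tumor = tumor_class in classes
    col_classes = [c for c in classes if c != tumor_class]
    cost_cols = [-logp[:, classes.index(c)] for c in col_classes]
    if has_tumor:
        t = -logp[:, classes.index(tumor_class)]
        cost_cols.extend([t] * n_regions)
        col_classes.extend([tumor_class] * n_regions)
    elif n_regions > len(col_classes):
        raise ValueError(
            "more regions than available singleton classes and no tumor class"
        )
    cost = np.stack(cost_cols, axis=1)
    rows, cols = linear_sum_assignment(cost)
    labels = [None] * n_regions
    objective = 0.0
    for r, c in zip(rows, cols):
        labels[r] = col_classes[c]
        objective += -cost[r, c]
    return TissueAssignment(
        region_ids=region_ids,
        classes=classes,
        prob_matrix=p,
        labels=tuple(labels),
        objective=float(objective),
    )


class ConstrainedTissueClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over radiomics features with per-scan label uniqueness.

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 50; doubled when texture features are added).
    criterion, max_depth, max_features : forwarded to the CART trees; defaults
        are Gini impurity, unlimited depth and sqrt(p) features per split.
    random_state : int or None
        Seed for bootstrap resampling and split randomisation.
    enforce_uniqueness : bool
        Apply the sole-occurrence constraint in ``predict`` when per-scan
        groups are supplied.

    Attributes
    ----------
    forest_ : fitted RandomForestClassifier
    classes_ : class labels seen in training
    oob_error_ : out-of-bag misclassification fraction
    feature_names_ : training feature column order (frozen into the model)
    """

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        criterion: str = "gini",
        max_depth=None,
        max_features="sqrt",
        random_state=None,
        enforce_uniqueness: bool = True,
    ):
        self.n_trees = n_trees
        self.criterion = criterion
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state
        self.enforce_uniqueness = enforce_uniqueness

    # -- fitting ------------------------------------------------------------

    def _as_matrix(self, X, fitting: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if not fitting:
                if names != self.feature_names_:
                    missing = set(self.feature_names_) - set(names)
                    if missing:
                        raise ValueError(f"missing feature columns: {sorted(missing)}")
                    extra = set(names) - set(self.feature_names_)
                    if extra:
                        raise ValueError(f"unknown feature columns: {sorted(extra)}")
                    X = X[self.feature_names_]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(values.shape[1])]
            if not fitting and values.shape[1] != len(self.feature_names_):
                raise ValueError("feature count does not match the fitted model")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains missing or non-finite values")
        return values, names

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        values, names = self._as_matrix(X, fitting=True)
        y = np.asarray(y)
        if y.shape[0] != values.shape[0]:
            raise ValueError("feature/label length mismatch")
        if np.unique(y).size < 2:
            raise ValueError("training data must contain at least 2 classes")
        self.feature_names_ = names
        self.n_features_in_ = values.shape[1]
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion=self.criterion,
            max_depth=self.max_depth,
            max_features=self.max_features,
            bootstrap=True,
            oob_score=self.n_trees >= 10,
            random_state=self.random_state,
            n_jobs=1,
            class_weight=None,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
            self.forest_.fit(values, y)
        self.classes_ = self.forest_.classes_
        self.oob_error_ = (
            1.0 - float(self.forest_.oob_score_) if self.n_trees >= 10 else np.nan
        )
        return self

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Per-region class probabilities as the fraction of trees voting
        each class (combinatorial decision among the trees)."""
        check_is_fitted(self, "forest_")
        values, _ = self._as_matrix(X, fitting=False)
        n = values.shape[0]
        k = len(self.classes_)
        votes = np.zeros((n, k))
        class_index = {c: j for j, c in enumerate(self.classes_)}
        for tree in self.forest_.estimators_:
            pred = self.forest_.classes_[
                np.argmax(tree.predict_proba(values), axis=1)
            ]
            for j, c in enumerate(self.classes_):
                votes[:, j] += pred == c
        return votes / self.forest_.n_estimators

    def predict(self, X, groups=None) -> np.ndarray:
        """Labels; with ``groups`` (per-scan ids) the sole-occurrence
        constraint is enforced within each group."""
        proba = self.predict_proba(X)
        if groups is None or not self.enforce_uniqueness:
            return self.classes_[np.argmax(proba, axis=1)]
        groups = np.asarray(groups)
        if groups.shape[0] != proba.shape[0]:
            raise ValueError("groups must align with rows of X")
        labels = np.empty(proba.shape[0], dtype=object)
        for g in pd.unique(groups):
            sel = np.flatnonzero(groups == g)
            assignment = assign_with_uniqueness(
                proba[sel], region_ids=sel, classes=tuple(self.classes_)
            )
            labels[sel] = assignment.labels
        return labels

    def assign(self, X, groups) -> list[TissueAssignment]:
        """Per-scan TissueAssignment objects (probabilities + labels)."""
        proba = self.predict_proba(X)
        groups = np.asarray(groups)
        out = []
        for g in pd.unique(groups):
            sel = np.flatnonzero(groups == g)
            out.append(
                assign_with_uniqueness(
                    proba[sel], region_ids=sel, classes=tuple(self.classes_)
                )
            )
        return out


def evaluate_holdout(model, X, truth_labels, groups=None) -> pd.DataFrame:
    """Hold-out report: correctly-classified / total, per tissue and overall.

    Mirrors the train-on-one-cohort / test-on-the-other protocol; pass the
    per-scan grouping to evaluate under the sole-occurrence constraint.
    """
    truth = np.asarray(truth_labels)
    if truth.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(X, groups=groups)
    rows = []
    for cls in sorted(set(truth)):
        sel = truth == cls
        rows.append(
            {
                "tissue": cls,
                "correct": int((pred[sel] == cls).sum()),
                "total": int(sel.sum()),
            }
        )
    rows.append(
        {"tissue": "overall", "correct": int((pred == truth).sum()), "total": truth.size}
    )
    df = pd.DataFrame(rows)
    df["accuracy"] = df["correct"] / df["total"]
    return df


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_BUNDLE_VERSION = 1


def save_model(model: ConstrainedTissueClassifier, path) -> None:
    """Persist a fitted model as a joblib bundle with embedded metadata."""
    import joblib

    check_is_fitted(model, "forest_")
    bundle = {
        "metadata": json.dumps(
            {
                "bundle_version": _BUNDLE_VERSION,
                "feature_names": model.feature_names_,
                "classes": [str(c) for c in model.classes_],
                "n_trees": model.n_trees,
                "oob_error": None if np.isnan(model.oob_error_) else model.oob_error_,
            }
        ),
        "model": model,
    }
    joblib.dump(bundle, path)


def load_model(path) -> ConstrainedTissueClassifier:
    import joblib

    bundle = joblib.load(path)
    meta = json.loads(bundle["metadata"])
    if meta.get("bundle_version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version: {meta.get('bundle_version')}")
    model = bundle["model"]
    if list(model.feature_names_) != list(meta["feature_names"]):
        raise ValueError("model bundle metadata does not match the stored ensemble")
    return model
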