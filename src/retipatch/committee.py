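"""Class-imbalance committee: balanced undersampled partitions + soft voting.

Patch datasets are heavily imbalanced (lesions cover well under 1% of a
retinal image), so a single classifier overfits the healthy majority.  The
committee protocol trains ``T = round(M/N)`` base classifiers, where ``M``
and ``N`` are the healthy and pathological sample counts of the training
fold: the healthy samples are randomly permuted and split into ``T``
near-equal subsets, and base model ``t`` is fit on *all* pathological samples
joined with healthy subset ``t`` — every healthy sample is used exactly once.
At test time the committee score is the arithmetic mean of the members'
pathological-class probabilities (soft majority voting); a patch is called
pathological when that score is *strictly greater* than the decision
threshold ``delta`` (0.5 unless optimized on validation data).

Cross-validation is grouped by image: patches from one image never straddle
the train/test boundary.  Within each training fold a validation sub-fold of
images can be held out to optimize ``delta`` on the ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, GroupShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import evaluation

CLASSIFIER_KINDS = ("random_forest", "linear_svm", "rbf_svm", "gaussian_process")


@dataclass(frozen=True)
class CommitteeConfig:
    """Committee and cross-validation parameters."""

    classifier_kind: str = "rbf_svm"
    k_folds: int = 5
    delta: float = 0.5
    optimize_delta: bool = False
    rng_seed: int = 0
    n_trees: int = 200
    svm_c: float = 1.0
    rbf_gamma: float | str = "auto"  # "auto" = 1/n_features
    gp_length_scale: float = 1.0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.classifier_kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier_kind {self.classifier_kind!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")


@dataclass
class CommitteeModel:
    """T trained base classifiers plus the voting rule and threshold."""

    base_models: list
    delta: float
    n_features: int
    classifier_kind: str
    rng_seed: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def t(self) -> int:
        return len(self.base_models)


def make_base_classifier(config: CommitteeConfig, seed: int):
    """One standardizing pipeline around the configured classifier.

    The StandardScaler stage realizes the per-block feature standardization:
    it is fit on each base model's own balanced training subset.
    """
    kind = config.classifier_kind
    if kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=config.n_trees, random_state=seed)
    elif kind == "linear_svm":
        clf = CalibratedClassifierCV(
            SVC(kernel="linear", C=config.svm_c, random_state=seed), ensemble=False
        )
    elif kind == "rbf_svm":
        clf = CalibratedClassifierCV(
            SVC(kernel="rbf", C=config.svm_c, gamma=config.rbf_gamma, random_state=seed),
            ensemble=False,
        )
    else:  # gaussian_process
        clf = GaussianProcessClassifier(
            kernel=1.0 * RBF(length_scale=config.gp_length_scale), random_state=seed
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def healthy_partitions(
    healthy_idx: np.ndarray, t: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random permutation of the healthy indices split into ``t`` near-equal
    subsets (sizes differ by at most one; remainders spread one per subset)."""
    perm = rng.permutation(healthy_idx)
    return list(np.array_split(perm, t))


def train_committee(
    X: np.ndarray, y: np.ndarray, config: CommitteeConfig = CommitteeConfig()
) -> CommitteeModel:
    """Fit the balanced committee on a training fold.

    ``y`` is binary with 1 = pathological.  ``T = round(M/N)``; a training
    fold with more pathological than healthy samples degenerates to ``T = 1``
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    healthy_idx = np.flatnonzero(y == 0)
    path_idx = np.flatnonzero(y == 1)
    m, n = len(healthy_idx), len(path_idx)
    if m == 0 or n == 0:
        raise ValueError(f"both classes required to train a committee (M={m}, N={n})")
    if m < n:
        warnings.warn(
            f"healthy class is the minority (M={m} < N={n}); degenerating to a single model"
        )
        t = 1
    else:
        t = max(1, _round_half_up(m / n))
    rng = np.random.default_rng(config.rng_seed)
    subsets = healthy_partitions(healthy_idx, t, rng)
    base_models = []
    for k, subset in enumerate(subsets):
        idx = np.concatenate([path_idx, subset])
        model = make_base_classifier(config, seed=config.rng_seed + k)
        model.fit(X[idx], y[idx])
        base_models.append(model)
    return CommitteeModel(
        base_models=base_models,
        delta=config.delta,
        n_features=X.shape[1],
        classifier_kind=config.classifier_kind,
        rng_seed=config.rng_seed,
        extra={"M": m, "N": n, "subset_sizes": [len(s) for s in subsets]},
    )


def predict_proba(model: CommitteeModel, X: np.ndarray) -> np.ndarray:
    """Soft majority vote: mean pathological-class probability over members."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature matrix with {X.shape[1] if X.ndim == 2 else '?'} columns does not "
            f"match the model schema ({model.n_features})"
        )
    probs = [m.predict_proba(X)[:, list(m.classes_).index(1)] for m in model.base_models]
    return np.mean(probs, axis=0)


def predict_label(
    model: CommitteeModel, X: np.ndarray, delta: float | None = None
) -> np.ndarray:
    """Pathological iff the committee probability is strictly above ``delta``."""
    thr = model.delta if delta is None else delta
    return (predict_proba(model, X) > thr).astype(int)


def _fold_metrics(y_true, prob, delta) -> dict:
    pred = (prob > delta).astype(int)
    counts = evaluation.confusion(y_true, pred)
    metrics = evaluation.metrics_from_counts(counts)
    if len(np.unique(y_true)) == 2:
        metrics["auc"] = evaluation.roc_auc(prob, y_true).auc
    else:
        warnings.warn("single-class test fold: AUC undefined, reported as NaN")
        metrics["auc"] = float("nan")
    metrics["delta"] = delta
    return metrics


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: CommitteeConfig = CommitteeConfig(),
    leave_one_image_out: bool = False,
) -> pd.DataFrame:
    """Image-grouped K-fold cross-validation of the committee.

    Images (groups) are partitioned into K folds so patches from one image
    never leak between train and test.  When ``config.optimize_delta`` is
    set, a validation sub-fold of training images is held out per fold and
    ``delta`` is chosen there at the sensitivity/specificity balance point;
    otherwise the configured ``delta`` is used.  Returns one row per fold
    plus ``mean`` and ``std`` summary rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    unique_groups = np.unique(groups)
    k = len(unique_groups) if leave_one_image_out else config.k_folds
    if len(unique_groups) < k:
        raise ValueError(f"{len(unique_groups)} images cannot fill {k} folds")
    splitter = GroupKFold(n_splits=k, shuffle=True, random_state=config.rng_seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y, groups)):
        delta = config.delta
        fit_idx = train_idx
        if config.optimize_delta:
            gss = GroupShuffleSplit(
                n_splits=1,
                test_size=config.validation_fraction,
                random_state=config.rng_seed + fold,
            )
            sub_fit, sub_val = next(gss.split(X[train_idx], y[train_idx], groups[train_idx]))
            fit_idx, val_idx = train_idx[sub_fit], train_idx[sub_val]
            if len(np.unique(y[val_idx])) == 2 and len(np.unique(y[fit_idx])) == 2:
                model = train_committee(X[fit_idx], y[fit_idx], config)
                roc = evaluation.roc_auc(predict_proba(model, X[val_idx]), y[val_idx])
                delta = evaluation.optimal_delta(roc)
            else:
                fit_idx = train_idx  # validation split unusable; fall back
        model = train_committee(X[fit_idx], y[fit_idx], config)
        prob = predict_proba(model, X[test_idx])
        row = {"fold": fold, "n_test": len(test_idx)}
        row.update(_fold_metrics(y[test_idx], prob, delta))
        rows.append(row)
    table = pd.DataFrame(rows)
    numeric = table.drop(columns=["fold", "n_test"])
    summary = pd.DataFrame(
        {
            **{"fold": ["mean", "std"], "n_test": [table["n_test"].mean(), table["n_test"].std(ddof=1)]},
            **{c: [numeric[c].mean(), numeric[c].std(ddof=1)] for c in numeric.columns},
        }
    )
    return pd.concat([table, summary], ignore_index=True)


def save_model(model: CommitteeModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> CommitteeModel:
    return joblib.load(path)
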