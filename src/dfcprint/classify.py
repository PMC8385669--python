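"""L1-penalized classification of a binary label from DFC coefficients.

The label (e.g. sex, coded male=0 / female=1) is regressed on the profile
coefficients with an L1 (lasso) penalty, which doubles as a feature
selector: only a sparse subset of coefficients receives nonzero weight.
Performance is estimated by Monte-Carlo cross-validation: repeated random
80/20 train/test splits, the training split age-matched between classes,
with the held-out AUC (area under the ROC curve) recorded per repeat and
per-coefficient selection frequencies aggregated.  The penalty strength is
chosen within each training split by internal 5-fold cross-validation of
the squared-error (0/1 regression) objective; ROC analysis uses the raw
continuous scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_auc_score

from .errors import AlignmentError, InsufficientDataError
from .group_stats import age_matched_subsets

logger = logging.getLogger(__name__)


@dataclass
class SparseLinearModel:
    """Standardization parameters plus lasso weights from one training split."""

    feature_mean: np.ndarray
    feature_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    alpha: float

    @property
    def selected(self) -> np.ndarray:
        return np.nonzero(self.coef != 0)[0]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.feature_mean) / self.feature_scale
        return Z @ self.coef + self.intercept


@dataclass
class ClassificationRun:
    models: list[SparseLinearModel]
    aucs: np.ndarray
    selection_frequency: np.ndarray
    n_repeats: int
    train_fraction: float

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    @property
    def auc_range(self) -> tuple[float, float]:
        return float(self.aucs.min()), float(self.aucs.max())

    @property
    def n_selected(self) -> np.ndarray:
        return np.array([m.selected.size for m in self.models])


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InsufficientDataError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def fit_l1_model(train_profiles: np.ndarray, train_labels: np.ndarray,
                 cv: int = 5, seed: int | None = None,
                 max_iter: int = 5000) -> SparseLinearModel:
    """Lasso fit of 0/1 labels on standardized features.

    Features are standardized with the training split's own mean and
    standard deviation (constant features get unit scale); the penalty is
    chosen by ``cv``-fold cross-validation over the lasso path.
    """
    X = np.asarray(train_profiles, dtype=np.float64)
    y = np.asarray(train_labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("training labels contain a single class")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    model = LassoCV(cv=cv, random_state=seed, max_iter=max_iter, n_jobs=1)
    model.fit(Z, y)
    return SparseLinearModel(mu, sd, model.coef_.copy(), float(model.intercept_),
                             float(model.alpha_))


def monte_carlo_cv(profiles: np.ndarray, meta: pd.DataFrame,
                   label_column: str = "sex", positive_level: str = "F",
                   n_repeats: int = 500, train_fraction: float = 0.8,
                   seed: int | None = None, age_match: bool = True,
                   internal_cv: int = 5) -> ClassificationRun:
    """Repeated random-split cross-validation of the lasso classifier.

    Each repeat holds out ``1 - train_fraction`` of subjects, age-matches
    the two classes within the remaining training set (one random matched
    draw), fits the model and scores the held-out AUC.  Splits whose test
    set lacks a class are redrawn (logged).
    """
    X = np.asarray(profiles, dtype=np.float64)
    y = (meta[label_column].to_numpy() == positive_level).astype(float)
    ages = meta["age"].to_numpy() if "age" in meta else np.zeros(len(meta))
    n = X.shape[0]
    if n != len(meta):
        raise AlignmentError("profile rows must match metadata rows")
    n_train = int(round(train_fraction * n))
    if not (2 <= n_train <= n - 1):
        raise InsufficientDataError("train fraction leaves no usable split")
    rng = np.random.default_rng(seed)
    models: list[SparseLinearModel] = []
    aucs = np.empty(n_repeats)
    sel_freq = np.zeros(X.shape[1])
    for r in range(n_repeats):
        for _attempt in range(100):
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            if len(np.unique(y[test_idx])) == 2 and len(np.unique(y[train_idx])) == 2:
                break
            logger.info("repeat %d: single-class split redrawn", r)
        else:  # pragma: no cover
            raise InsufficientDataError("could not draw a two-class test split")
        if age_match:
            tr_meta = pd.DataFrame({
                label_column: meta[label_column].to_numpy()[train_idx],
                "age": ages[train_idx],
            })
            sub = age_matched_subsets(tr_meta, label_column, n_repeats=1,
                                      seed=int(rng.integers(2**31)))[0]
            train_idx = train_idx[sub]
            if len(np.unique(y[train_idx])) < 2:  # pragma: no cover
                continue
        m = fit_l1_model(X[train_idx], y[train_idx], cv=internal_cv,
                         seed=int(rng.integers(2**31)))
        scores = m.decision_scores(X[test_idx])
        aucs[r] = auc(scores, y[test_idx])
        sel_freq[m.selected] += 1
        models.append(m)
    return ClassificationRun(models, aucs, sel_freq, n_repeats, train_fraction)


def apply_model(run: ClassificationRun, profiles: np.ndarray,
                labels: np.ndarray | None = None) -> dict:
    """Score an external cohort with every per-repeat model.

    Returns per-repeat AUCs (mean and SD) and the scores of the averaged
    model.  With labels of a single class (or none), AUC is reported as
    missing.
    """
    X = np.asarray(profiles, dtype=np.float64)
    if X.shape[1] != run.models[0].coef.size:
        raise AlignmentError("feature space does not match the trained models")
    all_scores = np.stack([m.decision_scores(X) for m in run.models])
    out: dict = {"mean_scores": all_scores.mean(axis=0)}
    if labels is not None and len(np.unique(labels)) == 2:
        per_repeat = np.array([auc(s, labels) for s in all_scores])
        out.update(auc_mean=float(per_repeat.mean()), auc_sd=float(per_repeat.std()),
                   auc_per_repeat=per_repeat,
                   auc_mean_model=auc(out["mean_scores"], labels))
    else:
        out.update(auc_mean=None, auc_sd=None, auc_per_repeat=None,
                   auc_mean_model=None)
    return out
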