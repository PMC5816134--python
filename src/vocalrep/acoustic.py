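"""Aligning objective acoustic features with perceptual naming.

The acoustic space is a weighted Euclidean feature space: per-feature
nonnegative weights are learned by maximizing the Mantel-style Pearson
correlation between the weighted acoustic distance matrix and a reference
(semantic) distance matrix.  Subset selection happens through weights
shrinking to zero.  The weighted space is summarized by PCA, visualized
through a multinomial decision map on the first two components, and used to
classify call types with a random forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import recall_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .datatypes import AcousticFeatureTable, DistanceMatrix, ValidationError
from .synthdata import _SOUND_LABELS, _SOUND_LABEL_TYPE

#: Pooling of fine-grained sound names into the six major call types plus
#: a residual "other" category; unmapped labels fall into "other".
MAJOR7_MAP: dict[str, str] = {
    lab: typ
    for lang in _SOUND_LABELS
    for lab, typ in zip(_SOUND_LABELS[lang], _SOUND_LABEL_TYPE[lang])
}
MAJOR7_CATEGORIES = ("laugh", "cry", "scream", "moan", "sigh", "roar", "other")


@dataclass
class AcousticEmbedding:
    pc_scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    stimuli: tuple[str, ...]
    features: tuple[str, ...]


# ---------------------------------------------------------------------------
# Standardization and weighted distances
# ---------------------------------------------------------------------------

def standardize_features(table: AcousticFeatureTable) -> AcousticFeatureTable:
    """Z-score each feature (population sd)."""
    X = table.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s <= 0:
            raise ValidationError(f"feature {table.features[j]!r} is constant")
    return AcousticFeatureTable(table.stimuli, table.features, (X - mu) / sd)


def weighted_distance_matrix(table: AcousticFeatureTable,
                             weights: Sequence[float]) -> DistanceMatrix:
    """Euclidean distances after per-feature scaling by the weights."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(table.features),):
        raise ValidationError("weights must align with the feature list")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValidationError("at least one weight must be positive")
    D = squareform(pdist(table.values * w))
    return DistanceMatrix(table.stimuli, D)


def matrix_correlation(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 0,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Pearson correlation over the strict upper triangles of two distance
    matrices, with an optional Mantel permutation test (rows and columns of
    the second matrix permuted jointly)."""
    if d1.stimuli != d2.stimuli:
        raise ValidationError("distance matrices must share the stimulus ordering")
    a, b = d1.upper_triangle(), d2.upper_triangle()
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("correlation undefined for a constant distance matrix")
    r = float(stats.pearsonr(a, b)[0])
    if permutations <= 0:
        return r, None
    rng = np.random.default_rng(seed)
    n = d2.n
    count = 1
    for _ in range(permutations):
        perm = rng.permutation(n)
        bp = d2.values[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        if abs(float(stats.pearsonr(a, bp)[0])) >= abs(r):
            count += 1
    return r, count / (permutations + 1)


# ---------------------------------------------------------------------------
# Metric-weight learning
# ---------------------------------------------------------------------------

class DistanceMetricLearner(BaseEstimator):
    """Learn nonnegative per-feature weights maximizing the Mantel
    correlation between the weighted acoustic distances and a reference
    distance matrix.

    Optimization is multi-start Nelder-Mead on log-weights followed by
    greedy zero-drop moves (setting a weight exactly to zero and keeping the
    drop when the correlation improves), so feature-subset selection and
    weighting use one mechanism.  Never returns a solution below the
    uniform-weights baseline.
    """

    def __init__(self, n_starts: int = 5, seed: int = 0,
                 maxiter: int = 2000, tol: float = 1e-10):
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter
        self.tol = tol

    def fit(self, table: AcousticFeatureTable, reference: DistanceMatrix):
        if table.stimuli != reference.stimuli:
            raise ValidationError("feature table and reference must share stimuli")
        X = table.values
        ref = reference.upper_triangle()
        if ref.std() == 0:
            raise ValidationError("reference distances are constant")
        p = X.shape[1]

        def corr_of(w):
            d = pdist(X * w)
            sd = d.std()
            if sd == 0:
                return -1.0
            return float(np.corrcoef(d, ref)[0, 1])

        def neg_corr_log(logw, active):
            w = np.zeros(p)
            w[active] = np.exp(np.clip(logw, -20, 20))
            return -corr_of(w)

        rng = np.random.default_rng(self.seed)
        uniform = np.ones(p)
        best_w, best_r = uniform.copy(), corr_of(uniform)
        baseline_r = best_r

        starts = [np.zeros(p)]
        starts += [rng.normal(scale=1.0, size=p) for _ in range(self.n_starts - 1)]
        for logw0 in starts:
            active = np.arange(p)
            res = optimize.minimize(
                neg_corr_log, logw0[active], args=(active,), method="Nelder-Mead",
                options={"maxiter": self.maxiter, "xatol": 1e-6, "fatol": 1e-12})
            w = np.zeros(p)
            w[active] = np.exp(np.clip(res.x, -20, 20))
            r = corr_of(w)
            # greedy zero-drop moves with re-polish
            improved = True
            while improved and np.count_nonzero(w) > 1:
                improved = False
                for j in np.flatnonzero(w):
                    w_try = w.copy()
                    w_try[j] = 0.0
                    r_try = corr_of(w_try)
                    if r_try > r + self.tol:
                        w, r = w_try, r_try
                        improved = True
                if improved:
                    active = np.flatnonzero(w)
                    res = optimize.minimize(
                        neg_corr_log, np.log(w[active]), args=(active,),
                        method="Nelder-Mead",
                        options={"maxiter": self.maxiter, "xatol": 1e-6, "fatol": 1e-12})
                    w2 = np.zeros(p)
                    w2[active] = np.exp(np.clip(res.x, -20, 20))
                    r2 = corr_of(w2)
                    if r2 > r:
                        w, r = w2, r2
            if r > best_r:
                best_w, best_r = w, r

        self.fallback_uniform_ = False
        if best_r < baseline_r:
            warnings.warn("optimizer failed to improve over uniform weights")
            best_w, best_r = uniform, baseline_r
            self.fallback_uniform_ = True
        nz = best_w[best_w > 0]
        if nz.size:
            best_w = best_w / nz.mean()  # correlation is scale-free; mean weight 1
        self.weights_ = best_w
        self.achieved_correlation_ = best_r
        self.features_ = table.features
        return self

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights_, index=list(self.features_), name="weight")


def optimize_weights(
    features: AcousticFeatureTable,
    reference_distances: DistanceMatrix,
    n_starts: int = 5,
    seed: int = 0,
) -> DistanceMetricLearner:
    return DistanceMetricLearner(n_starts=n_starts, seed=seed).fit(
        features, reference_distances)


# ---------------------------------------------------------------------------
# PCA of the weighted acoustic space
# ---------------------------------------------------------------------------

def acoustic_pca(table: AcousticFeatureTable, k: int = 2) -> AcousticEmbedding:
    """SVD-based PCA of the (already standardized and weight-scaled)
    feature table; loading-column signs fixed so the largest-magnitude entry
    of each column is positive."""
    X = table.values - table.values.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = max(rank, 1)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    var = s ** 2
    return AcousticEmbedding(
        pc_scores=scores,
        loadings=loadings,
        explained_variance=var[:k] / var.sum(),
        stimuli=table.stimuli,
        features=table.features,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def multinomial_decision_map(
    pc_scores_2d: np.ndarray,
    labels: Sequence[str],
    grid_resolution: int = 100,
    ridge: float = 1e-4,
) -> dict:
    """Multinomial logistic fit on two PC scores plus a predicted-class grid
    for decision-region visualization."""
    X = np.asarray(pc_scores_2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValidationError("pc_scores_2d must have exactly 2 columns")
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValidationError("need at least 2 classes")
    model = LogisticRegression(C=1.0 / ridge, max_iter=5000)
    model.fit(X, y)
    pad = 0.05 * (X.max(axis=0) - X.min(axis=0) + 1e-9)
    gx = np.linspace(X[:, 0].min() - pad[0], X[:, 0].max() + pad[0], grid_resolution)
    gy = np.linspace(X[:, 1].min() - pad[1], X[:, 1].max() + pad[1], grid_resolution)
    GX, GY = np.meshgrid(gx, gy)
    grid_pred = model.predict(np.column_stack([GX.ravel(), GY.ravel()]))
    return {
        "model": model,
        "grid_x": gx,
        "grid_y": gy,
        "grid_class": grid_pred.reshape(GX.shape),
        "train_accuracy": float(model.score(X, y)),
    }


def pool_major7(labels: Sequence[str],
                synonym_map: dict[str, str] | None = None) -> np.ndarray:
    """Map fine-grained sound names to the six major call types + 'other'."""
    m = MAJOR7_MAP if synonym_map is None else synonym_map
    return np.array([m.get(lab, "other") for lab in labels])


def calltype_classifier_accuracy(
    features: AcousticFeatureTable,
    labels: Sequence[str],
    pooling: str = "full",
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
    synonym_map: dict[str, str] | None = None,
) -> dict:
    """Stratified cross-validated random-forest accuracy of predicting each
    stimulus's (modal) sound name from its acoustic features."""
    if pooling not in ("full", "major7"):
        raise ValidationError("pooling must be 'full' or 'major7'")
    y = np.asarray([str(l) for l in labels])
    if len(y) != len(features.stimuli):
        raise ValidationError("labels must align with the feature table")
    if pooling == "major7":
        y = pool_major7(y, synonym_map)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least 2 call-type classes")
    folds = cv_folds
    if counts.min() < cv_folds:
        folds = max(2, int(counts.min()))
        warnings.warn(f"smallest class has {counts.min()} instances; "
                      f"reducing folds to {folds}")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, features.values, y, cv=cv)
    acc = float((pred == y).mean())
    recalls = recall_score(y, pred, labels=classes, average=None, zero_division=0)
    baseline = float(counts.max() / counts.sum())
    return {
        "accuracy": acc,
        "per_class_recall": dict(zip(classes.tolist(), recalls.tolist())),
        "majority_baseline": baseline,
        "cv_folds": folds,
        "pooling": pooling,
    }
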