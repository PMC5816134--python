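"""Semantic spaces of sound and emotion names.

The more often two stimuli received the same label, the closer they sit:
per-stimulus label-choice profiles give pairwise Euclidean distances, which
are embedded by classical (Torgerson) MDS and clustered by affinity
propagation, with the exemplar preference set to a sample quantile ``q`` of
the off-diagonal similarities.  Cluster quality is measured by the mean
silhouette index and by the adjusted Rand index against the partition
defined by each stimulus's most common name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .datatypes import DistanceMatrix, NamingTrial, ValidationError


@dataclass
class LabelProfileMatrix:
    """Per-stimulus label-choice proportions (rows sum to 1)."""

    stimuli: tuple[str, ...]
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.stimuli), len(self.labels)):
            raise ValidationError("profile shape must be (n_stimuli, n_labels)")
        if self.values.min(initial=0.0) < 0:
            raise ValidationError("profile values must be nonnegative")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("profile rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.stimuli), columns=list(self.labels))


@dataclass
class SpaceEmbedding:
    coords: np.ndarray
    explained_variance: np.ndarray
    method: str
    stimuli: tuple[str, ...]


@dataclass
class ClusterSolution:
    stimuli: tuple[str, ...]
    assignment: np.ndarray      # cluster index per stimulus
    exemplars: tuple[int, ...]  # stimulus indices acting as exemplars
    q: float
    damping: float
    converged: bool
    silhouette: float | None = None
    ari_vs_reference: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def exemplar_ids(self) -> tuple[str, ...]:
        return tuple(self.stimuli[i] for i in self.exemplars)


# ---------------------------------------------------------------------------
# Profiles and distances
# ---------------------------------------------------------------------------

def name_profile_matrix(
    trials: Iterable[NamingTrial],
    label_set: Sequence[str],
    name_kind: str = "sound",
) -> LabelProfileMatrix:
    """Count label choices per stimulus and normalize to proportions.

    Multi-label trials contribute one count per chosen label.
    """
    if name_kind not in ("sound", "emotion"):
        raise ValidationError("name_kind must be 'sound' or 'emotion'")
    labels = tuple(label_set)
    pos = {lab: i for i, lab in enumerate(labels)}
    counts: dict[str, np.ndarray] = {}
    for t in trials:
        chosen = t.sound_names if name_kind == "sound" else t.emotion_names
        row = counts.setdefault(t.stimulus, np.zeros(len(labels)))
        for lab in chosen:
            if lab not in pos:
                raise ValidationError(f"label {lab!r} not in label_set")
            row[pos[lab]] += 1
    if not counts:
        raise ValidationError("no trials supplied")
    stimuli = tuple(sorted(counts))
    values = np.vstack([counts[s] for s in stimuli])
    empty = [stimuli[i] for i in np.flatnonzero(values.sum(axis=1) == 0)]
    if empty:
        raise ValidationError(f"stimuli with zero {name_kind}-name choices: {empty}")
    values = values / values.sum(axis=1, keepdims=True)
    return LabelProfileMatrix(stimuli, labels, values)


def cooccurrence_distances(profiles: LabelProfileMatrix) -> DistanceMatrix:
    """Euclidean distances between per-stimulus label-proportion rows."""
    diff = profiles.values[:, None, :] - profiles.values[None, :, :]
    return DistanceMatrix(profiles.stimuli, np.sqrt((diff ** 2).sum(axis=2)))


def average_distance_matrices(matrices: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Element-wise mean of distance matrices sharing a stimulus ordering."""
    if not matrices:
        raise ValidationError("need at least one matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.stimuli != ref.stimuli:
            raise ValidationError("all matrices must share the same stimulus ordering")
    return DistanceMatrix(ref.stimuli, np.mean([m.values for m in matrices], axis=0))


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

class ClassicalMDS(BaseEstimator):
    """Torgerson MDS: eigendecomposition of the double-centered squared
    distance matrix; explained variance = eigenvalue shares among the
    nonnegative eigenvalues."""

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, distances: DistanceMatrix):
        D = distances.values
        n = D.shape[0]
        if self.n_components > n - 1:
            raise ValidationError("n_components must be <= n - 1")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        tol = max(1e-12, 1e-9 * max(vals.max(initial=0.0), 1.0))
        npos = int((vals > tol).sum())
        k = self.n_components
        if k > npos:
            warnings.warn(
                f"only {npos} nonnegative eigenvalues; truncating embedding from {k}")
            k = max(npos, 1)
        pos = np.clip(vals[:k], 0.0, None)
        self.coords_ = vecs[:, :k] * np.sqrt(pos)
        total = vals[:npos].sum() if npos else 1.0
        self.explained_variance_ratio_ = pos / total
        self.eigenvalues_ = vals
        self.stimuli_ = distances.stimuli
        return self

    def fit_transform(self, distances: DistanceMatrix) -> np.ndarray:
        return self.fit(distances).coords_


def embed_space(distances: DistanceMatrix, k: int = 3) -> SpaceEmbedding:
    mds = ClassicalMDS(n_components=k).fit(distances)
    return SpaceEmbedding(
        coords=mds.coords_,
        explained_variance=mds.explained_variance_ratio_,
        method="classical_mds",
        stimuli=distances.stimuli,
    )


def embed_profiles(profiles: LabelProfileMatrix, k: int = 3) -> SpaceEmbedding:
    """PCA on centered profile rows; coincides with classical MDS of the
    Euclidean profile distances up to sign."""
    X = profiles.values - profiles.values.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(s))
    var = s ** 2
    return SpaceEmbedding(
        coords=(U * s)[:, :k],
        explained_variance=var[:k] / var.sum(),
        method="pca_on_profiles",
        stimuli=profiles.stimuli,
    )


# ---------------------------------------------------------------------------
# Modal-name clusters and weighted centroids
# ---------------------------------------------------------------------------

def modal_clusters(
    trials: Iterable[NamingTrial],
    label_set: Sequence[str],
    name_kind: str = "sound",
) -> pd.DataFrame:
    """Most commonly chosen name per stimulus (the reference partition).

    Exact ties break to the lowest-index label in ``label_set`` order and are
    flagged in the ``tie`` column.
    """
    profiles = name_profile_matrix(trials, label_set, name_kind)
    rows = []
    for i, s in enumerate(profiles.stimuli):
        row = profiles.values[i]
        best = int(np.argmax(row))  # argmax takes the lowest index on ties
        tie = bool((row == row[best]).sum() > 1)
        rows.append({"stimulus": s, "modal_label": profiles.labels[best],
                     "modal_proportion": float(row[best]), "tie": tie})
    return pd.DataFrame(rows).set_index("stimulus")


def weighted_centroids(
    embedding: SpaceEmbedding,
    assignment: Sequence,
    certainty_by_stimulus: Sequence[float],
    modal_proportion: Sequence[float],
) -> pd.DataFrame:
    """Prototypicality-adjusted centroids: weighted mean of cluster member
    coordinates with weights = mean certainty x modal-name proportion."""
    assignment = np.asarray(assignment)
    w = np.asarray(certainty_by_stimulus, dtype=float) * np.asarray(modal_proportion, dtype=float)
    if w.min(initial=0.0) < 0:
        raise ValidationError("weights must be nonnegative")
    out = {}
    for c in pd.unique(assignment):
        mask = assignment == c
        if w[mask].sum() <= 0:
            raise ValidationError(f"cluster {c!r} has all-zero weights")
        out[c] = (embedding.coords[mask] * w[mask, None]).sum(axis=0) / w[mask].sum()
    df = pd.DataFrame.from_dict(out, orient="index",
                                columns=[f"dim{i+1}" for i in range(embedding.coords.shape[1])])
    df.index.name = "cluster"
    return df


# ---------------------------------------------------------------------------
# Affinity propagation
# ---------------------------------------------------------------------------

class AffinityPropagationQ(BaseEstimator):
    """Affinity propagation on a distance matrix with quantile preference.

    Similarities are negative squared distances; every self-similarity
    (preference) is set to the ``q``-quantile of the off-diagonal
    similarities, tuning the algorithm's propensity to split (high q) or
    lump (low q).  Message passing runs with the given damping until the
    exemplar set is stable for ``conv_iter`` iterations; non-convergence is
    reported through ``converged_``, never silently.
    """

    def __init__(self, q: float = 0.5, damping: float = 0.9,
                 max_iter: int = 1000, conv_iter: int = 50):
        self.q = q
        self.damping = damping
        self.max_iter = max_iter
        self.conv_iter = conv_iter

    def fit(self, distances: DistanceMatrix):
        if not (0.0 <= self.q <= 1.0):
            raise ValidationError("q must lie in [0, 1]")
        if not (0.5 <= self.damping < 1.0):
            raise ValidationError("damping must lie in [0.5, 1)")
        D = distances.values
        n = D.shape[0]
        if n == 1:
            self.labels_ = np.zeros(1, dtype=int)
            self.exemplar_indices_ = (0,)
            self.converged_ = True
            self.preference_ = 0.0
            self.stimuli_ = distances.stimuli
            return self

        S = -(D ** 2)
        off = S[~np.eye(n, dtype=bool)]
        pref = float(np.quantile(off, self.q))
        np.fill_diagonal(S, pref)
        self.preference_ = pref

        exemplars, converged = _ap_message_passing(
            S, self.damping, self.max_iter, self.conv_iter)
        labels, exemplars = _ap_assign(S, exemplars)
        self.labels_ = labels
        self.exemplar_indices_ = exemplars
        self.converged_ = converged
        self.stimuli_ = distances.stimuli
        return self

    def fit_predict(self, distances: DistanceMatrix) -> np.ndarray:
        return self.fit(distances).labels_


def _ap_message_passing(S, damping, max_iter, conv_iter):
    n = S.shape[0]
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    prev = None
    stable = 0
    converged = False
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        first_k = AS.argmax(axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        tmp = np.maximum(R, 0.0)
        tmp[idx, idx] = R[idx, idx]
        tmp = tmp.sum(axis=0)[None, :] - tmp
        dA = tmp[idx, idx].copy()
        Anew = np.minimum(tmp, 0.0)
        Anew[idx, idx] = dA
        A = damping * A + (1 - damping) * Anew

        exemplars = np.flatnonzero(np.diag(A) + np.diag(R) > 0)
        key = exemplars.tobytes()
        if exemplars.size and key == prev:
            stable += 1
            if stable >= conv_iter:
                converged = True
                break
        else:
            stable = 0
        prev = key
    if exemplars.size == 0:
        # degenerate: fall back to the best single medoid, flagged unconverged
        exemplars = np.array([int(np.argmax(S.sum(axis=0)))])
        converged = False
    return exemplars, converged


def _net_similarity_of(S, exemplars: np.ndarray) -> float:
    """AP objective for an exemplar set: each point pays its similarity to
    its best exemplar; exemplars pay their preference (diagonal of S)."""
    sub = S[:, exemplars].max(axis=1)
    sub[exemplars] = S[exemplars, exemplars]
    return float(sub.sum())


_EXACT_N = 12  # exemplar sets are enumerated exactly up to this size


def _ap_assign(S, exemplars):
    """Finalize the exemplar set and assign points to their best exemplar.

    For instances small enough to enumerate (n <= 12) the exemplar set
    maximizing net similarity is found exactly; larger instances get a
    greedy add/remove/swap polish (k-medoids-style local search) from two
    starts — the message-passing solution and the best single medoid —
    keeping the better local optimum."""
    n = S.shape[0]
    if n <= _EXACT_N:
        ex = _ap_exact(S)
    else:
        starts = [tuple(int(e) for e in exemplars),
                  (int(np.argmax(S.sum(axis=0))),)]
        ex = max((_ap_polish(S, st) for st in starts), key=lambda t: t[1])[0]
    new_ex = np.array(sorted(ex))
    labels = new_ex[np.argmax(S[:, new_ex], axis=1)]
    labels[new_ex] = new_ex
    # relabel clusters 0..k-1 in exemplar order
    uniq = np.unique(labels)
    remap = {e: c for c, e in enumerate(uniq)}
    return np.array([remap[e] for e in labels]), tuple(int(e) for e in uniq)


def _ap_exact(S):
    """Exhaustive search over nonempty exemplar subsets (tiny n only)."""
    n = S.shape[0]
    best_val, best_set = -np.inf, {0}
    for mask in range(1, 1 << n):
        idx = np.flatnonzero([(mask >> i) & 1 for i in range(n)])
        val = _net_similarity_of(S, idx)
        if val > best_val:
            best_val, best_set = val, set(int(i) for i in idx)
    return best_set


def _ap_polish(S, exemplars):
    n = S.shape[0]
    ex = set(exemplars)
    best = _net_similarity_of(S, np.fromiter(ex, int))
    improved = True
    while improved:
        improved = False
        for move in ("swap", "add", "remove"):
            for e in sorted(ex) if move != "add" else []:
                if move == "remove" and len(ex) > 1:
                    cand = ex - {e}
                    val = _net_similarity_of(S, np.fromiter(cand, int))
                    if val > best + 1e-12:
                        ex, best, improved = cand, val, True
                elif move == "swap":
                    for j in range(n):
                        if j in ex:
                            continue
                        cand = (ex - {e}) | {j}
                        val = _net_similarity_of(S, np.fromiter(cand, int))
                        if val > best + 1e-12:
                            ex, best, improved = cand, val, True
                            break
            if move == "add":
                for j in range(n):
                    if j in ex:
                        continue
                    cand = ex | {j}
                    val = _net_similarity_of(S, np.fromiter(cand, int))
                    if val > best + 1e-12:
                        ex, best, improved = cand, val, True
    return ex, best


def affinity_propagation(
    distances: DistanceMatrix,
    q: float = 0.5,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
) -> ClusterSolution:
    model = AffinityPropagationQ(q=q, damping=damping,
                                 max_iter=max_iter, conv_iter=conv_iter).fit(distances)
    sol = ClusterSolution(
        stimuli=distances.stimuli,
        assignment=model.labels_,
        exemplars=model.exemplar_indices_,
        q=q, damping=damping,
        converged=model.converged_,
    )
    if 2 <= sol.n_clusters <= distances.n - 1:
        sol.silhouette = silhouette_index(distances, sol.assignment)
    return sol


def net_similarity(distances: DistanceMatrix, q: float,
                   assignment: np.ndarray, exemplars: Sequence[int]) -> float:
    """The affinity-propagation objective: sum of similarities of points to
    their exemplars plus the preferences of the exemplars."""
    S = -(distances.values ** 2)
    off = S[~np.eye(S.shape[0], dtype=bool)]
    pref = float(np.quantile(off, q))
    np.fill_diagonal(S, pref)
    exemplars = list(exemplars)
    total = 0.0
    for i, c in enumerate(assignment):
        total += S[i, exemplars[c]] if i != exemplars[c] else pref
    return total


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

def silhouette_index(distances: DistanceMatrix, assignment: Sequence) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b); singletons and degenerate
    a = b = 0 points contribute 0."""
    labels = np.asarray(assignment)
    if len(np.unique(labels)) < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    return float(silhouette_score(distances.values, labels, metric="precomputed"))


def adjusted_rand(assignment_a: Sequence, assignment_b: Sequence) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    a, b = np.asarray(assignment_a), np.asarray(assignment_b)
    if a.shape != b.shape:
        raise ValidationError("partitions must cover the same stimuli")
    return float(adjusted_rand_score(a, b))


def q_sweep(
    distances: DistanceMatrix,
    reference_assignment: Sequence,
    q_grid: Sequence[float],
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
) -> pd.DataFrame:
    """Sweep the preference quantile and report clustering quality per q."""
    qs = sorted(dict.fromkeys(float(q) for q in q_grid))
    if not qs:
        raise ValidationError("q grid must be nonempty")
    ref = np.asarray(reference_assignment)
    rows = []
    for q in qs:
        sol = affinity_propagation(distances, q=q, damping=damping,
                                   max_iter=max_iter, conv_iter=conv_iter)
        sil = sol.silhouette if sol.silhouette is not None else np.nan
        rows.append({
            "q": q,
            "n_clusters": sol.n_clusters,
            "silhouette": sil,
            "ari": adjusted_rand(sol.assignment, ref),
            "converged": sol.converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cladograms
# ---------------------------------------------------------------------------

def hierarchical_cladogram(items_distances: DistanceMatrix) -> np.ndarray:
    """Agglomerative average-linkage tree; returns the scipy linkage matrix."""
    if items_distances.n < 2:
        raise ValidationError("need at least 2 items to build a tree")
    condensed = squareform(items_distances.values, checks=False)
    return linkage(condensed, method="average")


def cladogram_newick(items_distances: DistanceMatrix,
                     labels: Sequence[str] | None = None) -> str:
    """Average-linkage tree in Newick text with branch lengths."""
    Z = hierarchical_cladogram(items_distances)
    labels = list(labels) if labels is not None else list(items_distances.stimuli)
    root = to_tree(Z)

    def _walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(root, root.dist).rsplit(":", 1)[0] + ";"
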