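import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform

import vocalrep.semspace as ss
from vocalrep.datatypes import DistanceMatrix, NamingTrial, ValidationError


def _trial(stimulus, sound=("laugh",), emotion=("joy",), participant="p0"):
    return NamingTrial(participant=participant, language="english",
                       stimulus=stimulus, sound_names=tuple(sound),
                       emotion_names=tuple(emotion), certainty_sound=3,
                       certainty_emotion=3, t_first_sound=2.0,
                       t_first_emotion=3.0, t_next=8.0, layout="sound_left")


def _dm(X):
    return DistanceMatrix([f"s{i}" for i in range(len(X))],
                          squareform(pdist(np.atleast_2d(X))))


LABELS = ("laugh", "moan", "groan")


class TestProfiles:
    def test_pure_and_mixed_counts(self):
        trials = [_trial("s1", ("laugh",), participant=f"p{i}") for i in range(10)]
        trials += [_trial("s2", ("moan",), participant=f"p{i}") for i in range(3)]
        trials += [_trial("s2", ("groan",), participant="p9")]
        prof = ss.name_profile_matrix(trials, LABELS, "sound")
        df = prof.to_frame()
        assert df.loc["s1"].tolist() == [1.0, 0.0, 0.0]
        assert df.loc["s2", "moan"] == pytest.approx(0.75)
        assert df.loc["s2", "groan"] == pytest.approx(0.25)

    def test_multilabel_counts_once_per_label(self):
        trials = [_trial("s1", ("laugh", "moan"))]
        prof = ss.name_profile_matrix(trials, LABELS, "sound")
        assert prof.to_frame().loc["s1"].tolist() == [0.5, 0.5, 0.0]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            ss.name_profile_matrix([_trial("s1", ("shout",))], LABELS, "sound")

    def test_distance_invariant_to_duplicating_trials(self):
        trials = [_trial("s1", ("laugh",)), _trial("s2", ("moan",)),
                  _trial("s2", ("laugh",), participant="p1")]
        d1 = ss.cooccurrence_distances(ss.name_profile_matrix(trials, LABELS, "sound"))
        d2 = ss.cooccurrence_distances(ss.name_profile_matrix(trials * 3, LABELS, "sound"))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


class TestCooccurrenceDistances:
    @pytest.mark.parametrize("rows,expected", [
        ([[1, 0], [0, 1]], np.sqrt(2)),
        ([[1, 0], [1, 0]], 0.0),
        ([[1, 0], [0.5, 0.5]], np.sqrt(0.5)),
    ])
    def test_hand_values(self, rows, expected):
        prof = ss.LabelProfileMatrix(("a", "b"), ("x", "y"), np.array(rows, float))
        d = ss.cooccurrence_distances(prof)
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-4)


class TestAverageDistances:
    def test_idempotent_linear_single(self):
        D = _dm(np.random.default_rng(0).normal(size=(4, 2)))
        same = ss.average_distance_matrices([D, D])
        np.testing.assert_allclose(same.values, D.values, atol=1e-12)
        tripled = DistanceMatrix(D.stimuli, 3 * D.values)
        avg = ss.average_distance_matrices([D, tripled])
        np.testing.assert_allclose(avg.values, 2 * D.values, atol=1e-12)
        single = ss.average_distance_matrices([D])
        np.testing.assert_allclose(single.values, D.values, atol=1e-12)

    def test_mismatched_stimuli_rejected(self):
        D = _dm(np.zeros((3, 1)))
        other = DistanceMatrix(["x", "y", "z"], D.values)
        with pytest.raises(ValidationError):
            ss.average_distance_matrices([D, other])


class TestEmbedSpace:
    def test_collinear_points_need_one_dimension(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        emb = ss.embed_space(D, k=2)
        assert emb.explained_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_exact_recovery_of_euclidean_distances(self, rng):
        X = rng.normal(size=(20, 3))
        emb = ss.embed_space(_dm(X), k=3)
        np.testing.assert_allclose(pdist(emb.coords), pdist(X), atol=1e-8)

    def test_unit_square_splits_variance_evenly(self):
        X = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        emb = ss.embed_space(_dm(X), k=2)
        assert emb.explained_variance[0] == pytest.approx(0.5, abs=1e-9)
        assert emb.explained_variance[1] == pytest.approx(0.5, abs=1e-9)

    def test_matches_skbio_pcoa(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa
        X = rng.normal(size=(12, 3))
        D = _dm(X)
        emb = ss.embed_space(D, k=3)
        ref = pcoa(D.values, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(emb.coords), np.abs(ref.samples.to_numpy()), atol=1e-8)
        np.testing.assert_allclose(
            emb.explained_variance, ref.proportion_explained.to_numpy(),
            atol=1e-8)

    def test_pca_on_profiles_matches_mds_on_euclidean_profiles(self, rng):
        P = rng.dirichlet(np.ones(4), size=8)
        prof = ss.LabelProfileMatrix(tuple(f"s{i}" for i in range(8)),
                                     ("a", "b", "c", "d"), P)
        mds = ss.embed_space(ss.cooccurrence_distances(prof), k=2)
        pca = ss.embed_profiles(prof, k=2)
        np.testing.assert_allclose(pdist(mds.coords[:, :2]),
                                   pdist(pca.coords[:, :2]), atol=1e-8)


class TestModalClusters:
    def test_modal_label_and_tiebreak(self):
        trials = [_trial("s1", ("laugh",), participant=f"p{i}") for i in range(3)]
        trials += [_trial("s1", ("moan",), participant="p4")]
        trials += [_trial("s2", ("laugh",)), _trial("s2", ("moan",), participant="p1")]
        trials += [_trial("s3", ("groan",))]
        out = ss.modal_clusters(trials, LABELS, "sound")
        assert out.loc["s1", "modal_label"] == "laugh"
        assert out.loc["s1", "modal_proportion"] == pytest.approx(0.75)
        assert not out.loc["s1", "tie"]
        # exact tie: lowest-index label in label_set order, flagged
        assert out.loc["s2", "modal_label"] == "laugh"
        assert out.loc["s2", "tie"]
        assert out.loc["s3", "modal_proportion"] == 1.0


class TestWeightedCentroids:
    def test_hand_cases(self):
        emb = ss.SpaceEmbedding(np.array([[0.0], [3.0], [7.0]]),
                                np.array([1.0]), "classical_mds",
                                ("a", "b", "c"))
        cents = ss.weighted_centroids(emb, ["c1", "c1", "c2"],
                                      [2.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert cents.loc["c1", "dim1"] == pytest.approx(1.0)  # (2*0 + 1*3)/3
        assert cents.loc["c2", "dim1"] == pytest.approx(7.0)  # singleton

    def test_equal_weights_are_plain_mean(self):
        emb = ss.SpaceEmbedding(np.array([[1.0], [5.0]]), np.array([1.0]),
                                "classical_mds", ("a", "b"))
        cents = ss.weighted_centroids(emb, ["c", "c"], [1, 1], [0.5, 0.5])
        assert cents.loc["c", "dim1"] == pytest.approx(3.0)

    def test_zero_weight_cluster_rejected(self):
        emb = ss.SpaceEmbedding(np.array([[1.0], [5.0]]), np.array([1.0]),
                                "classical_mds", ("a", "b"))
        with pytest.raises(ValidationError):
            ss.weighted_centroids(emb, ["c", "c"], [0, 0], [1, 1])


def _brute_force_best(D, q):
    S = -(D.values ** 2)
    n = S.shape[0]
    off = S[~np.eye(n, dtype=bool)]
    pref = float(np.quantile(off, q))
    np.fill_diagonal(S, pref)
    best = -np.inf
    best_set = None
    for r in range(1, n + 1):
        for E in itertools.combinations(range(n), r):
            sub = S[:, list(E)].max(axis=1)
            sub[list(E)] = pref
            val = float(sub.sum())
            if val > best:
                best, best_set = val, E
    return best, best_set


class TestAffinityPropagation:
    def test_single_point(self):
        sol = ss.affinity_propagation(DistanceMatrix(["a"], np.zeros((1, 1))))
        assert sol.exemplars == (0,)
        assert sol.converged

    def test_two_tight_pairs_found(self):
        X = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0]], float)
        D = _dm(X)
        sol = ss.affinity_propagation(D, q=0.5)
        assert sol.n_clusters == 2
        assert sol.assignment[0] == sol.assignment[1]
        assert sol.assignment[2] == sol.assignment[3]
        best, _ = _brute_force_best(D, 0.5)
        assert ss.net_similarity(D, 0.5, sol.assignment, sol.exemplars) == \
            pytest.approx(best, abs=1e-9)

    def test_high_preference_never_fewer_exemplars(self, rng):
        X = rng.normal(size=(7, 2))
        D = _dm(X)
        _, set_lo = _brute_force_best(D, 0.0)
        _, set_hi = _brute_force_best(D, 1.0)
        assert len(set_hi) >= len(set_lo)
        sol_lo = ss.affinity_propagation(D, q=0.0)
        sol_hi = ss.affinity_propagation(D, q=1.0)
        if sol_lo.converged and sol_hi.converged:
            assert sol_hi.n_clusters >= sol_lo.n_clusters

    def test_nonconvergence_is_flagged_not_silent(self):
        D = _dm(np.zeros((4, 1)))  # identical points: degenerate
        sol = ss.affinity_propagation(D, q=0.5, max_iter=5, conv_iter=50)
        assert sol.converged is False
        assert len(sol.assignment) == 4

    def test_matches_sklearn_on_well_separated_data(self, rng):
        from sklearn.cluster import AffinityPropagation as SkAP
        X = np.vstack([rng.normal(loc, 0.2, size=(5, 2))
                       for loc in ([0, 0], [6, 0], [0, 6])])
        D = _dm(X)
        sol = ss.affinity_propagation(D, q=0.5)
        S = -(D.values ** 2)
        off = S[~np.eye(15, dtype=bool)]
        sk = SkAP(affinity="precomputed", damping=0.9,
                  preference=float(np.quantile(off, 0.5)), random_state=0).fit(S)
        assert ss.adjusted_rand(sol.assignment, sk.labels_) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [{"q": 1.5}, {"damping": 0.4}, {"damping": 1.0}])
    def test_parameter_validation(self, bad):
        with pytest.raises(ValidationError):
            ss.affinity_propagation(_dm(np.zeros((2, 1))), **bad)


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        D = _dm(np.array([[0.0], [0.1], [10.0], [10.1]]))
        s = ss.silhouette_index(D, [0, 0, 1, 1])
        assert s == pytest.approx(0.99, abs=1e-2)

    def test_identical_points_degenerate_zero(self):
        D = _dm(np.zeros((4, 1)))
        assert ss.silhouette_index(D, [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            ss.silhouette_index(_dm(np.zeros((3, 1))), [0, 0, 0])


class TestAdjustedRand:
    def test_identity_and_relabeling(self):
        assert ss.adjusted_rand([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert ss.adjusted_rand([0, 0, 1, 1], [5, 5, 2, 2]) == 1.0

    def test_hand_case(self):
        assert ss.adjusted_rand([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_symmetric(self, rng):
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 4, size=30)
        assert ss.adjusted_rand(a, b) == pytest.approx(ss.adjusted_rand(b, a))

    def test_near_zero_under_random_permutation(self, rng):
        a = np.repeat([0, 1, 2, 3], 10)
        vals = []
        for _ in range(1000):
            vals.append(ss.adjusted_rand(a, rng.permutation(a)))
        assert abs(np.mean(vals)) < 0.02


class TestQSweep:
    def test_duplicates_deduplicated_and_rows_reported(self, rng):
        X = np.vstack([rng.normal(loc, 0.3, size=(6, 2))
                       for loc in ([0, 0], [5, 0])])
        D = _dm(X)
        ref = np.repeat([0, 1], 6)
        out = ss.q_sweep(D, ref, [0.3, 0.3, 0.5])
        assert out["q"].tolist() == [0.3, 0.5]
        assert {"n_clusters", "silhouette", "ari", "converged"} <= set(out.columns)
        assert out["ari"].max() == pytest.approx(1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            ss.q_sweep(_dm(np.zeros((3, 1))), [0, 0, 0], [])


class TestCladogram:
    def test_first_merge_is_closest_pair(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], float))
        Z = ss.hierarchical_cladogram(D)
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert Z[0, 2] == pytest.approx(1.0)

    def test_ultrametric_heights_preserved(self):
        # ultrametric: d(a,b)=2, d(a,c)=d(b,c)=6
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
        Z = ss.hierarchical_cladogram(D)
        from scipy.cluster.hierarchy import cophenet
        np.testing.assert_allclose(cophenet(Z), [2, 6, 6], atol=1e-12)

    def test_two_items_and_newick(self):
        D = DistanceMatrix(["a", "b"], np.array([[0, 3.0], [3.0, 0]]))
        Z = ss.hierarchical_cladogram(D)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(3.0)
        nwk = ss.cladogram_newick(D)
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "a" in nwk and "b" in nwk

    def test_single_item_rejected(self):
        with pytest.raises(ValidationError):
            ss.hierarchical_cladogram(DistanceMatrix(["a"], np.zeros((1, 1))))


@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6))
def test_mds_eigen_shares_sorted_and_bounded(diag):
    # random 1-D configurations always give valid embeddings
    X = np.cumsum(diag)[:, None]
    emb = ss.embed_space(_dm(X), k=min(2, len(diag) - 1))
    ev = emb.explained_variance
    assert np.all(ev >= -1e-12) and np.all(ev <= 1 + 1e-12)
    assert np.all(np.diff(ev) <= 1e-12)
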