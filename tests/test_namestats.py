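import numpy as np
import pytest
from hypothesis import given, strategies as st

import vocalrep.namestats as ns
import vocalrep.synthdata as sd
from vocalrep.datatypes import NamingTrial, ValidationError


def _trial(**kw):
    base = dict(participant="p0", language="english", stimulus="s0",
                sound_names=("laugh",), emotion_names=("joy",),
                certainty_sound=3, certainty_emotion=2,
                t_first_sound=2.0, t_first_emotion=3.0, t_next=8.0,
                layout="sound_left")
    base.update(kw)
    return NamingTrial(**base)


def _entropy_oracle(a, n_alt):
    """Independent direct evaluation of the normalized entropy formula."""
    a = np.asarray(a, float)
    p = a / a.sum()
    total = 0.0
    for pi in p:
        if pi > 0:
            total -= np.log2(pi) * pi
    return total / np.log2(n_alt) * 100.0


class TestNormalizedEntropy:
    def test_uniform_is_100(self):
        assert ns.normalized_entropy([5, 5, 5, 5]) == pytest.approx(100.0)

    def test_degenerate_is_0(self):
        assert ns.normalized_entropy([10, 0, 0, 0]) == pytest.approx(0.0)

    def test_printed_formula_hand_case(self):
        assert ns.normalized_entropy([3, 1]) == pytest.approx(81.13, abs=0.01)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 17))
            a = rng.integers(0, 30, size=n)
            if a.sum() == 0:
                a[0] = 1
            assert ns.normalized_entropy(a, n) == pytest.approx(
                _entropy_oracle(a, n), abs=1e-10)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=16).filter(
        lambda a: sum(a) > 0),
        st.integers(2, 20))
    def test_permutation_and_scale_invariance(self, counts, k):
        a = np.array(counts)
        base = ns.normalized_entropy(a)
        assert ns.normalized_entropy(a[::-1]) == pytest.approx(base, abs=1e-9)
        assert ns.normalized_entropy(a * k) == pytest.approx(base, abs=1e-9)
        assert -1e-9 <= base <= 100 + 1e-9

    def test_bounds_sharp(self):
        # 100 iff uniform over all alternatives; 0 iff a single nonzero entry
        assert ns.normalized_entropy([2, 2, 2]) == pytest.approx(100.0)
        assert ns.normalized_entropy([2, 2, 0]) < 100.0
        assert ns.normalized_entropy([0, 7]) == pytest.approx(0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            ns.normalized_entropy([0, 0, 0])


class TestEntropyContrast:
    def test_identical_vectors_interval_contains_zero(self, rng):
        e = rng.uniform(20, 80, size=50)
        fit = ns.entropy_contrast(e, e, seed=1)
        d = fit.fixed_effects["difference_emotion_minus_sound"]
        assert d["ci_low"] <= 0 <= d["ci_high"]
        assert abs(fit.fixed_effects["cohens_d"]["mean"]) < 0.05

    def test_recovers_true_difference_across_replicates(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            es = rng.normal(50, 5, size=132)
            ee = es + rng.normal(10, 5, size=132)
            fit = ns.entropy_contrast(es, ee, n_draws=2000, seed=rep)
            mean = fit.fixed_effects["difference_emotion_minus_sound"]["mean"]
            hits += (8.0 <= mean <= 12.0)
        assert hits >= 45  # >= 90% of replicates

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            ns.entropy_contrast([1, 2], [1, 2])


class TestRTModel:
    def test_parameter_recovery_at_scale(self, default_world, english_lexicon):
        trials = sd.simulate_naming(default_world, english_lexicon, 50,
                                    sd.GenParams(), seed=31)
        fit = ns.fit_rt_model(trials, seed=32)
        eff = fit.fixed_effects["kind_emotion_minus_sound"]
        assert eff["mean"] == pytest.approx(0.2, abs=0.05)
        assert fit.diagnostics["ess"]["kind_emotion_minus_sound"] > 100

    def test_cutoff_removes_everything_is_error(self):
        trials = [_trial(t_first_sound=100.0, t_first_emotion=120.0,
                         t_next=130.0, participant=f"p{i}", stimulus=f"s{i}")
                  for i in range(4)]
        with pytest.raises(ValidationError):
            ns.fit_rt_model(trials)

    def test_single_grouping_level_rejected(self):
        trials = [_trial(participant="p0", stimulus=f"s{i}") for i in range(5)]
        with pytest.raises(ValidationError):
            ns.fit_rt_model(trials)


class TestCertaintyModel:
    def test_positive_latent_shift_recovered(self, small_world):
        # sound prototypes better separated than emotion -> positive contrast
        lex = sd.default_lexicon(small_world, "english", seed=2)
        trials = sd.simulate_naming(small_world, lex, 25, sd.GenParams(), seed=41)
        fit = ns.fit_certainty_model(trials, n_iter=2000, warmup=1000, seed=42)
        assert fit.fixed_effects["kind_sound_minus_emotion"]["mean"] > 0
        probs = fit.diagnostics["category_probabilities"]
        total = sum(v["mean"] for v in probs["sound"].values())
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_certainty_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            _trial(certainty_sound=4)

    def test_single_category_rejected(self):
        trials = [_trial(certainty_sound=3, certainty_emotion=3,
                         participant=f"p{i}") for i in range(4)]
        with pytest.raises(ValidationError):
            ns.fit_certainty_model(trials, n_iter=100, warmup=50)


class TestOrderPreference:
    def test_layout_only_behavior_covers_or_one(self):
        trials = sd.simulate_order_trials(40, 60, pref_log_odds=0.0,
                                          layout_log_odds=4.0, seed=51)
        fit = ns.order_preference(trials, seed=52)
        d = fit.fixed_effects["log_preference"]
        assert d["ci_low"] <= 0 <= d["ci_high"]

    def test_true_or_5_recovered(self):
        trials = sd.simulate_order_trials(50, 100, pref_log_odds=np.log(5.0),
                                          layout_log_odds=2.0, seed=53)
        fit = ns.order_preference(trials, seed=54)
        assert 3.5 <= fit.fixed_effects["odds_ratio"]["median"] <= 7.0

    def test_single_layout_rejected(self):
        trials = [_trial(participant=f"p{i}") for i in range(6)]
        with pytest.raises(ValidationError):
            ns.order_preference(trials)


class TestContingency:
    def test_diagonal_table_chi2(self):
        trials = []
        for i in range(10):
            trials.append(_trial(sound_names=("laugh",), emotion_names=("joy",),
                                 participant=f"p{i}"))
            trials.append(_trial(sound_names=("moan",), emotion_names=("pain",),
                                 participant=f"p{i}", stimulus="s1"))
        tab = ns.sound_emotion_contingency(trials)
        assert tab.chi2 == pytest.approx(20.0)
        assert tab.df == 1

    def test_independent_uniform_chi2_zero(self):
        trials = []
        k = 0
        for s in ("laugh", "moan"):
            for e in ("joy", "pain"):
                for _ in range(5):
                    trials.append(_trial(sound_names=(s,), emotion_names=(e,),
                                         participant=f"p{k}"))
                    k += 1
        tab = ns.sound_emotion_contingency(trials)
        assert tab.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_closed_form_on_random_2x2(self, rng):
        # oracle: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            trials = []
            k = 0
            for (s, e), count in zip(
                    [("laugh", "joy"), ("laugh", "pain"),
                     ("moan", "joy"), ("moan", "pain")], (a, b, c, d)):
                for _ in range(count):
                    trials.append(_trial(sound_names=(s,), emotion_names=(e,),
                                         participant=f"p{k}"))
                    k += 1
            tab = ns.sound_emotion_contingency(trials)
            n = a + b + c + d
            oracle = n * (a * d - b * c) ** 2 / \
                ((a + b) * (c + d) * (a + c) * (b + d))
            assert tab.chi2 == pytest.approx(oracle, abs=1e-10)

    def test_df_from_full_label_lists(self):
        trials = [_trial(sound_names=(s,), emotion_names=(e,), participant=f"p{i}")
                  for i, (s, e) in enumerate([("laugh", "joy"), ("moan", "pain"),
                                              ("cry", "grief")])]
        tab = ns.sound_emotion_contingency(trials)
        assert tab.counts.shape == (3, 3)
        assert tab.df == 4  # (3-1) * (3-1)

    def test_clustered_ordering_is_a_permutation(self, naming_trials):
        tab = ns.sound_emotion_contingency(naming_trials)
        assert sorted(tab.row_order()) == sorted(tab.rows)
        assert sorted(tab.col_order()) == sorted(tab.cols)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ns.sound_emotion_contingency([_trial(sound_names=(), emotion_names=())])


class TestEmotionFromName:
    def test_deterministic_mapping_perfect(self):
        trials = []
        mapping = {"laugh": "joy", "cry": "grief", "moan": "pain"}
        for i in range(30):
            s = list(mapping)[i % 3]
            trials.append(_trial(sound_names=(s,), emotion_names=(mapping[s],),
                                 participant=f"p{i}"))
        out = ns.emotion_from_name_accuracy(trials, cv_folds=5, seed=0)
        assert out["accuracy"] == pytest.approx(1.0)

    def test_shuffled_labels_near_majority_baseline(self, rng):
        sounds = ["laugh", "cry", "moan", "sigh"]
        emotions = ["joy", "grief", "pain", "relief"]
        trials = [
            _trial(sound_names=(rng.choice(sounds),),
                   emotion_names=(rng.choice(emotions),), participant=f"p{i}")
            for i in range(400)]
        out = ns.emotion_from_name_accuracy(trials, cv_folds=5, seed=1)
        baseline = max(np.bincount([emotions.index(t.emotion_names[0])
                                    for t in trials])) / 400
        assert out["accuracy"] == pytest.approx(baseline, abs=0.05)

    def test_single_emotion_rejected(self):
        trials = [_trial(participant=f"p{i}") for i in range(10)]
        with pytest.raises(ValidationError):
            ns.emotion_from_name_accuracy(trials)
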