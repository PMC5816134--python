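"""Consistency, speed, certainty and meaning of naming responses.

Covers: normalized Shannon entropy of the names chosen per stimulus (0% =
perfect agreement, 100% = uniform over all alternatives), a Bayesian paired
contrast of sound-name vs emotion-name entropy, a lognormal response-time
model and a cumulative-logit certainty model with crossed random intercepts
for stimulus and participant, the response-order preference (odds of naming
the sound first, net of screen layout), and the sound-name x emotion-name
contingency analysis (chi-square plus a tree-ensemble prediction of the
emotion from the chosen sound name).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from ._samplers import gibbs_crossed_gaussian, mh_crossed_glmm, summarize_draws
from .datatypes import DistanceMatrix, NamingTrial, ValidationError
from .semspace import hierarchical_cladogram

__all__ = [
    "HierarchicalFit", "ContingencyTable", "normalized_entropy",
    "stimulus_name_entropies", "entropy_contrast", "fit_rt_model",
    "fit_certainty_model", "order_preference", "sound_emotion_contingency",
    "emotion_from_name_accuracy",
]


@dataclass
class HierarchicalFit:
    """Posterior summaries of a hierarchical model fit."""

    fixed_effects: dict
    random_effect_sds: dict
    posterior_draws: dict
    diagnostics: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fixed_effects).T


@dataclass
class ContingencyTable:
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: np.ndarray
    chi2: float = np.nan
    df: int = 0
    p_value: float = np.nan

    def to_frame(self, clustered: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.rows), columns=list(self.cols))
        if clustered:
            df = df.loc[self.row_order(), self.col_order()]
        return df

    def _profile_order(self, M: np.ndarray, labels: Sequence[str]) -> list[str]:
        if len(labels) < 2:
            return list(labels)
        P = M / np.maximum(M.sum(axis=1, keepdims=True), 1e-12)
        D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(axis=2))
        Z = hierarchical_cladogram(DistanceMatrix(labels, D))
        from scipy.cluster.hierarchy import leaves_list
        return [labels[i] for i in leaves_list(Z)]

    def row_order(self) -> list[str]:
        """Row labels ordered by average-linkage clustering of row profiles."""
        return self._profile_order(self.counts, self.rows)

    def col_order(self) -> list[str]:
        return self._profile_order(self.counts.T, self.cols)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def normalized_entropy(counts: Sequence[float], n_alternatives: int | None = None) -> float:
    """Shannon entropy of the choice counts, normalized by log2 of the
    number of alternative labels, in percent (0 * log 0 := 0)."""
    a = np.asarray(counts, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValidationError("counts must be a vector of length >= 2")
    if np.any(a < 0):
        raise ValidationError("counts must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValidationError("counts must not be all zero")
    n_alt = int(n_alternatives) if n_alternatives is not None else a.size
    p = a / total
    nz = p > 0
    h = -(p[nz] * np.log2(p[nz])).sum()
    return float(h / np.log2(n_alt) * 100.0)


def stimulus_name_entropies(
    trials: Iterable[NamingTrial],
    label_set: Sequence[str],
    name_kind: str = "sound",
) -> pd.Series:
    """Normalized entropy of all names chosen for each stimulus."""
    trials = list(trials)
    counts: dict[str, np.ndarray] = {}
    pos = {lab: i for i, lab in enumerate(label_set)}
    for t in trials:
        chosen = t.sound_names if name_kind == "sound" else t.emotion_names
        row = counts.setdefault(t.stimulus, np.zeros(len(label_set)))
        for lab in chosen:
            if lab not in pos:
                raise ValidationError(f"label {lab!r} not in label_set")
            row[pos[lab]] += 1
    out = {s: normalized_entropy(c, len(label_set))
           for s, c in sorted(counts.items()) if c.sum() > 0}
    return pd.Series(out, name=f"entropy_{name_kind}")


def entropy_contrast(
    entropies_sound: Sequence[float],
    entropies_emotion: Sequence[float],
    n_draws: int = 4000,
    seed: int = 0,
) -> HierarchicalFit:
    """Bayesian Gaussian model on paired per-stimulus entropy differences
    (emotion minus sound) with a noninformative prior; reports the mean
    difference, its 95% interval and Cohen's d."""
    es = np.asarray(entropies_sound, float)
    ee = np.asarray(entropies_emotion, float)
    if es.shape != ee.shape:
        raise ValidationError("paired entropy vectors must have equal length")
    n = es.size
    if n < 3:
        raise ValidationError("need at least 3 paired stimuli")
    d = ee - es
    rng = np.random.default_rng(seed)
    # Normal model, Jeffreys prior: sigma^2 ~ scaled-inv-chi2, mu | sigma ~ N
    s2 = d.var(ddof=1)
    if s2 == 0:  # identical pairs: point-mass posterior at the observed mean
        sigma2 = np.zeros(n_draws)
        mu = np.full(n_draws, d.mean())
        cohens_d = np.zeros(n_draws)
    else:
        sigma2 = (n - 1) * s2 / rng.chisquare(n - 1, size=n_draws)
        mu = rng.normal(d.mean(), np.sqrt(sigma2 / n))
        cohens_d = mu / np.sqrt(sigma2)
    fixed = {
        "difference_emotion_minus_sound": summarize_draws(mu),
        "cohens_d": summarize_draws(cohens_d),
    }
    return HierarchicalFit(
        fixed_effects=fixed,
        random_effect_sds={"residual": summarize_draws(np.sqrt(sigma2))},
        posterior_draws={"difference": mu, "cohens_d": cohens_d},
        diagnostics=_ess_diag({"difference": mu}),
    )


def _ess_diag(draw_map: dict) -> dict:
    ess = {}
    for k, v in draw_map.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[k] = float(az.ess(np.asarray(v)[None, :]))
    return {"ess": ess}


# ---------------------------------------------------------------------------
# Response-time model
# ---------------------------------------------------------------------------

def _codes(values: list) -> tuple[np.ndarray, dict]:
    uniq = sorted(set(values))
    m = {v: i for i, v in enumerate(uniq)}
    return np.array([m[v] for v in values]), m


def fit_rt_model(
    trials: Iterable[NamingTrial],
    response: str = "both_long",
    rt_cutoff_s: float = 60.0,
    n_iter: int = 1500,
    warmup: int = 500,
    seed: int = 0,
) -> HierarchicalFit:
    """Gaussian model of log first-click latency with fixed effects for
    name kind and screen side and crossed random intercepts for stimulus and
    participant.  Latencies above ``rt_cutoff_s`` seconds are removed before
    fitting (long online-testing pauses).

    Kind is coded +1/2 for emotion and -1/2 for sound, so the kind effect is
    the emotion-minus-sound contrast on the log-seconds scale; a
    back-transformed millisecond difference at the mean intercept is also
    reported.  Side is coded +1/2 when the named block sat on the right.
    """
    if response not in ("both_long", "first_sound", "first_emotion"):
        raise ValidationError("response must be both_long, first_sound or first_emotion")
    rows = []
    for t in trials:
        for kind, lat in (("sound", t.t_first_sound), ("emotion", t.t_first_emotion)):
            if response == "first_sound" and kind != "sound":
                continue
            if response == "first_emotion" and kind != "emotion":
                continue
            if lat is None or lat > rt_cutoff_s:
                continue
            on_right = (t.layout == "sound_left") == (kind == "emotion")
            rows.append((np.log(lat), 0.5 if kind == "emotion" else -0.5,
                         0.5 if on_right else -0.5, t.participant, t.stimulus))
    if not rows:
        raise ValidationError("no latencies remain after filtering")
    y = np.array([r[0] for r in rows])
    x_kind = np.array([r[1] for r in rows])
    x_side = np.array([r[2] for r in rows])
    g_part, _ = _codes([r[3] for r in rows])
    g_stim, _ = _codes([r[4] for r in rows])
    if g_part.max() < 1 or g_stim.max() < 1:
        raise ValidationError("need at least 2 participants and 2 stimuli")

    cols = [np.ones_like(y), x_side]
    names = ["intercept", "side_right_minus_left"]
    if response == "both_long":
        cols.insert(1, x_kind)
        names.insert(1, "kind_emotion_minus_sound")
    X = np.column_stack(cols)

    res = gibbs_crossed_gaussian(y, X, g_part, g_stim,
                                 n_iter=n_iter, warmup=warmup, seed=seed)
    beta = res["beta"]
    fixed = {nm: summarize_draws(beta[:, i]) for i, nm in enumerate(names)}
    draws = {nm: beta[:, i] for i, nm in enumerate(names)}
    if response == "both_long":
        b0 = beta[:, 0]
        bk = beta[:, 1]
        ms = 1000.0 * np.exp(b0) * (np.exp(bk / 2.0) - np.exp(-bk / 2.0))
        fixed["ms_difference_emotion_minus_sound"] = summarize_draws(ms)
        draws["ms_difference_emotion_minus_sound"] = ms
    sds = {"participant": summarize_draws(res["sd"][:, 0]),
           "stimulus": summarize_draws(res["sd"][:, 1]),
           "residual": summarize_draws(res["sd"][:, 2])}
    return HierarchicalFit(fixed, sds, draws, _ess_diag(draws))


# ---------------------------------------------------------------------------
# Certainty model
# ---------------------------------------------------------------------------

def fit_certainty_model(
    trials: Iterable[NamingTrial],
    n_iter: int = 3000,
    warmup: int = 1500,
    seed: int = 0,
) -> HierarchicalFit:
    """Cumulative-logit model of the 3-level certainty rating with a fixed
    effect of name kind (+1/2 sound, -1/2 emotion; positive = more certain
    for sound names) and random intercepts for participant and stimulus.
    Reports the kind contrast and per-category probabilities by kind."""
    rows = []
    for t in trials:
        for kind, c in (("sound", t.certainty_sound), ("emotion", t.certainty_emotion)):
            if c is None:
                continue
            rows.append((c, 0.5 if kind == "sound" else -0.5, t.participant, t.stimulus))
    if not rows:
        raise ValidationError("no certainty ratings supplied")
    y = np.array([r[0] for r in rows])
    cats = np.unique(y)
    if cats.size == 1:
        raise ValidationError("certainty has a single observed category")
    if cats.size == 2:
        warnings.warn("one certainty category absent; thresholds still estimable")
    x = np.array([r[1] for r in rows])
    g_part, _ = _codes([r[2] for r in rows])
    g_stim, _ = _codes([r[3] for r in rows])

    def row_loglik(theta, re):
        beta, c1, log_dc = theta
        c2 = c1 + np.exp(log_dc)
        eta = beta * x + re
        p1 = _sigmoid(c1 - eta)
        p2 = _sigmoid(c2 - eta)
        probs = np.where(y == 1, p1, np.where(y == 2, p2 - p1, 1.0 - p2))
        return np.log(np.clip(probs, 1e-12, None))

    res = mh_crossed_glmm(row_loglik, 3, g_part, g_stim,
                          n_iter=n_iter, warmup=warmup, seed=seed,
                          theta0=np.array([0.0, -2.0, 0.0]))
    th = res["theta"]
    beta, c1 = th[:, 0], th[:, 1]
    c2 = c1 + np.exp(th[:, 2])
    cat_probs = {}
    for kind, xv in (("sound", 0.5), ("emotion", -0.5)):
        eta = beta * xv
        p1 = _sigmoid(c1 - eta)
        p2 = _sigmoid(c2 - eta)
        cat_probs[kind] = {
            "dont_know": summarize_draws(p1),
            "unsure": summarize_draws(p2 - p1),
            "sure": summarize_draws(1.0 - p2),
        }
    fixed = {"kind_sound_minus_emotion": summarize_draws(beta),
             "cut_1": summarize_draws(c1), "cut_2": summarize_draws(c2)}
    sds = {"participant": summarize_draws(res["sd"][:, 0]),
           "stimulus": summarize_draws(res["sd"][:, 1])}
    fit = HierarchicalFit(fixed, sds, {"kind_sound_minus_emotion": beta},
                          _ess_diag({"kind": beta}))
    fit.diagnostics["category_probabilities"] = cat_probs
    return fit


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))


# ---------------------------------------------------------------------------
# Order preference
# ---------------------------------------------------------------------------

def order_preference(
    trials: Iterable[NamingTrial],
    n_iter: int = 3000,
    warmup: int = 1500,
    seed: int = 0,
) -> HierarchicalFit:
    """Odds ratio for naming the sound before the emotion, net of layout.

    Logistic model ``logit P(sound first) = pref/2 + layout * x + a_p`` with
    x = +1/2 when sound names are on the left.  The preference odds ratio is
    exp(pref): the odds of starting with the sound block when it is on the
    right relative to the odds of starting with the emotion block when it is
    on the right (i.e. crossing the reading order in either direction).
    """
    rows = []
    for t in trials:
        if t.t_first_sound is None or t.t_first_emotion is None:
            continue
        if t.layout not in ("sound_left", "sound_right"):
            raise ValidationError(f"missing/invalid layout: {t.layout!r}")
        rows.append((1.0 if t.t_first_sound < t.t_first_emotion else 0.0,
                     0.5 if t.layout == "sound_left" else -0.5, t.participant))
    if not rows:
        raise ValidationError("no trials with both first-name timestamps")
    y = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows])
    if np.unique(x).size < 2:
        raise ValidationError("both layouts required to identify the preference")
    g_part, _ = _codes([r[2] for r in rows])

    def row_loglik(theta, re):
        pref, lay = theta
        eta = pref / 2.0 + lay * x + re
        p = _sigmoid(eta)
        return y * np.log(np.clip(p, 1e-12, None)) + (1 - y) * np.log(np.clip(1 - p, 1e-12, None))

    res = mh_crossed_glmm(row_loglik, 2, g_part, None,
                          n_iter=n_iter, warmup=warmup, seed=seed)
    pref, lay = res["theta"][:, 0], res["theta"][:, 1]
    or_draws = np.exp(pref)
    fixed = {"log_preference": summarize_draws(pref),
             "odds_ratio": summarize_draws(or_draws),
             "layout_log_odds": summarize_draws(lay)}
    sds = {"participant": summarize_draws(res["sd"][:, 0])}
    return HierarchicalFit(fixed, sds,
                           {"odds_ratio": or_draws, "log_preference": pref},
                           _ess_diag({"log_preference": pref}))


# ---------------------------------------------------------------------------
# Sound name x emotion name
# ---------------------------------------------------------------------------

def sound_emotion_contingency(
    trials: Iterable[NamingTrial],
    sound_labels: Sequence[str] | None = None,
    emotion_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate chosen sound and emotion names (one count per chosen
    label pair per trial) and test independence with Pearson chi-square."""
    trials = [t for t in trials if t.sound_names and t.emotion_names]
    if not trials:
        raise ValidationError("no trials with both a sound name and an emotion name")
    pairs: dict[tuple[str, str], int] = {}
    for t in trials:
        for s in t.sound_names:
            for e in t.emotion_names:
                pairs[(s, e)] = pairs.get((s, e), 0) + 1
    rows = tuple(sound_labels) if sound_labels is not None else \
        tuple(sorted({s for s, _ in pairs}))
    cols = tuple(emotion_labels) if emotion_labels is not None else \
        tuple(sorted({e for _, e in pairs}))
    M = np.zeros((len(rows), len(cols)))
    rpos = {r: i for i, r in enumerate(rows)}
    cpos = {c: i for i, c in enumerate(cols)}
    for (s, e), c in pairs.items():
        if s in rpos and e in cpos:
            M[rpos[s], cpos[e]] += c
    nz_r = M.sum(axis=1) > 0
    nz_c = M.sum(axis=0) > 0
    sub = M[np.ix_(nz_r, nz_c)]
    if sub.size == 0 or sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValidationError("contingency table needs at least 2 used rows and columns")
    chi2, p, df, _ = stats.chi2_contingency(sub, correction=False)
    return ContingencyTable(rows, cols, M, chi2=float(chi2), df=int(df), p_value=float(p))


def emotion_from_name_accuracy(
    trials: Iterable[NamingTrial],
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
) -> dict:
    """Cross-validated accuracy of a random forest predicting the primary
    emotion name from the chosen sound name(s) (multi-hot features)."""
    trials = [t for t in trials if t.sound_names and t.emotion_names]
    sound_labels = sorted({s for t in trials for s in t.sound_names})
    X = np.zeros((len(trials), len(sound_labels)))
    pos = {s: i for i, s in enumerate(sound_labels)}
    y = []
    for i, t in enumerate(trials):
        for s in t.sound_names:
            X[i, pos[s]] = 1.0
        y.append(t.emotion_names[0])  # primary = first-chosen label
    y = np.array(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least 2 emotion classes")
    folds = cv_folds
    if counts.min() < cv_folds:
        folds = max(2, int(counts.min()))
        warnings.warn(f"smallest class has {counts.min()} instances; "
                      f"reducing folds to {folds}")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, X, y, cv=cv)
    acc = float((pred == y).mean())
    cm = pd.DataFrame(confusion_matrix(y, pred, labels=classes),
                      index=classes, columns=classes)
    return {"accuracy": acc, "confusion": cm, "n_trials": len(trials), "cv_folds": folds}
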