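"""Bayesian embedding of triad similarity judgments.

Each stimulus occupies a point in a d-dimensional perceptual space.  For a
triad (i, j, k) the probability of choosing a pair is a softmax over the
negative pairwise distances, so the closest pair is the most likely choice:

    P(pair p) = exp(-d_p / tau) / sum_q exp(-d_q / tau)

Coordinates get independent normal(0, prior_sd) priors and are sampled by
Hamiltonian Monte Carlo with analytic gradients and dual-averaging step-size
adaptation.  Because the likelihood is invariant under global isometries,
all inference summaries are distance-based (posterior mean of per-draw
pairwise distances); Procrustes alignment is provided only for display.
Model dimensionality is compared via WAIC on the stored pointwise log
likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .datatypes import DistanceMatrix, TriadTrial, ValidationError

_PAIR_SLOTS = ((0, 1), (0, 2), (1, 2))


def triad_choice_prob(d_ij: float, d_ik: float, d_jk: float,
                      temperature: float = 1.0) -> np.ndarray:
    """Choice probabilities for the pairs ((i,j), (i,k), (j,k))."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    d = np.asarray([d_ij, d_ik, d_jk], dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be nonnegative")
    z = -(d - d.min()) / temperature
    w = np.exp(z)
    return w / w.sum()


@dataclass
class EmbeddingConfig:
    """Sampler configuration for the triad embedding."""

    d: int = 3
    temperature: float = 1.0
    prior_sd: float = 1.0
    chains: int = 4
    warmup: int = 500
    samples: int = 500
    seed: int = 0
    leapfrog_steps: int = 15
    target_accept: float = 0.8
    min_triads_per_participant: int = 1

    def __post_init__(self):
        if self.d < 1:
            raise ValidationError("d must be >= 1")
        for name in ("chains", "warmup", "samples", "leapfrog_steps"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.temperature <= 0 or self.prior_sd <= 0:
            raise ValidationError("temperature and prior_sd must be positive")


@dataclass
class EmbeddingPosterior:
    stimuli: tuple[str, ...]
    draws: np.ndarray             # total_draws x n_stimuli x d
    chain_id: np.ndarray          # total_draws
    pointwise_loglik: np.ndarray  # total_draws x n_trials
    mean_distance_matrix: DistanceMatrix
    diagnostics: dict = field(default_factory=dict)
    config: EmbeddingConfig | None = None


# ---------------------------------------------------------------------------
# HMC machinery
# ---------------------------------------------------------------------------

def _prepare(triads: Sequence[TriadTrial], min_per_participant: int):
    counts: dict[str, int] = {}
    for t in triads:
        counts[t.participant] = counts.get(t.participant, 0) + 1
    kept = [t for t in triads if counts[t.participant] >= min_per_participant]
    if not kept:
        raise ValidationError("no triads remain after the participant threshold")
    stimuli = tuple(sorted({s for t in kept for s in t.items}))
    pos = {s: i for i, s in enumerate(stimuli)}
    T = len(kept)
    ii = np.empty(T, dtype=int)
    jj = np.empty(T, dtype=int)
    kk = np.empty(T, dtype=int)
    choice = np.empty(T, dtype=int)
    for n, t in enumerate(kept):
        a, b, c = (pos[s] for s in t.items)
        ii[n], jj[n], kk[n] = a, b, c
        pair = frozenset(pos[s] for s in t.chosen_pair)
        items = (a, b, c)
        for ci, (x, y) in enumerate(_PAIR_SLOTS):
            if frozenset((items[x], items[y])) == pair:
                choice[n] = ci
                break
    return stimuli, ii, jj, kk, choice


def _logp_grad(flat, n, d, ii, jj, kk, choice, tau, prior_sd):
    """Joint log posterior and its gradient w.r.t. the flattened coords."""
    X = flat.reshape(n, d)
    vij = X[ii] - X[jj]
    vik = X[ii] - X[kk]
    vjk = X[jj] - X[kk]
    eps = 1e-12
    dij = np.sqrt((vij ** 2).sum(1) + eps)
    dik = np.sqrt((vik ** 2).sum(1) + eps)
    djk = np.sqrt((vjk ** 2).sum(1) + eps)
    M = -np.column_stack([dij, dik, djk]) / tau
    m = M.max(axis=1)
    lse = m + np.log(np.exp(M - m[:, None]).sum(axis=1))
    T = len(ii)
    ll_rows = M[np.arange(T), choice] - lse
    P = np.exp(M - lse[:, None])
    coef = -(np.equal.outer(choice, np.arange(3)).astype(float) - P) / tau

    # scatter-add via bincount (much faster than np.add.at)
    g0 = coef[:, 0, None] * (vij / dij[:, None])
    g1 = coef[:, 1, None] * (vik / dik[:, None])
    g2 = coef[:, 2, None] * (vjk / djk[:, None])
    idx = np.concatenate([ii, jj, ii, kk, jj, kk])
    W = np.concatenate([g0, -g0, g1, -g1, g2, -g2])
    G = np.empty_like(X)
    for col in range(d):
        G[:, col] = np.bincount(idx, weights=W[:, col], minlength=n)

    logp = ll_rows.sum() - 0.5 * (flat ** 2).sum() / prior_sd ** 2
    grad = G.ravel() - flat / prior_sd ** 2
    return logp, grad, ll_rows


def _run_chain(n, d, ii, jj, kk, choice, cfg: EmbeddingConfig, rng):
    dim = n * d
    q = rng.normal(scale=0.3 * cfg.prior_sd, size=dim)
    logp, grad, cur_ll = _logp_grad(q, n, d, ii, jj, kk, choice,
                                    cfg.temperature, cfg.prior_sd)
    # dual averaging (Nesterov) toward the target acceptance rate
    step = 0.1
    mu = np.log(10.0 * step)
    log_step_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    n_keep = cfg.samples
    draws = np.empty((n_keep, n, d))
    lls = np.empty((n_keep, len(ii)))
    total = cfg.warmup + n_keep
    for it in range(total):
        p = rng.normal(size=dim)
        q_new, p_new = q.copy(), p.copy()
        grad_new = grad
        L = max(1, int(cfg.leapfrog_steps * (0.8 + 0.4 * rng.random())))
        p_new = p_new + 0.5 * step * grad_new
        for l in range(L):
            q_new = q_new + step * p_new
            logp_new, grad_new, ll_new = _logp_grad(
                q_new, n, d, ii, jj, kk, choice, cfg.temperature, cfg.prior_sd)
            if l < L - 1:
                p_new = p_new + step * grad_new
        p_new = p_new + 0.5 * step * grad_new
        h_old = logp - 0.5 * (p ** 2).sum()
        h_new = logp_new - 0.5 * (p_new ** 2).sum()
        log_accept = min(0.0, h_new - h_old)
        if not np.isfinite(log_accept):
            log_accept = -np.inf
        accept_prob = np.exp(log_accept)
        if np.log(rng.random()) < log_accept:
            q, logp, grad, cur_ll = q_new, logp_new, grad_new, ll_new
        if it < cfg.warmup:
            t = it + 1
            h_bar = (1 - 1 / (t + t0)) * h_bar + (cfg.target_accept - accept_prob) / (t + t0)
            log_step = mu - np.sqrt(t) / gamma * h_bar
            eta = t ** (-kappa)
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if it == cfg.warmup - 1:
                step = float(np.exp(log_step_bar))
        else:
            idx = it - cfg.warmup
            draws[idx] = q.reshape(n, d)
            lls[idx] = cur_ll
    return draws, lls


class TriadEmbedding(BaseEstimator):
    """sklearn-style wrapper around the HMC triad-embedding sampler."""

    def __init__(self, d: int = 3, temperature: float = 1.0, prior_sd: float = 1.0,
                 chains: int = 4, warmup: int = 500, samples: int = 500,
                 seed: int = 0, leapfrog_steps: int = 15,
                 target_accept: float = 0.8, min_triads_per_participant: int = 1):
        self.d = d
        self.temperature = temperature
        self.prior_sd = prior_sd
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.seed = seed
        self.leapfrog_steps = leapfrog_steps
        self.target_accept = target_accept
        self.min_triads_per_participant = min_triads_per_participant

    def _config(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            d=self.d, temperature=self.temperature, prior_sd=self.prior_sd,
            chains=self.chains, warmup=self.warmup, samples=self.samples,
            seed=self.seed, leapfrog_steps=self.leapfrog_steps,
            target_accept=self.target_accept,
            min_triads_per_participant=self.min_triads_per_participant)

    def fit(self, triads: Sequence[TriadTrial],
            stimuli: Sequence[str] | None = None):
        cfg = self._config()
        stim, ii, jj, kk, choice = _prepare(triads, cfg.min_triads_per_participant)
        if stimuli is not None:
            missing = sorted(set(map(str, stimuli)) - set(stim))
            if missing:
                raise ValidationError(f"stimuli absent from all triads: {missing}")
        n = len(stim)
        rng = np.random.default_rng(cfg.seed)
        all_draws, all_lls, chain_id = [], [], []
        for c in range(cfg.chains):
            chain_rng = np.random.default_rng(rng.integers(2 ** 31))
            draws, lls = _run_chain(n, cfg.d, ii, jj, kk, choice, cfg, chain_rng)
            all_draws.append(draws)
            all_lls.append(lls)
            chain_id.append(np.full(len(draws), c))
        draws = np.concatenate(all_draws)
        lls = np.concatenate(all_lls)
        chain_id = np.concatenate(chain_id)

        # posterior mean of per-draw pairwise distances
        acc = np.zeros(n * (n - 1) // 2)
        for X in draws:
            acc += pdist(X)
        mean_D = DistanceMatrix(stim, squareform(acc / len(draws)))

        diagnostics = _embedding_diagnostics(all_lls, all_draws)
        self.posterior_ = EmbeddingPosterior(
            stimuli=stim, draws=draws, chain_id=chain_id,
            pointwise_loglik=lls, mean_distance_matrix=mean_D,
            diagnostics=diagnostics, config=cfg)
        return self


def _embedding_diagnostics(all_lls, all_draws) -> dict:
    """ESS and R-hat on isometry-invariant summaries (total log likelihood
    and a reference interpoint distance), flagged when poor."""
    total_ll = np.stack([l.sum(axis=1) for l in all_lls])  # chains x draws
    d01 = np.stack([np.linalg.norm(d[:, 0] - d[:, 1], axis=1) for d in all_draws])
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        diag = {
            "ess_total_loglik": float(az.ess(total_ll)),
            "rhat_total_loglik": float(az.rhat(total_ll)) if total_ll.shape[0] > 1 else np.nan,
            "ess_ref_distance": float(az.ess(d01)),
            "rhat_ref_distance": float(az.rhat(d01)) if d01.shape[0] > 1 else np.nan,
        }
    rhats = [v for k, v in diag.items() if k.startswith("rhat") and np.isfinite(v)]
    diag["ok"] = bool(all(r < 1.1 for r in rhats)) if rhats else True
    return diag


def fit_embedding(triads: Sequence[TriadTrial],
                  config: EmbeddingConfig | None = None) -> EmbeddingPosterior:
    cfg = config or EmbeddingConfig()
    est = TriadEmbedding(**{k: getattr(cfg, k) for k in (
        "d", "temperature", "prior_sd", "chains", "warmup", "samples", "seed",
        "leapfrog_steps", "target_accept", "min_triads_per_participant")})
    return est.fit(triads).posterior_


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------

def waic(pointwise_loglik: np.ndarray) -> dict:
    """WAIC = -2 (lppd - p_waic) with lppd_n = log mean_s exp(ll_ns) and
    p_waic_n = var_s(ll_ns)."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValidationError("need a draws x trials matrix with >= 2 draws")
    if not np.all(np.isfinite(ll)):
        raise ValidationError("log likelihoods must be finite")
    m = ll.max(axis=0)
    lppd_n = m + np.log(np.exp(ll - m).mean(axis=0))
    # population variance: exactly invariant to duplicating draws
    p_n = ll.var(axis=0, ddof=0)
    waic_n = -2.0 * (lppd_n - p_n)
    return {
        "waic": float(waic_n.sum()),
        "lppd": float(lppd_n.sum()),
        "p_waic": float(p_n.sum()),
        "se": float(np.sqrt(len(waic_n) * np.var(waic_n, ddof=1))) if len(waic_n) > 1 else 0.0,
    }


def posterior_distance_matrix(posterior: EmbeddingPosterior) -> DistanceMatrix:
    """Per-draw pairwise distances averaged over draws (not distances of the
    mean coordinates, which shrink under rotational posterior spread)."""
    return posterior.mean_distance_matrix


# ---------------------------------------------------------------------------
# Dimension sweep
# ---------------------------------------------------------------------------

def dimension_sweep(
    triads: Sequence[TriadTrial],
    d_values: Sequence[int],
    config: EmbeddingConfig | None = None,
    reference_matrices: dict[str, DistanceMatrix] | None = None,
) -> pd.DataFrame:
    """Fit one embedding per candidate dimensionality; report WAIC and the
    Mantel correlation against each reference distance matrix.  The
    ``neg_waic_normalized`` column rescales -WAIC to [0, 1] across the sweep
    for plotting."""
    from .acoustic import matrix_correlation

    if not list(d_values):
        raise ValidationError("d_values must be nonempty")
    cfg = config or EmbeddingConfig()
    rows = []
    for d in d_values:
        c = EmbeddingConfig(**{**cfg.__dict__, "d": int(d)})
        post = fit_embedding(triads, c)
        w = waic(post.pointwise_loglik)
        row = {"d": int(d), "waic": w["waic"], "lppd": w["lppd"],
               "p_waic": w["p_waic"]}
        if reference_matrices:
            for name, ref in reference_matrices.items():
                ref2 = ref.reorder(post.stimuli)
                r, _ = matrix_correlation(post.mean_distance_matrix, ref2)
                row[f"r_vs_{name}"] = r
        rows.append(row)
    df = pd.DataFrame(rows)
    neg = -df["waic"]
    rng_ = neg.max() - neg.min()
    df["neg_waic_normalized"] = (neg - neg.min()) / rng_ if rng_ > 0 else 1.0
    return df


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def procrustes_align(coords_a: np.ndarray,
                     coords_b: np.ndarray) -> tuple[np.ndarray, float]:
    """Align b onto a by translation, rotation/reflection and uniform
    scaling; returns the aligned copy of b and the disparity (residual sum
    of squares normalized by the centered norm of a)."""
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape:
        raise ValidationError("configurations must have the same shape")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na, nb = np.linalg.norm(Ac), np.linalg.norm(Bc)
    if na == 0 or nb == 0:
        raise ValidationError("degenerate configuration (all points identical)")
    R, s = orthogonal_procrustes(Bc, Ac)
    scale = s / nb ** 2
    aligned = scale * Bc @ R + A.mean(axis=0)
    disparity = float(((Ac - scale * Bc @ R) ** 2).sum() / na ** 2)
    return aligned, disparity
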