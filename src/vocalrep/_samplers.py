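"""MCMC backends for the hierarchical models.

Two samplers cover every model in the package:

* :func:`gibbs_crossed_gaussian` — exact conjugate Gibbs for a Gaussian
  response with fixed effects and two crossed random intercepts (the log
  response-time model).
* :func:`mh_crossed_glmm` — blocked Metropolis-within-Gibbs for non-Gaussian
  responses (cumulative-logit certainty, Bernoulli response order) with up
  to two crossed random-intercept factors.  Random-effect vectors update in
  one vectorized sweep with independent accept/reject per group, which is
  valid because the likelihood factorizes over groups given everything else.

Priors are weakly informative: normal(0, 2.5) on fixed effects, inverse
gamma (Gibbs) or half-normal(0, 1) (MH) on variance components.
"""

from __future__ import annotations

import numpy as np


def gibbs_crossed_gaussian(
    y: np.ndarray,
    X: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    n_iter: int = 1500,
    warmup: int = 500,
    seed: int = 0,
    beta_prior_sd: float = 2.5,
    ig_shape: float = 2.0,
    ig_scale: float = 0.5,
) -> dict:
    """Gibbs sampler for ``y = X beta + u[g1] + v[g2] + eps``.

    Returns post-warmup draws of ``beta`` and the three standard deviations.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    n1, n2 = g1.max() + 1, g2.max() + 1

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u = np.zeros(n1)
    v = np.zeros(n2)
    s2_u = s2_v = 0.1
    s2_e = max(np.var(y - X @ beta), 1e-3)

    XtX = X.T @ X
    cnt1 = np.bincount(g1, minlength=n1)
    cnt2 = np.bincount(g2, minlength=n2)

    keep = n_iter - warmup
    beta_draws = np.empty((keep, p))
    sd_draws = np.empty((keep, 3))  # sd_u, sd_v, sd_resid

    for it in range(n_iter):
        # beta | rest
        r = y - u[g1] - v[g2]
        prec = XtX / s2_e + np.eye(p) / beta_prior_sd ** 2
        mean = np.linalg.solve(prec, X.T @ r / s2_e)
        beta = mean + np.linalg.cholesky(np.linalg.inv(prec)) @ rng.normal(size=p)

        # u | rest
        r = y - X @ beta - v[g2]
        var_u = 1.0 / (cnt1 / s2_e + 1.0 / s2_u)
        mean_u = var_u * np.bincount(g1, weights=r, minlength=n1) / s2_e
        u = mean_u + np.sqrt(var_u) * rng.normal(size=n1)

        # v | rest
        r = y - X @ beta - u[g1]
        var_v = 1.0 / (cnt2 / s2_e + 1.0 / s2_v)
        mean_v = var_v * np.bincount(g2, weights=r, minlength=n2) / s2_e
        v = mean_v + np.sqrt(var_v) * rng.normal(size=n2)

        # variances | rest
        s2_u = 1.0 / rng.gamma(ig_shape + n1 / 2.0, 1.0 / (ig_scale + (u ** 2).sum() / 2.0))
        s2_v = 1.0 / rng.gamma(ig_shape + n2 / 2.0, 1.0 / (ig_scale + (v ** 2).sum() / 2.0))
        resid = y - X @ beta - u[g1] - v[g2]
        s2_e = 1.0 / rng.gamma(ig_shape + n / 2.0, 1.0 / (ig_scale + (resid ** 2).sum() / 2.0))

        if it >= warmup:
            beta_draws[it - warmup] = beta
            sd_draws[it - warmup] = np.sqrt([s2_u, s2_v, s2_e])

    return {"beta": beta_draws, "sd": sd_draws}


def mh_crossed_glmm(
    row_loglik,
    n_theta: int,
    g1: np.ndarray,
    g2: np.ndarray | None = None,
    n_iter: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
    theta_prior_sd: float = 2.5,
    sd_prior_scale: float = 1.0,
    theta0: np.ndarray | None = None,
) -> dict:
    """Metropolis-within-Gibbs for a GLMM with crossed random intercepts.

    ``row_loglik(theta, re)`` must return the per-row log likelihood given
    the global parameter vector ``theta`` and the random-effect contribution
    ``re`` (already expanded to rows).  Step sizes adapt toward standard
    acceptance targets during warmup and are then frozen.
    """
    rng = np.random.default_rng(seed)
    g1 = np.asarray(g1)
    n1 = g1.max() + 1
    has_v = g2 is not None
    if has_v:
        g2 = np.asarray(g2)
        n2 = g2.max() + 1
    theta = np.zeros(n_theta) if theta0 is None else np.array(theta0, float)
    u = np.zeros(n1)
    v = np.zeros(n2) if has_v else None
    log_su = np.log(0.5)
    log_sv = np.log(0.5) if has_v else None

    def _re():
        re = u[g1]
        if has_v:
            re = re + v[g2]
        return re

    def _theta_logpost(th):
        ll = row_loglik(th, _re()).sum()
        return ll - 0.5 * (th ** 2).sum() / theta_prior_sd ** 2

    def _halfnormal_logprior(log_s):
        s = np.exp(log_s)
        return -0.5 * s ** 2 / sd_prior_scale ** 2 + log_s  # + Jacobian

    step_theta, step_u, step_v, step_s = 0.2, 0.3, 0.3, 0.3
    keep = n_iter - warmup
    theta_draws = np.empty((keep, n_theta))
    sd_draws = np.empty((keep, 2 if has_v else 1))
    cur_theta_lp = _theta_logpost(theta)

    for it in range(n_iter):
        # global block
        prop = theta + step_theta * rng.normal(size=n_theta)
        lp = _theta_logpost(prop)
        acc = lp - cur_theta_lp > np.log(rng.random())
        if acc:
            theta, cur_theta_lp = prop, lp
        if it < warmup:
            step_theta *= np.exp(0.05 * ((1.0 if acc else 0.0) - 0.25))

        # u block: independent accept/reject per group
        su = np.exp(log_su)
        base = v[g2] if has_v else 0.0
        ll_cur = row_loglik(theta, u[g1] + base)
        u_prop = u + step_u * rng.normal(size=n1)
        ll_prop = row_loglik(theta, u_prop[g1] + base)
        d_ll = np.bincount(g1, weights=ll_prop - ll_cur, minlength=n1)
        d_prior = -0.5 * (u_prop ** 2 - u ** 2) / su ** 2
        acc_u = d_ll + d_prior > np.log(rng.random(size=n1))
        u = np.where(acc_u, u_prop, u)
        if it < warmup:
            step_u *= np.exp(0.05 * (acc_u.mean() - 0.44))

        # v block
        if has_v:
            sv = np.exp(log_sv)
            ll_cur = row_loglik(theta, u[g1] + v[g2])
            v_prop = v + step_v * rng.normal(size=n2)
            ll_prop = row_loglik(theta, u[g1] + v_prop[g2])
            d_ll = np.bincount(g2, weights=ll_prop - ll_cur, minlength=n2)
            d_prior = -0.5 * (v_prop ** 2 - v ** 2) / sv ** 2
            acc_v = d_ll + d_prior > np.log(rng.random(size=n2))
            v = np.where(acc_v, v_prop, v)
            if it < warmup:
                step_v *= np.exp(0.05 * (acc_v.mean() - 0.44))

        # random-effect scales (conditional on u, v only)
        def _sd_logpost(log_s, vec):
            s = np.exp(log_s)
            return (-len(vec) * log_s - 0.5 * (vec ** 2).sum() / s ** 2
                    + _halfnormal_logprior(log_s))

        prop = log_su + step_s * rng.normal()
        if _sd_logpost(prop, u) - _sd_logpost(log_su, u) > np.log(rng.random()):
            log_su = prop
        if has_v:
            prop = log_sv + step_s * rng.normal()
            if _sd_logpost(prop, v) - _sd_logpost(log_sv, v) > np.log(rng.random()):
                log_sv = prop

        cur_theta_lp = _theta_logpost(theta)

        if it >= warmup:
            theta_draws[it - warmup] = theta
            sd_draws[it - warmup] = [np.exp(log_su)] + ([np.exp(log_sv)] if has_v else [])

    return {"theta": theta_draws, "sd": sd_draws}


def summarize_draws(draws: np.ndarray) -> dict:
    """Posterior mean, median and central 95% interval of a 1-D draw vector."""
    draws = np.asarray(draws, float)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "mean": float(draws.mean()),
        "median": float(np.median(draws)),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }
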