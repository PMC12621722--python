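"""Sequential Monte Carlo over latent learning trajectories.

The generative models place a Gaussian state-space prior on the policy
weights (and, in the dynamic variants, on a latent learning-rate gain or
baseline): weights drift under the learning rule evaluated at the animal's
realized choices and rewards, plus additive Gaussian noise.  The marginal
likelihood of a choice sequence integrates the latent trajectory out; a
bootstrap particle filter estimates that integral, the filtered posterior,
and -- via ancestral-lineage tracing -- the smoothed posterior.

Held-out trials contribute no likelihood to the training objective, but the
realized choice on a held-out trial still drives the learning dynamics (the
animal experienced it); their predictive log-probabilities are reported
from the particle mixture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import numba
from numba import njit

from .models import PGParams, TDRLParams, P_CLIP
from .trials import HeldoutMask, RegressorMatrix, build_regressors, side_to_sign

_VARIANT_CODE = {"noise_only": 0, "scalar_pg": 0, "vector_pg": 0,
                 "dynamic_rate": 1, "dynamic_baseline": 2}


class ParticleDegeneracyError(RuntimeError):
    """All particle weights underflowed to zero.

    Usually means far too few particles for the dynamics noise, or an
    initialization assigning the data negligible probability; increase
    ``n_particles`` or start from a better parameter point.
    """


@dataclass
class ParticlePosterior:
    """Filtered/smoothed latent trajectories and the likelihood estimate.

    ``filt_*``/``smooth_*`` are T x D with D = M weights, plus the latent
    learning-rate gain (dynamic-rate) or M latent baselines
    (dynamic-baseline) appended as extra columns.  ``loglik_per_trial``
    holds log predictive choice probabilities for every trial (held-out
    included); ``loglik_total`` is their sum over the full trajectory.
    """

    filt_mean: np.ndarray
    filt_sd: np.ndarray
    smooth_mean: np.ndarray | None
    smooth_sd: np.ndarray | None
    loglik_per_trial: np.ndarray
    ess_trace: np.ndarray
    n_particles: int
    state_names: tuple
    mask: np.ndarray | None = None
    paths: np.ndarray | None = None          # T x N x D particle states
    ancestors: np.ndarray | None = None      # T x N resampling genealogy
    weight_trace: np.ndarray | None = None   # T x N normalized weights

    @property
    def loglik_total(self) -> float:
        return float(self.loglik_per_trial.sum())

    @property
    def loglik_train(self) -> float:
        if self.mask is None:
            return self.loglik_total
        return float(self.loglik_per_trial[~self.mask].sum())

    @property
    def loglik_heldout(self) -> float:
        if self.mask is None:
            return 0.0
        return float(self.loglik_per_trial[self.mask].sum())


# ------------------------------------------------------------- kernels ---

@njit(cache=True)
def _systematic_resample(W, u):
    N = W.size
    idx = np.empty(N, np.int64)
    c = W[0]
    j = 0
    for i in range(N):
        target = (i + u) / N
        while c < target and j < N - 1:
            j += 1
            c += W[j]
        idx[i] = j
    return idx


@njit(cache=True)
def _pf_pg_kernel(x, ysign, r, observed, sd_step, alpha, beta, q,
                  w1_mean, w1_sd, dyn, alpha0, sigma_alpha, beta_sigma,
                  eps, us, store):
    """Bootstrap filter for the policy-gradient state-space family.

    ``sd_step[t]`` is the per-regressor noise SD of the transition *into*
    trial t (row 0 unused).  ``dyn``: 0 static, 1 latent rate, 2 latent
    baseline.  All randomness comes from the pre-generated standard-normal
    array ``eps`` (T x N x n_noise; row 0 seeds the initial states) and the
    uniforms ``us`` (resampling), so one noise realization defines a
    deterministic likelihood surface over parameters (common random
    numbers).  Returns per-trial log predictive probabilities, filtered
    moments, ESS trace, stored paths/ancestry/weights for smoothing, final
    weights, and an ok flag (0 on weight underflow).
    """
    T, M = x.shape
    N = eps.shape[1]
    D = M + (1 if dyn == 1 else (M if dyn == 2 else 0))

    w = np.empty((N, M))
    for i in range(N):
        for j in range(M):
            w[i, j] = w1_mean[j] + w1_sd * eps[0, i, j]
    a = np.zeros(N)
    if dyn == 1:
        for i in range(N):
            a[i] = alpha0 + sigma_alpha * eps[0, i, M]
    b = np.zeros((N, M))
    if dyn == 2:
        for i in range(N):
            for j in range(M):
                b[i, j] = beta[j]

    W = np.full(N, 1.0 / N)
    loglik = np.empty(T)
    filt_mean = np.zeros((T, D))
    filt_sd = np.zeros((T, D))
    ess = np.empty(T)
    n_store = T if store else 1
    paths = np.zeros((n_store, N, D))
    anc = np.zeros((n_store, N), np.int64)
    W_hist = np.zeros((n_store, N))
    lik = np.empty(N)
    ok = 1

    for t in range(T):
        xt = x[t]
        yt = ysign[t]
        # predictive likelihood of the realized choice under each particle
        for i in range(N):
            z = 0.0
            for j in range(M):
                z += w[i, j] * xt[j]
            p = 1.0 / (1.0 + np.exp(-z))
            if p < P_CLIP:
                p = P_CLIP
            elif p > 1.0 - P_CLIP:
                p = 1.0 - P_CLIP
            lik[i] = p if yt > 0 else 1.0 - p
        incr = 0.0
        for i in range(N):
            incr += W[i] * lik[i]
        if incr <= 0.0:
            ok = 0
            break
        loglik[t] = np.log(incr)
        if observed[t]:
            for i in range(N):
                W[i] = W[i] * lik[i] / incr

        # filtered moments and (optionally) genealogy storage
        for d in range(D):
            mu = 0.0
            for i in range(N):
                v = w[i, d] if d < M else (a[i] if dyn == 1 else b[i, d - M])
                mu += W[i] * v
                if store:
                    paths[t, i, d] = v
            var = 0.0
            for i in range(N):
                v = w[i, d] if d < M else (a[i] if dyn == 1 else b[i, d - M])
                var += W[i] * (v - mu) * (v - mu)
            filt_mean[t, d] = mu
            filt_sd[t, d] = np.sqrt(var)

        s2 = 0.0
        for i in range(N):
            s2 += W[i] * W[i]
        ess[t] = 1.0 / s2
        if store:
            for i in range(N):
                W_hist[t, i] = W[i]

        if t == T - 1:
            break

        resample = ess[t] < N / 2.0
        if resample:
            # sort by the current logit before systematic resampling: keeps
            # the survivor set near-continuous in the parameters, so the
            # common-random-numbers likelihood surface stays smooth
            key = np.empty(N)
            for i in range(N):
                z = 0.0
                for j in range(M):
                    z += w[i, j] * xt[j]
                key[i] = z
            order = np.argsort(key)
            W_sorted = np.empty(N)
            for i in range(N):
                W_sorted[i] = W[order[i]]
            picks = _systematic_resample(W_sorted, us[t])
            idx = np.empty(N, np.int64)
            for i in range(N):
                idx[i] = order[picks[i]]
            w_new = np.empty((N, M))
            a_new = np.empty(N)
            b_new = np.empty((N, M))
            for i in range(N):
                k = idx[i]
                for j in range(M):
                    w_new[i, j] = w[k, j]
                    b_new[i, j] = b[k, j]
                a_new[i] = a[k]
            w, a, b = w_new, a_new, b_new
            for i in range(N):
                W[i] = 1.0 / N
            if store:
                for i in range(N):
                    anc[t + 1, i] = idx[i]
        else:
            if store:
                for i in range(N):
                    anc[t + 1, i] = i

        # propagate through the learning rule conditioned on (x_t, y_t, r_t)
        rt = r[t]
        sd_next = sd_step[t + 1]
        for i in range(N):
            z = 0.0
            for j in range(M):
                z += w[i, j] * xt[j]
            p = 1.0 / (1.0 + np.exp(-z))
            p_y = p if yt > 0 else 1.0 - p
            gain = a[i] if dyn == 1 else 1.0
            for j in range(M):
                bj = b[i, j] if dyn == 2 else beta[j]
                drift = (gain * alpha[j] * (rt - bj) * (1.0 - p_y) * yt * xt[j]
                         - q[j] * w[i, j])
                w[i, j] = w[i, j] + drift + sd_next[j] * eps[t + 1, i, j]
            if dyn == 1 and sigma_alpha > 0.0:
                a[i] = a[i] + sigma_alpha * eps[t + 1, i, M]
            if dyn == 2 and beta_sigma > 0.0:
                for j in range(M):
                    b[i, j] = b[i, j] + beta_sigma * eps[t + 1, i, M + j]

    return loglik, filt_mean, filt_sd, ess, paths, anc, W_hist, W, ok


@njit(cache=True)
def _ndtri(p):
    """Inverse standard-normal CDF (Acklam's rational approximation)."""
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    p_low = 0.02425
    if p < p_low:
        q_ = np.sqrt(-2.0 * np.log(p))
        return (((((c[0] * q_ + c[1]) * q_ + c[2]) * q_ + c[3]) * q_ + c[4]) * q_ + c[5]) / \
               ((((d[0] * q_ + d[1]) * q_ + d[2]) * q_ + d[3]) * q_ + 1.0)
    if p > 1 - p_low:
        q_ = np.sqrt(-2.0 * np.log(1.0 - p))
        return -(((((c[0] * q_ + c[1]) * q_ + c[2]) * q_ + c[3]) * q_ + c[4]) * q_ + c[5]) / \
               ((((d[0] * q_ + d[1]) * q_ + d[2]) * q_ + d[3]) * q_ + 1.0)
    q_ = p - 0.5
    r_ = q_ * q_
    return (((((a[0] * r_ + a[1]) * r_ + a[2]) * r_ + a[3]) * r_ + a[4]) * r_ + a[5]) * q_ / \
           (((((b[0] * r_ + b[1]) * r_ + b[2]) * r_ + b[3]) * r_ + b[4]) * r_ + 1.0)


@njit(cache=True)
def _norm_cdf(z):
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


@njit(cache=True)
def _pf_tdrl_kernel(s, ysign, r, observed, sigma_m, td_rate, v_l0, v_r0,
                    lapse, eps, us, store):
    """Bootstrap filter over the stochastic TD action-value trajectory."""
    T = s.size
    N = eps.shape[1]
    v = np.empty((N, 2))
    for i in range(N):
        v[i, 0] = v_l0
        v[i, 1] = v_r0
    W = np.full(N, 1.0 / N)
    loglik = np.empty(T)
    filt_mean = np.zeros((T, 2))
    filt_sd = np.zeros((T, 2))
    ess = np.empty(T)
    n_store = T if store else 1
    paths = np.zeros((n_store, N, 2))
    anc = np.zeros((n_store, N), np.int64)
    W_hist = np.zeros((n_store, N))
    lik = np.empty(N)
    ok = 1
    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)

    for t in range(T):
        st = s[t]
        yt = ysign[t]
        for i in range(N):
            ratio = v[i, 0] / (v[i, 0] + v[i, 1])
            if ratio < P_CLIP:
                ratio = P_CLIP
            elif ratio > 1 - P_CLIP:
                ratio = 1 - P_CLIP
            p = _norm_cdf(st / sigma_m - _ndtri(ratio))
            p = (1.0 - lapse) * p + lapse * 0.5
            if p < P_CLIP:
                p = P_CLIP
            elif p > 1.0 - P_CLIP:
                p = 1.0 - P_CLIP
            lik[i] = p if yt > 0 else 1.0 - p
        incr = 0.0
        for i in range(N):
            incr += W[i] * lik[i]
        if incr <= 0.0:
            ok = 0
            break
        loglik[t] = np.log(incr)
        if observed[t]:
            for i in range(N):
                W[i] = W[i] * lik[i] / incr

        for d in range(2):
            mu = 0.0
            for i in range(N):
                mu += W[i] * v[i, d]
                if store:
                    paths[t, i, d] = v[i, d]
            var = 0.0
            for i in range(N):
                var += W[i] * (v[i, d] - mu) * (v[i, d] - mu)
            filt_mean[t, d] = mu
            filt_sd[t, d] = np.sqrt(var)

        s2 = 0.0
        for i in range(N):
            s2 += W[i] * W[i]
        ess[t] = 1.0 / s2
        if store:
            for i in range(N):
                W_hist[t, i] = W[i]
        if t == T - 1:
            break

        if ess[t] < N / 2.0:
            idx = _systematic_resample(W, us[t])
            v_new = np.empty((N, 2))
            for i in range(N):
                v_new[i, 0] = v[idx[i], 0]
                v_new[i, 1] = v[idx[i], 1]
            v = v_new
            for i in range(N):
                W[i] = 1.0 / N
            if store:
                for i in range(N):
                    anc[t + 1, i] = idx[i]
        else:
            if store:
                for i in range(N):
                    anc[t + 1, i] = i

        rt = r[t]
        k = 1 if yt > 0 else 0
        belief = _norm_cdf(yt * st / (2.0 * sigma_m))
        dens = inv_sqrt2pi / sigma_m * np.exp(-0.5 * (st / sigma_m) ** 2)
        for i in range(N):
            vy = v[i, k]
            vy = vy + td_rate * (rt - vy * belief) + vy * dens * eps[t + 1, i, 0]
            if vy < 1e-6:
                vy = 1e-6
            v[i, k] = vy

    return loglik, filt_mean, filt_sd, ess, paths, anc, W_hist, W, ok


# ------------------------------------------------------------- wrappers ---

def _smooth_from_genealogy(paths, anc, W_final):
    """Ancestral-lineage smoother: weighted moments of surviving paths."""
    T, N, D = paths.shape
    lineage = np.arange(N)
    smooth_mean = np.empty((T, D))
    smooth_sd = np.empty((T, D))
    for t in range(T - 1, -1, -1):
        if t < T - 1:
            lineage = anc[t + 1][lineage]
        pts = paths[t, lineage, :]
        mu = W_final @ pts
        smooth_mean[t] = mu
        smooth_sd[t] = np.sqrt(np.maximum(W_final @ (pts - mu) ** 2, 0.0))
    n_unique_root = np.unique(lineage).size
    return smooth_mean, smooth_sd, n_unique_root


def _prep_pg_arrays(trials, regressors, params, mask):
    x = regressors.x
    T = x.shape[0]
    ysign = side_to_sign(trials["choice"]).astype(np.float64)
    r = trials["reward"].to_numpy(np.float64)
    observed = np.ones(T, bool) if mask is None else ~np.asarray(
        mask.mask if isinstance(mask, HeldoutMask) else mask, bool)
    day_break = regressors.session_start
    sd_step = np.where(day_break[:, None], params.sigma_day[None, :],
                       params.sigma[None, :])
    return x, ysign, r, observed, sd_step


def pf_noise(T: int, n_particles: int, params, seed: int = 0):
    """Pre-generate the filter's randomness for a given model and size.

    Returns ``(eps, us)``: standard normals of shape (T, n_particles, K)
    driving the state dynamics (K set by the model family/variant) and
    uniforms for systematic resampling.  Passing the same pair to repeated
    :func:`particle_filter` calls freezes the Monte Carlo randomness, so
    the likelihood is a deterministic function of the parameters (common
    random numbers for optimization).
    """
    if isinstance(params, TDRLParams):
        k = 1
    else:
        m = params.m
        dyn = _VARIANT_CODE[params.variant]
        k = m + (1 if dyn == 1 else (m if dyn == 2 else 0))
    rng = np.random.default_rng(_checked_seed(seed))
    return rng.standard_normal((T, n_particles, k)), rng.random(T)


def particle_filter(trials, regressors: RegressorMatrix | None, params,
                    mask: HeldoutMask | np.ndarray | None = None,
                    n_particles: int = 1000, seed: int = 0,
                    store_paths: bool = True,
                    noise: tuple | None = None) -> ParticlePosterior:
    """Run the bootstrap filter and (optionally) the genealogy smoother.

    ``params`` selects the model family: a :class:`PGParams` runs the
    policy-gradient state-space filter over weights (plus latent rate or
    baseline), a :class:`TDRLParams` the TD action-value filter.  The
    filter conditions the learning dynamics on the realized choices and
    rewards; observation weights use the Bernoulli likelihood of each
    choice, skipped on held-out trials.  Systematic resampling triggers
    when the effective sample size drops below ``n_particles / 2``.

    ``noise`` optionally supplies a pre-generated ``(eps, us)`` pair from
    :func:`pf_noise` (common random numbers); otherwise fresh noise is
    drawn from ``seed``.
    """
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    mask_arr = None if mask is None else np.asarray(
        mask.mask if isinstance(mask, HeldoutMask) else mask, bool)
    T = len(trials)
    if noise is None:
        noise = pf_noise(T, n_particles, params, seed=seed)
    eps, us = noise
    if eps.shape[0] != T or us.shape[0] != T:
        raise ValueError("noise arrays do not match the number of trials")
    n_particles = eps.shape[1]

    if isinstance(params, TDRLParams):
        t = trials.reset_index(drop=True)
        s = (t["contrast_right"] - t["contrast_left"]).to_numpy(np.float64)
        ysign = side_to_sign(t["choice"]).astype(np.float64)
        r = t["reward"].to_numpy(np.float64)
        observed = np.ones(s.size, bool) if mask_arr is None else ~mask_arr
        out = _pf_tdrl_kernel(s, ysign, r, observed, params.sigma_m,
                              params.td_rate, params.v_init[0], params.v_init[1],
                              params.stochasticity, eps, us, store_paths)
        names = ("V_L", "V_R")
    else:
        if regressors is None:
            regressors = build_regressors(trials)
        x, ysign, r, observed, sd_step = _prep_pg_arrays(
            trials, regressors, params, mask)
        dyn = _VARIANT_CODE[params.variant]
        out = _pf_pg_kernel(x, ysign, r, observed, sd_step, params.alpha,
                            params.beta, params.qdiag, params.w1_mean,
                            params.w1_sd, dyn, params.alpha0,
                            params.sigma_alpha, params.beta_sigma,
                            eps, us, store_paths)
        names = tuple(regressors.names)
        if dyn == 1:
            names = names + ("alpha_t",)
        elif dyn == 2:
            names = names + tuple(f"beta_{n}" for n in regressors.names)

    loglik, filt_mean, filt_sd, ess, paths, anc, W_hist, W_final, ok = out
    if not ok:
        raise ParticleDegeneracyError(
            "particle weights underflowed; increase n_particles or improve "
            "the initialization")
    smooth_mean = smooth_sd = None
    if store_paths:
        smooth_mean, smooth_sd, n_root = _smooth_from_genealogy(paths, anc, W_final)
        if n_root <= max(1, 0.01 * n_particles) and len(loglik) > 50:
            warnings.warn(
                f"degenerate genealogy: {n_root} unique ancestors at t=0; "
                "early-trial smoothed SDs collapse -- consider the "
                "backward-simulation smoother (smooth_posterior)",
                RuntimeWarning)
    return ParticlePosterior(filt_mean=filt_mean, filt_sd=filt_sd,
                             smooth_mean=smooth_mean, smooth_sd=smooth_sd,
                             loglik_per_trial=loglik, ess_trace=ess,
                             n_particles=n_particles, state_names=names,
                             mask=mask_arr,
                             paths=paths if store_paths else None,
                             ancestors=anc if store_paths else None,
                             weight_trace=W_hist if store_paths else None)


def smooth_posterior(posterior: ParticlePosterior, method: str = "ancestral",
                     trials=None, regressors: RegressorMatrix | None = None,
                     params: PGParams | None = None, n_draws: int = 200,
                     seed: int = 0) -> ParticlePosterior:
    """Recompute smoothed trajectories from a stored filter run.

    ``method="ancestral"`` re-traces the surviving genealogy (cheap, but
    early-trial uncertainty collapses on long series once lineages
    coalesce).  ``method="backward"`` runs a backward-simulation pass
    (FFBSi) drawing ``n_draws`` full trajectories against the model's
    Gaussian transition density -- it needs ``trials`` and ``params`` of
    the policy-gradient family.  Either way the likelihood estimate is
    untouched; a new :class:`ParticlePosterior` is returned with
    ``smooth_mean``/``smooth_sd`` replaced.
    """
    if posterior.paths is None:
        raise ValueError("filter was run with store_paths=False")
    from dataclasses import replace
    if method == "ancestral":
        W_final = posterior.weight_trace[-1]
        mean, sd, _ = _smooth_from_genealogy(posterior.paths,
                                             posterior.ancestors, W_final)
        return replace(posterior, smooth_mean=mean, smooth_sd=sd)
    if method != "backward":
        raise ValueError(f"unknown smoothing method {method!r}")
    if trials is None or params is None or isinstance(params, TDRLParams):
        raise ValueError("backward smoothing needs trials and PG-family params")
    if regressors is None:
        regressors = build_regressors(trials)
    mean, sd = _backward_simulation(posterior, trials, regressors, params,
                                    n_draws, seed)
    return replace(posterior, smooth_mean=mean, smooth_sd=sd)


def _backward_simulation(posterior, trials, regressors, params, n_draws, seed):
    """FFBSi smoother for the policy-gradient state-space family.

    Vectorized over backward draws: at each step the ancestor of each
    sampled trajectory is re-drawn with probability proportional to the
    filtering weight times the Gaussian transition density from the stored
    particle to the trajectory's next state.  Deterministic state
    dimensions (zero transition SD) are matched by genealogy instead.
    """
    paths = posterior.paths
    W_hist = np.maximum(posterior.weight_trace, 1e-300)
    T, N, D = paths.shape
    m = params.m
    x, ysign, r, _, sd_step = _prep_pg_arrays(trials, regressors, params, None)
    dyn = _VARIANT_CODE[params.variant]
    # transition SD of every state dimension, per target trial
    sd_full = np.zeros((T, D))
    sd_full[:, :m] = sd_step
    if dyn == 1:
        sd_full[:, m] = params.sigma_alpha
    elif dyn == 2:
        sd_full[:, m:] = params.beta_sigma
    rng = np.random.default_rng(seed)

    idx = rng.choice(N, size=n_draws, p=W_hist[-1] / W_hist[-1].sum())
    traj = np.empty((T, n_draws, D))
    traj[-1] = paths[-1, idx]
    anc = posterior.ancestors
    lineage = idx.copy()
    for t in range(T - 2, -1, -1):
        lineage = anc[t + 1][lineage]
        # transition mean from each stored particle at t to trial t+1
        w_t = paths[t, :, :m]
        p_r = 1.0 / (1.0 + np.exp(-(w_t @ x[t])))
        p_y = np.clip(p_r if ysign[t] > 0 else 1.0 - p_r, P_CLIP, 1 - P_CLIP)
        gain = paths[t, :, m] if dyn == 1 else 1.0
        beta = paths[t, :, m:] if dyn == 2 else params.beta[None, :]
        drift = (np.asarray(gain)[..., None] * params.alpha[None, :]
                 * (r[t] - beta) * (1.0 - p_y)[:, None] * ysign[t] * x[t][None, :]
                 - params.qdiag[None, :] * w_t)
        mean_next = paths[t].copy()
        mean_next[:, :m] = w_t + drift

        sd = sd_full[t + 1]
        stoch = sd > 0
        diff = traj[t + 1][:, None, :] - mean_next[None, :, :]   # (K, N, D)
        logw = np.broadcast_to(np.log(W_hist[t])[None, :],
                               (n_draws, N)).copy()
        if stoch.any():
            logw += (-0.5 * (diff[:, :, stoch] / sd[stoch]) ** 2
                     - np.log(sd[stoch])).sum(axis=2)
        if (~stoch).any():
            # deterministic dims: follow the stored genealogy exactly
            exact = np.abs(diff[:, :, ~stoch]).max(axis=2) < 1e-9
            logw = np.where(exact, logw, -np.inf)
            dead = ~np.isfinite(logw.max(axis=1))
            if dead.any():
                logw[dead] = -np.inf
                logw[dead, lineage[dead]] = 0.0
        pick = np.argmax(logw + rng.gumbel(size=logw.shape), axis=1)
        traj[t] = paths[t, pick]
        lineage = pick
    return traj.mean(axis=1), traj.std(axis=1)


def _checked_seed(seed: int) -> int:
    seed = int(seed)
    if not 0 <= seed < 2**32:
        seed = seed % 2**32
    return seed


def make_loglik_fn(trials, regressors, template, mask=None,
                   n_particles: int = 1000, seed: int = 0,
                   noise: tuple | None = None):
    """Build a fast ``params -> per-trial loglik`` closure for fitting.

    Hoists the trial arrays out of the hot loop and calls the compiled
    kernel directly, with fixed common-random-numbers noise: optimizers
    evaluate the likelihood thousands of times, and the DataFrame
    conversions otherwise dominate.  ``template`` fixes the model family
    and variant; every later call must use params of the same variant.
    """
    T = len(trials)
    if noise is None:
        noise = pf_noise(T, n_particles, template, seed=seed)
    eps, us = noise
    if isinstance(template, TDRLParams):
        t = trials.reset_index(drop=True)
        s = (t["contrast_right"] - t["contrast_left"]).to_numpy(np.float64)
        ysign = side_to_sign(t["choice"]).astype(np.float64)
        r = t["reward"].to_numpy(np.float64)
        mask_arr = None if mask is None else np.asarray(
            mask.mask if isinstance(mask, HeldoutMask) else mask, bool)
        observed = np.ones(T, bool) if mask_arr is None else ~mask_arr

        def loglik(params: TDRLParams) -> np.ndarray:
            out = _pf_tdrl_kernel(s, ysign, r, observed, params.sigma_m,
                                  params.td_rate, params.v_init[0],
                                  params.v_init[1], params.stochasticity,
                                  eps, us, False)
            if not out[-1]:
                raise ParticleDegeneracyError("particle weights underflowed")
            return out[0]

        return loglik

    if regressors is None:
        regressors = build_regressors(trials)
    x, ysign, r, observed, _ = _prep_pg_arrays(trials, regressors, template, mask)
    day_break = regressors.session_start
    dyn = _VARIANT_CODE[template.variant]

    def loglik(params: PGParams) -> np.ndarray:
        sd_step = np.where(day_break[:, None], params.sigma_day[None, :],
                           params.sigma[None, :])
        out = _pf_pg_kernel(x, ysign, r, observed, sd_step, params.alpha,
                            params.beta, params.qdiag, params.w1_mean,
                            params.w1_sd, dyn, params.alpha0,
                            params.sigma_alpha, params.beta_sigma,
                            eps, us, False)
        if not out[-1]:
            raise ParticleDegeneracyError("particle weights underflowed")
        return out[0]

    return loglik


def pf_loglik(trials, regressors, params, mask=None, n_particles: int = 1000,
              seed: int = 0) -> np.ndarray:
    """Per-trial log predictive probabilities without trajectory storage."""
    post = particle_filter(trials, regressors, params, mask=mask,
                           n_particles=n_particles, seed=seed,
                           store_paths=False)
    return post.loglik_per_trial


def heldout_predictive(posterior: ParticlePosterior, trials=None,
                       mask: HeldoutMask | np.ndarray | None = None) -> np.ndarray:
    """Predictive log choice probabilities on the held-out trials.

    The mask must be the one the filter ran with; each entry is the log of
    the particle-mixture probability of the realized choice.
    """
    mask_arr = None if mask is None else np.asarray(
        mask.mask if isinstance(mask, HeldoutMask) else mask, bool)
    if mask_arr is None:
        mask_arr = posterior.mask
    if mask_arr is None:
        raise ValueError("no held-out mask available")
    if posterior.mask is not None and not np.array_equal(mask_arr, posterior.mask):
        raise ValueError("mask does not match the one used by the filter")
    return posterior.loglik_per_trial[mask_arr]
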