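"""Learning-vs-noise decomposition of inferred weight trajectories.

The state-space models write each weight update as a deterministic
learning-rule drift plus Gaussian noise.  Applying the fitted rule to the
animal's realized choices without noise gives a *learning* trajectory; the
gap between the inferred (posterior-mean) trajectory and the per-trial
drift defines the *noise* residual.  The learning fraction summarizes, per
trial, how much of the inferred update the learning rule explains: 0 for a
pure random-walk model, 1 for a noiseless deterministic learner.

Cohort-level analyses built on the same pieces: preferred-side weight
averages (sides relabeled by the larger learning rate), the
expected-reward-after-error statistic, residual-vs-fitted-noise
consistency, and dynamic-learning-rate trend summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import PGParams, vector_pg_drift
from .trials import RegressorMatrix, build_regressors, side_to_sign, trial_warp


def _drift_inputs(trials, regressors=None):
    regressors = regressors or build_regressors(trials)
    y = side_to_sign(trials["choice"]).astype(float)
    r = trials["reward"].to_numpy(float)
    return regressors.x, y, r


def learning_rollout(params: PGParams, trials, w_start: np.ndarray,
                     rate_traj: np.ndarray | None = None,
                     regressors: RegressorMatrix | None = None) -> np.ndarray:
    """Noise-free weight trajectory under the fitted rule and realized choices.

    ``w_{t+1} = w_t + rate_t * drift(w_t; x_t, y_t, r_t)`` with the decay
    included in the drift; ``rate_traj`` defaults to 1 everywhere (static
    variants) and should be the posterior-mean latent gain for the
    dynamic-rate variant.
    """
    x, y, r = _drift_inputs(trials, regressors)
    T = x.shape[0]
    if rate_traj is None:
        rate_traj = np.ones(T)
    rate_traj = np.asarray(rate_traj, float)
    if rate_traj.size != T:
        raise ValueError(f"rate_traj length {rate_traj.size} != {T} trials")
    w = np.asarray(w_start, float).copy()
    out = np.empty((T, w.size))
    for t in range(T):
        out[t] = w
        if t < T - 1:
            w = w + vector_pg_drift(w, x[t], y[t], r[t], params,
                                    rate_scale=rate_traj[t])
    return out


@dataclass
class Decomposition:
    """Per-trial split of inferred weight updates into learning and noise."""

    learning_traj: np.ndarray          # T x M noise-free rollout
    residual_traj: np.ndarray          # T x M inferred minus rollout
    delta_learn: np.ndarray            # (T-1) x M drift at the inferred weights
    residuals: np.ndarray              # (T-1) x M inferred update minus drift
    per_trial_learn_norm: np.ndarray
    per_trial_resid_norm: np.ndarray
    learning_fraction: float
    per_regressor_fraction: np.ndarray
    projection_fraction: float
    mean_cosine: float


def update_residuals(inferred: np.ndarray, params: PGParams, trials,
                     rate_traj: np.ndarray | None = None,
                     regressors: RegressorMatrix | None = None):
    """Learning-rule drifts at the inferred weights and their residuals.

    ``delta_learn[t] = drift(w_hat_t; x_t, y_t, r_t)`` and
    ``residual[t] = (w_hat_{t+1} - w_hat_t) - delta_learn[t]``; the inferred
    trajectory is reconstructed exactly by accumulating the two.
    """
    inferred = np.asarray(inferred, float)
    T = inferred.shape[0]
    if T < 2:
        raise ValueError("need at least 2 trials to form updates")
    x, y, r = _drift_inputs(trials, regressors)
    if x.shape[0] != T:
        raise ValueError("inferred trajectory and trials disagree in length")
    if rate_traj is None:
        rate_traj = np.ones(T)
    delta_learn = np.empty((T - 1, inferred.shape[1]))
    for t in range(T - 1):
        delta_learn[t] = vector_pg_drift(inferred[t], x[t], y[t], r[t], params,
                                         rate_scale=rate_traj[t])
    residuals = np.diff(inferred, axis=0) - delta_learn
    return delta_learn, residuals


def learning_fraction(delta_learn: np.ndarray, residuals: np.ndarray,
                      ratio_of_sums: bool = False):
    """Share of each inferred update explained by the learning rule.

    Per trial ``f_t = |dl_t| / (|dl_t| + |eps_t|)`` (0 when both norms are
    0), averaged over trials; exactly 0 when the learning term vanishes
    everywhere and exactly 1 when the residual does.  ``ratio_of_sums``
    instead returns ``sum|dl| / (sum|dl| + sum|eps|)``.  Per-regressor
    fractions use coordinate-wise absolute values.
    """
    ln = np.linalg.norm(delta_learn, axis=1)
    rn = np.linalg.norm(residuals, axis=1)
    # norms at float-recomputation level (e.g. (w + d) - w vs d) count as 0,
    # so the 0 and 1 endpoints are exact for pure-noise / noise-free input
    floor = 1e-10 * max(ln.max(initial=0.0), rn.max(initial=0.0))
    ln = np.where(ln <= floor, 0.0, ln)
    rn = np.where(rn <= floor, 0.0, rn)
    if ratio_of_sums:
        tot = ln.sum() + rn.sum()
        frac = float(ln.sum() / tot) if tot > 0 else 0.0
    else:
        tot = ln + rn
        f_t = np.divide(ln, tot, out=np.zeros_like(ln), where=tot > 0)
        frac = float(f_t.mean())
    la, ra = np.abs(delta_learn), np.abs(residuals)
    la = np.where(la <= floor, 0.0, la)
    ra = np.where(ra <= floor, 0.0, ra)
    tot_m = la + ra
    per_reg = np.divide(la, tot_m, out=np.zeros_like(la), where=tot_m > 0)
    per_reg = per_reg.mean(axis=0)
    return frac, per_reg


def decompose(inferred: np.ndarray, params: PGParams, trials,
              rate_traj: np.ndarray | None = None,
              regressors: RegressorMatrix | None = None,
              ratio_of_sums: bool = False) -> Decomposition:
    """Full learning/noise decomposition of an inferred weight trajectory."""
    inferred = np.asarray(inferred, float)
    delta_learn, residuals = update_residuals(inferred, params, trials,
                                              rate_traj, regressors)
    rollout = learning_rollout(params, trials, inferred[0], rate_traj,
                               regressors)
    frac, per_reg = learning_fraction(delta_learn, residuals, ratio_of_sums)

    dw = np.diff(inferred, axis=0)
    denom = float((dw * dw).sum())
    proj = float((dw * delta_learn).sum() / denom) if denom > 0 else 0.0
    norms = np.linalg.norm(dw, axis=1) * np.linalg.norm(delta_learn, axis=1)
    valid = norms > 0
    cosine = float(((dw * delta_learn).sum(axis=1)[valid] / norms[valid]).mean()) \
        if valid.any() else 0.0
    return Decomposition(
        learning_traj=rollout, residual_traj=inferred - rollout,
        delta_learn=delta_learn, residuals=residuals,
        per_trial_learn_norm=np.linalg.norm(delta_learn, axis=1),
        per_trial_resid_norm=np.linalg.norm(residuals, axis=1),
        learning_fraction=frac, per_regressor_fraction=per_reg,
        projection_fraction=proj, mean_cosine=cosine)


# ------------------------------------------------------- cohort analyses ---

def preferred_relabel(alphas_lr: np.ndarray, stim_weights: list,
                      grid_size: int = 100, seed: int = 0,
                      permutation: np.ndarray | None = None):
    """Cohort averages of |stimulus weights| sorted preferred/non-preferred.

    ``alphas_lr`` is (n_animals, 2) fitted (alpha_left, alpha_right);
    ``stim_weights`` holds per animal a (T_i, 2) array of (left, right)
    stimulus-weight trajectories.  Each animal's preferred side is the one
    with the larger learning rate; weight magnitudes are trial-warped to a
    common grid and averaged.  The control re-draws the animal-to-parameter
    assignment (a seeded permutation of ``alphas_lr`` rows) before sorting.

    Returns ``(preferred, nonpreferred, control_preferred,
    control_nonpreferred)``, each a length-``grid_size`` cohort mean.
    """
    alphas_lr = np.asarray(alphas_lr, float)
    n = alphas_lr.shape[0]
    if n < 2:
        raise ValueError("need a cohort of >= 2 animals to build a shuffle control")

    def averaged(assign):
        pref, nonpref = [], []
        for i in range(n):
            w = np.abs(np.asarray(stim_weights[i], float))
            hi = int(np.argmax(assign[i]))       # 0 = left preferred, 1 = right
            pref.append(w[:, hi])
            nonpref.append(w[:, 1 - hi])
        return (trial_warp(pref, grid_size).mean(axis=0),
                trial_warp(nonpref, grid_size).mean(axis=0))

    pref, nonpref = averaged(alphas_lr)
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(n)
    ctrl_pref, ctrl_nonpref = averaged(alphas_lr[np.asarray(permutation)])
    return pref, nonpref, ctrl_pref, ctrl_nonpref


def reward_after_error(trials) -> tuple[float, float]:
    """Mean reward on trials following an error, versus the overall mean.

    Computes ``E[r_{t+1} | r_t = 0]`` over within-session (t, t+1) pairs
    and the shuffled control ``E[r_t]``; a conditional mean below the
    overall mean indicates that errors beget further errors.
    """
    t = trials.reset_index(drop=True)
    r = t["reward"].to_numpy(float)
    same_session = np.diff(t["session"].to_numpy()) == 0
    after_error = (r[:-1] == 0) & same_session
    if not after_error.any():
        raise ValueError("no incorrect non-final trials; conditional undefined")
    return float(r[1:][after_error].mean()), float(r.mean())


def noise_consistency(mean_resid_norms, sigma_norms) -> tuple[float, float]:
    """Pearson correlation (and R^2) of residual norm vs fitted noise scale.

    Across animals, the trial-averaged residual norm of the decomposition
    should track the fitted ``||sigma||``; returns ``(rho, r_squared)``.
    """
    x = np.asarray(mean_resid_norms, float)
    y = np.asarray(sigma_norms, float)
    if x.size < 3:
        raise ValueError("need at least 3 animals for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) inputs; correlation undefined")
    rho = float(stats.pearsonr(x, y)[0])
    return rho, rho ** 2


def cumulative_accuracy(trials) -> np.ndarray:
    """Running fraction of rewarded trials."""
    correct = (trials["choice"] == trials["correct_side"]).to_numpy(float)
    return np.cumsum(correct) / np.arange(1, correct.size + 1)


def rate_trend_summary(rate_trajs: list, trials_list: list,
                       grid_size: int = 100, floor: float = 1e-6) -> dict:
    """Cohort summary of dynamic learning-rate trends.

    Per animal the posterior-mean latent rate is reduced to
    ``delta_log_alpha_t = log(alpha_t) - log(alpha_1)`` (rates floored at
    ``floor``; animals at the floor throughout are dropped with a warning),
    trial-warped to a common grid and averaged; cumulative accuracy is
    warped likewise.  Returns the cohort mean +/- SE of the rate trend,
    pointwise one-sample t statistics against 0, the warped accuracy mean,
    and the correlation between the two cohort means.
    """
    import warnings as _w
    dlogs, accs = [], []
    for rates, trials in zip(rate_trajs, trials_list):
        rates = np.maximum(np.asarray(rates, float), floor)
        if np.all(rates <= floor):
            _w.warn("animal with learning rate at floor throughout; excluded")
            continue
        dlogs.append(np.log(rates) - np.log(rates[0]))
        accs.append(cumulative_accuracy(trials))
    if not dlogs:
        raise ValueError("no usable animals")
    dlog_w = trial_warp(dlogs, grid_size)
    acc_w = trial_warp(accs, grid_size)
    n = dlog_w.shape[0]
    mean = dlog_w.mean(axis=0)
    se = dlog_w.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(grid_size)
    if n > 1:
        tstat, pval = stats.ttest_1samp(dlog_w, 0.0, axis=0)
    else:
        tstat = pval = np.full(grid_size, np.nan)
    acc_mean = acc_w.mean(axis=0)
    rho = float(stats.pearsonr(mean, acc_mean)[0]) \
        if np.ptp(mean) > 0 and np.ptp(acc_mean) > 0 else np.nan
    return {"delta_log_rate_mean": mean, "delta_log_rate_se": se,
            "t_stat": np.asarray(tstat), "p_value": np.asarray(pval),
            "cum_accuracy_mean": acc_mean, "rate_accuracy_corr": rho,
            "n_animals": n}
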