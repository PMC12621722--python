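"""Synthetic two-alternative forced-choice training data.

Generates session-structured trial tables under a configurable stimulus
curriculum (contrast levels introduced gradually, as in staged mouse
training, or uniformly from the first session) and simulates choices from
any of the generative learning models, returning the latent ground truth
(weight trajectories, dynamic learning-rate gains, dynamic baselines) for
parameter- and trajectory-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .models import (PGParams, TDRLParams, policy_prob, vector_pg_drift,
                     signed_stimulus)
from .trials import TRIAL_COLUMNS, validate_trials

#: IBL-style contrast set (fraction of full contrast).
DEFAULT_CONTRASTS = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.0)

#: Session (1-based) at which each contrast level unlocks in the default
#: staged schedule; levels 1.0 and 0.5 are present from the start.  The
#: schedule is configurable -- real training protocols advance per animal.
DEFAULT_INTRO_SESSIONS = {1.0: 1, 0.5: 1, 0.25: 6, 0.125: 9, 0.0625: 12, 0.0: 15}


@dataclass
class Curriculum:
    """Per-session stimulus distribution for a simulated training course.

    ``schedule="staged"`` introduces each contrast level at the session
    index given by ``intro_sessions`` (1-based); ``"uniform"`` presents all
    levels from session 1.  Within a session, available contrast levels are
    equiprobable and the stimulus side is R with probability ``side_prob``.
    """

    contrast_levels: Sequence[float] = DEFAULT_CONTRASTS
    schedule: str = "staged"
    intro_sessions: dict = field(default_factory=lambda: dict(DEFAULT_INTRO_SESSIONS))
    side_prob: float = 0.5
    n_sessions: int = 15
    trials_per_session: int | Sequence[int] = 400

    def __post_init__(self):
        self.contrast_levels = tuple(float(c) for c in self.contrast_levels)
        if not self.contrast_levels:
            raise ValueError("contrast set must be nonempty")
        if any(not 0 <= c <= 1 for c in self.contrast_levels):
            raise ValueError("contrast levels must lie in [0, 1]")
        if not 0 < self.side_prob < 1:
            raise ValueError("side_prob must be in (0, 1)")
        if self.schedule not in ("staged", "uniform"):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def session_lengths(self) -> np.ndarray:
        tps = self.trials_per_session
        if np.ndim(tps) == 0:
            return np.full(self.n_sessions, int(tps))
        arr = np.asarray(tps, int)
        if arr.size != self.n_sessions:
            raise ValueError("trials_per_session list must match n_sessions")
        return arr

    def available_contrasts(self, session: int) -> np.ndarray:
        """Contrast levels unlocked in 1-based ``session``."""
        if self.schedule == "uniform":
            return np.asarray(self.contrast_levels)
        avail = [c for c in self.contrast_levels
                 if session >= self.intro_sessions.get(c, 1)]
        if not avail:  # degenerate config: fall back to the easiest level
            avail = [max(self.contrast_levels)]
        return np.asarray(avail)

    def sample_session(self, session: int, n: int, rng: np.random.Generator):
        """Sample ``n`` (contrast, signed side) pairs for one session."""
        levels = self.available_contrasts(session)
        contrast = rng.choice(levels, size=n)
        side = np.where(rng.random(n) < self.side_prob, 1, -1)
        return contrast, side


def make_curriculum(config: dict | None = None) -> Curriculum:
    """Build a :class:`Curriculum` from a flat config mapping."""
    return Curriculum(**(config or {}))


@dataclass
class SimResult:
    """A simulated animal: trial table plus latent ground truth."""

    trials: pd.DataFrame
    true_weights: np.ndarray
    params: PGParams | TDRLParams
    seed: int
    true_rates: np.ndarray | None = None
    true_baselines: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.trials)


def _stimulus_table(curriculum: Curriculum, rng: np.random.Generator):
    """Draw the full stimulus sequence: session ids, contrasts, correct sides.

    On zero-contrast trials the rewarded side is still drawn from the side
    distribution, so every trial has a defined correct side.
    """
    lengths = curriculum.session_lengths()
    sessions, contrasts, sides = [], [], []
    for s, n in enumerate(lengths, start=1):
        c, side = curriculum.sample_session(s, int(n), rng)
        sessions.append(np.full(int(n), s))
        contrasts.append(c)
        sides.append(side)
    return (np.concatenate(sessions), np.concatenate(contrasts),
            np.concatenate(sides))


def _assemble_trials(session, contrast, side, choice, reward):
    T = session.size
    cl = np.where(side < 0, contrast, 0.0)
    cr = np.where(side > 0, contrast, 0.0)
    trials = pd.DataFrame({
        "session": session,
        "trial": np.arange(T),
        "contrast_left": cl,
        "contrast_right": cr,
        "correct_side": np.where(side > 0, "R", "L"),
        "choice": np.where(choice > 0, "R", "L"),
        "reward": reward,
    }, columns=list(TRIAL_COLUMNS))
    return validate_trials(trials)


def simulate_pg(params: PGParams, curriculum: Curriculum | None = None,
                seed: int = 0, rate_traj: np.ndarray | None = None) -> SimResult:
    """Forward-simulate a policy-gradient learner through a curriculum.

    Draws w_1 from its Gaussian prior, then per trial samples the choice
    from the logistic policy, computes the reward, and propagates the
    weights with the learning-rule drift plus Gaussian noise whose SD is
    ``sigma_day`` (per regressor) across session boundaries and ``sigma``
    within sessions.  The dynamic-rate variant evolves a latent learning
    gain by a Gaussian random walk; the dynamic-baseline variant does the
    same for the per-regressor baseline.

    ``rate_traj`` optionally imposes a fixed per-trial gain trajectory on
    the learning rule (e.g. a planted step change) instead of the model's
    own constant or random-walk gain -- used for recovery studies.
    """
    curriculum = curriculum or Curriculum()
    rng = np.random.default_rng(seed)
    session, contrast, side = _stimulus_table(curriculum, rng)
    T, m = session.size, params.m
    if rate_traj is not None:
        rate_traj = np.asarray(rate_traj, float)
        if rate_traj.size != T:
            raise ValueError(f"rate_traj length {rate_traj.size} != T={T}")

    w = rng.normal(params.w1_mean, params.w1_sd, size=m)
    rate = params.alpha0 if params.variant == "dynamic_rate" else 1.0
    if params.variant == "dynamic_rate" and params.sigma_alpha > 0:
        rate = rng.normal(params.alpha0, params.sigma_alpha)
    beta_t = params.beta.copy()

    weights = np.empty((T, m))
    rates = np.empty(T)
    baselines = np.empty((T, m))
    choice = np.empty(T, int)
    rew = np.empty(T)
    prev_choice = prev_side = 0.0
    x = np.empty(m)
    for t in range(T):
        if rate_traj is not None:
            rate = rate_traj[t]
        if t > 0 and session[t] != session[t - 1]:
            prev_choice = prev_side = 0.0
        x[0] = 1.0
        x[1] = contrast[t] if side[t] < 0 else 0.0
        x[2] = contrast[t] if side[t] > 0 else 0.0
        x[3] = prev_choice
        x[4] = prev_side
        weights[t] = w
        rates[t] = rate
        baselines[t] = beta_t

        p_r = policy_prob(w, x)
        y = 1 if rng.random() < p_r else -1
        r = params.rstar if y == side[t] else 0.0
        choice[t], rew[t] = y, r

        if t < T - 1:
            p = params if params.variant != "dynamic_baseline" else \
                _with_beta(params, beta_t)
            drift = vector_pg_drift(w, x, y, r, p, rate_scale=rate)
            sd = params.sigma_day if session[t + 1] != session[t] else params.sigma
            w = w + drift + rng.normal(0.0, 1.0, m) * sd
            if params.variant == "dynamic_rate":
                rate = rate + rng.normal(0.0, params.sigma_alpha) \
                    if params.sigma_alpha > 0 else rate
            if params.variant == "dynamic_baseline" and params.beta_sigma > 0:
                beta_t = beta_t + rng.normal(0.0, params.beta_sigma, m)
        prev_choice, prev_side = float(y), float(side[t])

    trials = _assemble_trials(session, contrast, side, choice, rew)
    keep_rates = params.variant == "dynamic_rate" or rate_traj is not None
    return SimResult(trials=trials, true_weights=weights, params=params,
                     seed=seed,
                     true_rates=rates if keep_rates else None,
                     true_baselines=baselines if params.variant == "dynamic_baseline" else None)


def _with_beta(params: PGParams, beta_t: np.ndarray) -> PGParams:
    p = PGParams(**{**params.to_dict(), "beta": beta_t, "variant": "vector_pg"})
    return p


def simulate_tdrl(params: TDRLParams, curriculum: Curriculum | None = None,
                  seed: int = 0) -> SimResult:
    """Forward-simulate the TD action-value learner with noisy percepts.

    Per trial the agent perceives ``m_t ~ N(s_t, sigma_m^2)`` of the signed
    contrast, chooses R when the percept clears the value-dependent
    criterion ``sigma_m * Phi^-1(V_L / (V_L + V_R))`` (with an optional
    symmetric lapse), collects the reward, and TD-updates the chosen value.
    The (V_L, V_R) trajectory is returned in the ``true_weights`` slots.
    """
    curriculum = curriculum or Curriculum()
    rng = np.random.default_rng(seed)
    session, contrast, side = _stimulus_table(curriculum, rng)
    T = session.size

    v = np.array(params.v_init, float)
    values = np.empty((T, 2))
    choice = np.empty(T, int)
    rew = np.empty(T)
    for t in range(T):
        values[t] = v
        s = contrast[t] * side[t]
        m_t = rng.normal(s, params.sigma_m)
        crit = params.sigma_m * ndtri(v[0] / (v[0] + v[1]))
        y = 1 if m_t > crit else -1
        if params.stochasticity > 0 and rng.random() < params.stochasticity:
            y = 1 if rng.random() < 0.5 else -1
        r = params.rstar if y == side[t] else 0.0
        choice[t], rew[t] = y, r
        if t < T - 1:
            from .models import tdrl_value_update
            v = tdrl_value_update(v, y, s, r, params, noise_draw=rng.normal())
            v = np.maximum(v, 1e-6)  # values stay positive for the criterion

    trials = _assemble_trials(session, contrast, side, choice, rew)
    return SimResult(trials=trials, true_weights=values, params=params, seed=seed)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-animal seeds from one master seed.

    Uses counter-based seed splitting, so extending a cohort never changes
    the seeds (hence the data) of earlier animals.
    """
    return [int(np.random.SeedSequence((master_seed, i)).generate_state(1)[0] % (2**31))
            for i in range(n)]


def simulate_cohort(n_animals: int,
                    param_sampler: Callable[[np.random.Generator], PGParams | TDRLParams],
                    curriculum: Curriculum | None = None,
                    seed: int = 0) -> list[SimResult]:
    """Simulate a cohort of independent animals.

    ``param_sampler(rng)`` draws one animal's generative parameters; each
    animal gets an independent seed derived from ``seed``.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    seeds = spawn_seeds(seed, 2 * n_animals)
    out = []
    for i in range(n_animals):
        rng = np.random.default_rng(seeds[2 * i])
        params = param_sampler(rng)
        sim = (simulate_tdrl if isinstance(params, TDRLParams) else simulate_pg)(
            params, curriculum, seed=seeds[2 * i + 1])
        out.append(sim)
    return out


def write_sim_result(sim: SimResult, trials_path, latents_path) -> None:
    """Write the trial table and the latent-truth table as delimited text."""
    from .trials import write_trials
    write_trials(sim.trials, trials_path)
    m = sim.true_weights.shape[1]
    names = ["w_bias", "w_stimL", "w_stimR", "w_prevchoice", "w_prevside"][:m] \
        if m != 2 else ["V_L", "V_R"]
    df = pd.DataFrame(sim.true_weights, columns=names)
    df.insert(0, "trial", np.arange(len(sim)))
    if sim.true_rates is not None:
        df["alpha_t"] = sim.true_rates
    df.to_csv(latents_path, index=False)
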