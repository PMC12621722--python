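"""Policy, reward, and learning-rule primitives.

The behavioral policy is a Bernoulli GLM: the probability of a rightward
choice is a logistic function of the weighted regressors,
``p(y=R) = 1 / (1 + exp(-w.x))``.  Learning is modeled as trial-by-trial
drift of the weights under a REINFORCE-style policy-gradient rule with a
per-regressor learning rate, reward baseline, and weight decay; dynamics
noise is handled by the simulator and particle filter, not here.

An action-value alternative is also provided: a temporal-difference (TD)
learner over left/right choice values driven by a noisy Gaussian percept of
the signed stimulus contrast, whose percept-marginalized choice rule is a
probit GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import log_ndtr, ndtri
from scipy.stats import norm

M_DEFAULT = 5

PG_VARIANTS = ("noise_only", "scalar_pg", "vector_pg", "dynamic_rate", "dynamic_baseline")

#: probabilities are clamped to this band before logs
P_CLIP = 1e-12


def _vec(value, m: int) -> np.ndarray:
    out = np.broadcast_to(np.asarray(value, float), (m,)).copy()
    return out


@dataclass
class PGParams:
    """Parameters of a policy-gradient learning model.

    Attributes
    ----------
    alpha : (M,) learning rates (per trial, dimensionless).
    beta : (M,) reward baseline subtracted from the scalar reward
        (broadcast per regressor); negative values reinforce errors.
    qdiag : (M,) weight-decay rates (exponential forgetting).
    sigma : (M,) within-session dynamics-noise SDs per trial.
    sigma_day : (M,) noise SDs applied across session boundaries.
    rstar : reward magnitude on correct trials.
    w1_mean, w1_sd : initial-weight prior N(w1_mean, w1_sd^2 I).
    alpha0, sigma_alpha : dynamic-rate variant only -- initial mean and
        random-walk SD of the latent multiplicative learning-rate gain.
    beta_sigma : dynamic-baseline variant only -- random-walk SD of the
        latent per-regressor baseline.
    variant : one of ``noise_only, scalar_pg, vector_pg, dynamic_rate,
        dynamic_baseline``.
    """

    alpha: np.ndarray | float = 0.0
    beta: np.ndarray | float = 0.0
    qdiag: np.ndarray | float = 0.0
    sigma: np.ndarray | float = 0.1
    sigma_day: np.ndarray | float = 0.1
    rstar: float = 1.0
    w1_mean: np.ndarray | float = 0.0
    w1_sd: float = 1.0
    alpha0: float = 1.0
    sigma_alpha: float = 0.0
    beta_sigma: float = 0.0
    variant: str = "vector_pg"
    m: int = M_DEFAULT

    def __post_init__(self):
        if self.variant not in PG_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("alpha", "beta", "qdiag", "sigma", "sigma_day", "w1_mean"):
            setattr(self, name, _vec(getattr(self, name), self.m))
        for name, val in (("sigma", self.sigma), ("sigma_day", self.sigma_day),
                          ("qdiag", self.qdiag)):
            if (val < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        if self.rstar <= 0:
            raise ValueError("rstar must be positive")
        if self.sigma_alpha < 0 or self.w1_sd < 0 or self.beta_sigma < 0:
            raise ValueError("scale parameters must be nonnegative")
        if self.variant == "noise_only":
            if np.any(self.alpha != 0) or np.any(self.qdiag != 0):
                raise ValueError("noise_only requires alpha == 0 and qdiag == 0")
        if self.variant == "scalar_pg":
            for name in ("alpha", "beta", "qdiag", "sigma", "sigma_day"):
                v = getattr(self, name)
                if np.ptp(v) != 0:
                    raise ValueError(f"scalar_pg requires constant {name} entries")

    def to_dict(self) -> dict:
        d = {}
        for k, v in asdict(self).items():
            d[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PGParams":
        return cls(**d)


@dataclass
class TDRLParams:
    """Parameters of the TD action-value model with noisy percepts.

    ``sigma_m`` is the percept-noise SD in contrast units, ``td_rate`` the
    TD step size scaling the belief-weighted reward-prediction error,
    ``v_init`` the initial (V_L, V_R) action values, and ``stochasticity``
    a symmetric lapse rate mixing the threshold choice rule with a coin
    flip (stand-in for decision noise; 0 disables it).
    """

    sigma_m: float = 0.3
    td_rate: float = 1.0
    v_init: tuple = (0.5, 0.5)
    stochasticity: float = 0.0
    rstar: float = 1.0

    def __post_init__(self):
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")
        if not 0 <= self.td_rate <= 1:
            raise ValueError("td_rate must be in [0, 1]")
        if min(self.v_init) <= 0:
            raise ValueError("initial values must be positive")
        if not 0 <= self.stochasticity <= 1:
            raise ValueError("stochasticity (lapse) must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["v_init"] = list(self.v_init)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TDRLParams":
        d = dict(d)
        if "v_init" in d:
            d["v_init"] = tuple(d["v_init"])
        return cls(**d)


# ---------------------------------------------------------------- policy ---

def policy_prob(w: np.ndarray, x: np.ndarray) -> float | np.ndarray:
    """P(choice = R | w, x) under the logistic policy, clamped away from 0/1."""
    z = np.asarray(w) @ np.asarray(x) if np.ndim(w) == 1 else np.sum(w * x, axis=-1)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-z))
    return np.clip(p, P_CLIP, 1.0 - P_CLIP)


def choice_loglik(w: np.ndarray, x: np.ndarray, y) -> float | np.ndarray:
    """log p(y | w, x) for signed choices y in {-1, +1}."""
    p_r = policy_prob(w, x)
    y = np.asarray(y)
    return np.where(y > 0, np.log(p_r), np.log1p(-p_r))


def correct_side_sign(x: np.ndarray, correct_side: int | None = None) -> int:
    """Signed correct side from a regressor row (or an explicit label).

    The side with non-zero stimulus contrast is correct; on zero-contrast
    trials an explicit ``correct_side`` (+1/-1) is required.
    """
    if correct_side is not None:
        return int(np.sign(correct_side))
    x = np.asarray(x)
    if x[2] > 0:
        return +1
    if x[1] > 0:
        return -1
    raise ValueError("zero-contrast trial: correct side must be supplied explicitly")


def reward(x: np.ndarray, y: int, rstar: float = 1.0,
           correct_side: int | None = None) -> float:
    """Scalar reward: ``rstar`` if the choice matches the correct side, else 0."""
    return rstar if np.sign(y) == correct_side_sign(x, correct_side) else 0.0


def expected_return(w: np.ndarray, x: np.ndarray, rstar: float = 1.0,
                    correct_side: int | None = None) -> float:
    """Expected reward J(w; x) = rstar * p(correct | w, x) under the policy."""
    c = correct_side_sign(x, correct_side)
    p_r = policy_prob(w, x)
    return float(rstar * (p_r if c > 0 else 1.0 - p_r))


def reinforce_update(w: np.ndarray, x: np.ndarray, y: int, r: float,
                     beta: np.ndarray | float = 0.0) -> np.ndarray:
    """REINFORCE weight increment with a per-regressor reward baseline.

    ``(r - beta) * (1 - p(y | w, x)) * sign(y) * x`` elementwise in beta.
    With beta = 0 this is an unbiased single-sample estimate of the
    expected-return gradient; any beta leaves its expectation unchanged.
    """
    p_y = np.exp(choice_loglik(w, x, y))
    return (r - np.asarray(beta, float)) * (1.0 - p_y) * np.sign(y) * np.asarray(x, float)


def vector_pg_drift(w: np.ndarray, x: np.ndarray, y: int, r: float,
                    params: PGParams, rate_scale: float = 1.0) -> np.ndarray:
    """Deterministic part of the weight update (learning plus decay).

    ``rate_scale`` is 1 for static variants and the latent gain alpha_t for
    the dynamic-rate variant; all vector products are elementwise.
    """
    return (rate_scale * params.alpha * reinforce_update(w, x, y, r, params.beta)
            - params.qdiag * np.asarray(w, float))


# ------------------------------------------------------------------ TDRL ---

def tdrl_choice_prob(v: Sequence[float], s: float, sigma_m: float):
    """P(choice = R | V, s) with the noisy percept marginalized out.

    Probit form ``Phi(s / sigma_m - Phi^-1(V_L / (V_L + V_R)))``: the agent
    chooses R whenever the percept exceeds the value-dependent criterion.
    """
    v_l, v_r = float(v[0]), float(v[1])
    if v_l + v_r <= 0:
        raise ValueError("V_L + V_R must be positive")
    z = np.asarray(s, float) / sigma_m - ndtri(v_l / (v_l + v_r))
    return norm.cdf(z)


def tdrl_choice_loglik(v, s, y, sigma_m: float, lapse: float = 0.0):
    """log p(y | V, s) under the probit choice rule with optional lapse."""
    v_l, v_r = float(v[0]), float(v[1])
    z = np.asarray(s, float) / sigma_m - ndtri(v_l / (v_l + v_r))
    y = np.asarray(y)
    if lapse == 0.0:
        return np.where(y > 0, log_ndtr(z), log_ndtr(-z))
    p_r = (1 - lapse) * norm.cdf(z) + lapse * 0.5
    p_r = np.clip(p_r, P_CLIP, 1 - P_CLIP)
    return np.where(y > 0, np.log(p_r), np.log1p(-p_r))


def tdrl_belief(y: int, s: float, sigma_m: float) -> float:
    """Belief that the chosen side is correct, Phi(|s| direction / (2 sigma_m)).

    ``p_correct(y = R | s) = Phi(s / (2 sigma_m))`` and symmetrically for L:
    the two-channel success probability of signal detection theory.
    """
    return float(norm.cdf(np.sign(y) * s / (2.0 * sigma_m)))


def tdrl_value_update(v: Sequence[float], y: int, s: float, r: float,
                      params: TDRLParams, noise_draw: float = 0.0) -> np.ndarray:
    """TD update of the chosen action value with percept-induced noise.

    ``V_y <- V_y + td_rate * (r - V_y * p_correct(y | s)) + V_y * phi(s) * eps``
    where ``phi`` is the N(0, sigma_m^2) density at ``s`` and ``eps`` the
    supplied standard-normal draw; the unchosen value is unchanged.
    """
    v = np.array(v, float)
    i = 1 if np.sign(y) > 0 else 0
    belief = tdrl_belief(y, s, params.sigma_m)
    noise_gain = norm.pdf(s, scale=params.sigma_m)
    v[i] = (v[i] + params.td_rate * (r - v[i] * belief)
            + v[i] * noise_gain * noise_draw)
    return v


def signed_stimulus(contrast_left, contrast_right) -> np.ndarray:
    """Signed contrast s = contrast_right - contrast_left (s > 0 favors R)."""
    return np.asarray(contrast_right, float) - np.asarray(contrast_left, float)
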