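"""Maximum-likelihood estimators for the learning-rule models.

:class:`PolicyGradientLearner` and :class:`TDRLLearner` follow the
scikit-learn estimator idiom (constructor hyperparameters, ``fit`` on a
trial table, fitted attributes with a trailing underscore).  Fitting
maximizes the particle-filter marginal likelihood over unconstrained
parameter coordinates (softplus for scale-like parameters; the reward
baseline through the error-trial rate) with common random numbers
freezing the filter's randomness per optimization pass, so each candidate
parameter point has a deterministic objective.  That surface is rough at
the nat scale, so the default optimizer is derandomized grid coordinate
descent (see ``_BaseLearner._optimize``); L-BFGS with central finite
differences is available for smooth problems.  A fraction of trials is
held out of the training objective as single-trajectory cross-validation;
full-trajectory and held-out log-likelihoods are both reported at the
optimum.

Parameter posteriors come from particle-marginal Metropolis-Hastings
(:func:`pmmh_sample`): random-walk proposals in the unconstrained
coordinates accepted against a fresh unbiased particle-filter likelihood
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .models import PGParams, TDRLParams, M_DEFAULT
from .particle import (make_loglik_fn, particle_filter,
                       ParticleDegeneracyError)
from .trials import HeldoutMask, build_regressors, heldout_mask


def softplus(x):
    return np.logaddexp(0.0, x)


def inv_softplus(y):
    y = np.asarray(y, float)
    return y + np.log(-np.expm1(-np.maximum(y, 1e-10)))


# ------------------------------------------------- parameter transforms ---

@dataclass
class _Param:
    name: str        # PGParams / TDRLParams field (or "a_err", see below)
    size: int        # 1 for scalar, M for per-regressor vector
    positive: bool   # softplus-constrained if True
    scale: float = 1.0   # characteristic coordinate scale for line searches


def _pg_param_spec(variant: str, m: int, constrain_alpha: bool) -> list[_Param]:
    # the reward baseline is fitted through the error-trial rate
    # a_err = -alpha * beta (the drift magnitude on unrewarded trials, in
    # weight units): the (alpha, beta) pair is a multiplicative "banana"
    # that traps coordinate searches, while (alpha, a_err) is additive --
    # the correct-trial rate is alpha * rstar + a_err, the error-trial
    # rate a_err itself
    if variant == "noise_only":
        return [_Param("sigma", m, True), _Param("sigma_day", m, True)]
    if variant == "scalar_pg":
        return [_Param("alpha", 1, constrain_alpha), _Param("a_err", 1, False, 0.2),
                _Param("qdiag", 1, True), _Param("sigma", 1, True),
                _Param("sigma_day", 1, True)]
    spec = [_Param("alpha", m, constrain_alpha), _Param("a_err", m, False, 0.2),
            _Param("qdiag", m, True), _Param("sigma", m, True),
            _Param("sigma_day", m, True)]
    if variant == "dynamic_rate":
        spec += [_Param("alpha0", 1, False), _Param("sigma_alpha", 1, True)]
    elif variant == "dynamic_baseline":
        spec += [_Param("beta_sigma", 1, True)]
    return spec


class _PGTransform:
    """Bijection between a PGParams variant and an unconstrained vector."""

    def __init__(self, variant: str, m: int = M_DEFAULT,
                 constrain_alpha: bool = True, base: PGParams | None = None):
        self.variant, self.m = variant, m
        self.spec = _pg_param_spec(variant, m, constrain_alpha)
        self.n_free = sum(p.size for p in self.spec)
        self.base = base or PGParams(variant=variant, m=m)

    def _get(self, params: PGParams, name: str) -> np.ndarray:
        if name == "a_err":
            return -params.alpha * params.beta
        return np.atleast_1d(np.asarray(getattr(params, name), float))

    def to_vector(self, params: PGParams) -> np.ndarray:
        out = []
        for p in self.spec:
            v = self._get(params, p.name)
            v = v[:1] if p.size == 1 else v
            out.append(inv_softplus(np.maximum(v, 1e-8)) if p.positive else v)
        return np.concatenate(out)

    def to_params(self, vec: np.ndarray) -> PGParams:
        d = self.base.to_dict()
        i = 0
        a_err = None
        for p in self.spec:
            v = np.asarray(vec[i:i + p.size], float)
            i += p.size
            if p.positive:
                v = softplus(v)
            if p.name == "a_err":
                a_err = v
                continue
            d[p.name] = float(v[0]) if p.size == 1 else v.tolist()
        if a_err is not None:
            alpha = np.broadcast_to(np.atleast_1d(d["alpha"]), a_err.shape)
            safe = np.where(np.abs(alpha) < 1e-8,
                            np.where(alpha < 0, -1e-8, 1e-8), alpha)
            beta = -a_err / safe
            d["beta"] = float(beta[0]) if self.variant == "scalar_pg" \
                else beta.tolist()
        d["variant"] = self.variant
        d["m"] = self.m
        return PGParams.from_dict(d)

    def labels(self) -> list[str]:
        out = []
        for p in self.spec:
            out += [p.name] if p.size == 1 else [f"{p.name}_{j}" for j in range(p.size)]
        return out

    def scales(self) -> np.ndarray:
        return np.concatenate([np.full(p.size, p.scale) for p in self.spec])


class _TDRLTransform:
    """Bijection between TDRLParams and an unconstrained vector."""

    spec = [_Param("sigma_m", 1, True), _Param("td_rate", 1, True),
            _Param("v_init", 2, True)]
    n_free = 4

    def __init__(self, base: TDRLParams | None = None):
        self.base = base or TDRLParams()

    def to_vector(self, params: TDRLParams) -> np.ndarray:
        return np.concatenate([
            inv_softplus([params.sigma_m]),
            [np.log(params.td_rate / (1 - params.td_rate + 1e-12))],
            inv_softplus(np.asarray(params.v_init)),
        ])

    def to_params(self, vec: np.ndarray) -> TDRLParams:
        d = self.base.to_dict()
        d["sigma_m"] = float(softplus(vec[0]))
        d["td_rate"] = float(1.0 / (1.0 + np.exp(-vec[1])))
        d["v_init"] = softplus(vec[2:4]).tolist()
        return TDRLParams.from_dict(d)

    def labels(self):
        return ["sigma_m", "td_rate", "v_init_L", "v_init_R"]

    def scales(self) -> np.ndarray:
        return np.ones(4)


# ------------------------------------------------------------ estimators ---

#: coordinate-descent visiting order: well-identified scales first
_CD_PRIORITY = ("sigma", "alpha", "a_err", "beta", "qdiag", "sigma_day",
                "alpha0", "sigma_alpha", "beta_sigma", "sigma_m", "td_rate",
                "v_init")


class _BaseLearner(BaseEstimator):
    """Shared fitting machinery for the particle-filter learners."""

    def _transform(self):
        raise NotImplementedError

    def _init_params(self):
        raise NotImplementedError

    def _cd_order(self, tf) -> np.ndarray:
        labels = [lbl.rsplit("_", 1)[0] if lbl[-1].isdigit() else lbl
                  for lbl in tf.labels()]
        rank = {n: i for i, n in enumerate(_CD_PRIORITY)}
        return np.argsort([rank.get(lbl, len(_CD_PRIORITY)) for lbl in labels],
                          kind="stable")

    def _scan_coordinates(self, objective, x, f, coords, widths):
        """One coordinate-descent pass: 9-point scan + local refinement."""
        n_grid = 9
        for k in coords:
            w = widths[k]
            grid = x[k] + np.linspace(-w, w, n_grid)
            vals = np.empty(n_grid)
            for g, v in enumerate(grid):
                xx = x.copy()
                xx[k] = v
                vals[g] = objective(xx)
            j = int(np.argmin(vals))
            if vals[j] < f:
                x[k], f = grid[j], float(vals[j])
            step = 2 * w / (n_grid - 1)
            for v in x[k] + np.linspace(-step, step, 5):
                xx = x.copy()
                xx[k] = v
                fv = objective(xx)
                if fv < f:
                    x[k], f = v, float(fv)
        return x, f

    def _optimize(self, make_objective, crn_seed, x0, tf):
        """Minimize the CRN objective from one start; returns (x, f, n_iter).

        The particle-filter likelihood under common random numbers is
        deterministic but non-smooth (resampling reshuffles whole particle
        histories), so the default ``grid_cd`` is derivative-free cyclic
        coordinate descent with an exhaustive bracket scan plus local
        refinement per coordinate, a bracket that halves between passes,
        and the frozen noise re-drawn each pass so no single Monte Carlo
        realization's jitter is optimized into the estimate.  A final
        polish pass revisits the noise-scale coordinates with four times
        the particles (their nat-scale likelihood signal is easily buried
        in filter jitter).  ``"coordinate"`` uses bounded Brent line
        searches instead (fewer evaluations, less reliable on rough
        surfaces); ``"lbfgs"`` uses L-BFGS-B with central differences
        (adequate only for smooth low-noise problems).
        """
        if self.optimizer == "grid_cd":
            x = np.asarray(x0, float).copy()
            order = self._cd_order(tf)
            scales = tf.scales()
            width = self.cd_width
            for p in range(self.cd_passes):
                objective = make_objective(crn_seed + p, self.n_particles)
                f = objective(x)
                x, f = self._scan_coordinates(objective, x, f, order,
                                              width * scales)
                width *= 0.5
            # noise scales: small likelihood signal, polish with less jitter
            noise_coords = [k for k, lbl in enumerate(tf.labels())
                            if lbl.startswith("sigma")]
            if noise_coords:
                objective = make_objective(crn_seed + self.cd_passes,
                                           4 * self.n_particles)
                f = objective(x)
                x, f = self._scan_coordinates(objective, x, f, noise_coords,
                                              0.5 * scales)
            else:
                objective = make_objective(crn_seed + self.cd_passes,
                                           self.n_particles)
                f = objective(x)
            return x, f, self.cd_passes
        objective = make_objective(crn_seed, self.n_particles)
        if self.optimizer == "lbfgs":
            h = self.fd_step

            def grad(vec):
                g = np.empty(vec.size)
                for k in range(vec.size):
                    e = np.zeros(vec.size)
                    e[k] = h
                    g[k] = (objective(vec + e) - objective(vec - e)) / (2 * h)
                return g

            res = minimize(objective, x0, jac=grad, method="L-BFGS-B",
                           options={"maxiter": self.max_iter, "ftol": 1e-8})
            return res.x, float(res.fun), int(res.nit)
        if self.optimizer != "coordinate":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        x = np.asarray(x0, float).copy()
        f = objective(x)
        order = self._cd_order(tf)
        width = self.cd_width
        for _ in range(self.cd_passes):
            for k in order:
                def f1d(v, _k=k):
                    xx = x.copy()
                    xx[_k] = v
                    return objective(xx)

                res = minimize_scalar(f1d, bounds=(x[k] - width, x[k] + width),
                                      method="bounded",
                                      options={"xatol": 0.02, "maxiter": 12})
                if res.fun < f:
                    x[k] = res.x
                    f = float(res.fun)
            width *= 0.5
        return x, f, self.cd_passes

    def _make_posterior(self, trials, params, mask, seed, n_particles=None):
        return particle_filter(
            trials, getattr(self, "_regressors", None), params, mask=mask,
            n_particles=n_particles or self.n_particles, seed=seed,
            store_paths=True)

    def fit(self, trials, y=None):
        """Fit by maximizing the masked particle-filter log-likelihood.

        ``trials`` is a validated trial table (DataFrame); ``y`` is ignored
        (choices live in the table) and exists for API compatibility.
        """
        trials = trials.reset_index(drop=True)
        T = len(trials)
        if T < 500:
            warnings.warn(f"only {T} trials; parameter estimates will be noisy")
        rng = np.random.default_rng(self.seed)
        self.mask_ = heldout_mask(T, self.heldout_frac,
                                  seed=int(rng.integers(2**31)))
        self._regressors = build_regressors(trials) \
            if not isinstance(self, TDRLLearner) else None
        tf = self._transform()
        crn_seed = int(rng.integers(2**31))
        template = tf.to_params(tf.to_vector(self._init_params()))
        observed = ~self.mask_.mask
        n_eval = [0]

        def make_objective(seed, n_particles):
            loglik_fn = make_loglik_fn(trials, self._regressors, template,
                                       mask=self.mask_,
                                       n_particles=n_particles, seed=seed)

            def objective(vec):
                try:
                    ll = loglik_fn(tf.to_params(vec))
                except (ParticleDegeneracyError, ValueError,
                        FloatingPointError):
                    return 1e12
                n_eval[0] += 1
                val = -float(ll[observed].sum())
                return val if np.isfinite(val) else 1e12

            return objective

        x0 = tf.to_vector(self._init_params())
        if make_objective(crn_seed, self.n_particles)(x0) >= 1e12:
            raise RuntimeError("non-finite objective at the initial point; "
                               "check parameter initialization")
        starts = [x0] + [x0 + rng.normal(0, 0.5, x0.size)
                         for _ in range(self.n_starts - 1)]
        candidates = []
        self.loglik_trace_ = []
        best_nit = 0
        for s0 in starts:
            xs, fs, nit = self._optimize(make_objective, crn_seed, s0, tf)
            self.loglik_trace_.append(-fs)
            candidates.append((xs, fs, nit))
        if len(candidates) == 1:
            best_x, best_f, best_nit = candidates[0]
        else:
            # compare starts under one common fresh-noise objective
            ref = make_objective(crn_seed + 7919, self.n_particles)
            scored = [(ref(xs), xs, nit) for xs, _, nit in candidates]
            fsel, best_x, best_nit = min(scored, key=lambda c: c[0])
            best_f = float(fsel)
        if best_f >= 1e12:
            raise RuntimeError("optimization failed to find a finite-likelihood point")

        self.params_ = tf.to_params(best_x)
        self.n_iter_ = int(best_nit)
        self.converged_ = True
        # evaluation at the optimum with fresh randomness
        eval_seed = int(rng.integers(2**31))
        self.posterior_ = self._make_posterior(trials, self.params_, self.mask_,
                                               eval_seed)
        self.loglik_full_ = self.posterior_.loglik_total
        self.loglik_train_ = self.posterior_.loglik_train
        self.loglik_heldout_ = self.posterior_.loglik_heldout
        self.n_evaluations_ = n_eval[0]
        return self

    def score(self, trials, y=None) -> float:
        """Full-trajectory log-likelihood of ``trials`` at the fitted parameters."""
        post = particle_filter(trials,
                               None if isinstance(self, TDRLLearner)
                               else build_regressors(trials),
                               self.params_, n_particles=self.n_particles,
                               seed=self.seed, store_paths=False)
        return post.loglik_total


class PolicyGradientLearner(_BaseLearner):
    """GLM policy with policy-gradient learning dynamics, fitted by SMC MLE.

    Parameters
    ----------
    variant : model family -- ``noise_only`` (random-walk weights, no
        learning term), ``scalar_pg`` (one shared learning rate, baseline,
        decay, noise scale), ``vector_pg`` (all of those per regressor),
        ``dynamic_rate`` (vector PG plus a latent random-walk learning-rate
        gain), ``dynamic_baseline`` (vector PG plus latent baselines).
    n_particles : particles in the bootstrap filter.
    heldout_frac : fraction of trials excluded from the training objective.
    n_starts : random restarts of the optimizer.
    optimizer : ``"grid_cd"`` (default; scan-based coordinate descent with
        per-pass noise refresh and a high-particle polish of the noise
        scales), ``"coordinate"`` (bounded Brent), or ``"lbfgs"``
        (central finite differences; smooth problems only).
    cd_passes, cd_width : coordinate-descent passes and initial bracket
        half-width (in unconstrained coordinates).
    max_iter, fd_step : L-BFGS iteration cap and difference step.
    constrain_alpha : keep learning rates nonnegative (softplus); set False
        to allow signed rates.
    init_params : optional PGParams starting point.
    seed : master seed for the mask, common random numbers, and restarts.

    Attributes (after ``fit``)
    --------------------------
    ``params_`` (PGParams at the optimum), ``posterior_``
    (:class:`ParticlePosterior` at the optimum, fresh seed), ``mask_``,
    ``loglik_full_`` / ``loglik_train_`` / ``loglik_heldout_``,
    ``loglik_trace_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, variant: str = "vector_pg", n_particles: int = 1000,
                 heldout_frac: float = 0.1, n_starts: int = 3,
                 max_iter: int = 50, fd_step: float = 0.02,
                 optimizer: str = "grid_cd", cd_passes: int = 3,
                 cd_width: float = 1.5,
                 constrain_alpha: bool = True, rstar: float = 1.0,
                 w1_mean: float = 0.0, w1_sd: float = 1.0, m: int = M_DEFAULT,
                 init_params: PGParams | None = None, seed: int = 0):
        self.variant = variant
        self.n_particles = n_particles
        self.heldout_frac = heldout_frac
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.fd_step = fd_step
        self.optimizer = optimizer
        self.cd_passes = cd_passes
        self.cd_width = cd_width
        self.constrain_alpha = constrain_alpha
        self.rstar = rstar
        self.w1_mean = w1_mean
        self.w1_sd = w1_sd
        self.m = m
        self.init_params = init_params
        self.seed = seed

    def _base_params(self) -> PGParams:
        return PGParams(variant=self.variant, m=self.m, rstar=self.rstar,
                        w1_mean=self.w1_mean, w1_sd=self.w1_sd)

    def _transform(self) -> _PGTransform:
        return _PGTransform(self.variant, self.m, self.constrain_alpha,
                            base=self._base_params())

    def _init_params(self) -> PGParams:
        if self.init_params is not None:
            return self.init_params
        d = self._base_params().to_dict()
        if self.variant != "noise_only":
            d["alpha"] = 0.05
            d["qdiag"] = 0.01
        d["sigma"] = 0.05
        d["sigma_day"] = 0.1
        if self.variant == "dynamic_rate":
            d["alpha0"], d["sigma_alpha"] = 1.0, 0.05
        if self.variant == "dynamic_baseline":
            d["beta_sigma"] = 0.01
        return PGParams.from_dict(d)

    def predict_proba(self, trials) -> np.ndarray:
        """P(choice = R) per trial under the smoothed posterior-mean weights.

        Valid for the trials the model was fitted on (the weight
        trajectory is trial-indexed).
        """
        from .models import policy_prob
        x = build_regressors(trials.reset_index(drop=True)).x
        w = self.posterior_.smooth_mean[:, :self.m]
        return policy_prob(w, x)


class TDRLLearner(_BaseLearner):
    """TD action-value model with noisy percepts, fitted by SMC MLE.

    Free parameters: percept-noise SD ``sigma_m``, TD step ``td_rate``, and
    the initial action values; the lapse rate is held at its constructor
    value.  See :class:`PolicyGradientLearner` for the shared fitting
    machinery and fitted attributes.
    """

    def __init__(self, n_particles: int = 1000, heldout_frac: float = 0.1,
                 n_starts: int = 3, max_iter: int = 50, fd_step: float = 0.02,
                 optimizer: str = "grid_cd", cd_passes: int = 3,
                 cd_width: float = 1.5,
                 stochasticity: float = 0.0, rstar: float = 1.0,
                 init_params: TDRLParams | None = None, seed: int = 0):
        self.n_particles = n_particles
        self.heldout_frac = heldout_frac
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.fd_step = fd_step
        self.optimizer = optimizer
        self.cd_passes = cd_passes
        self.cd_width = cd_width
        self.stochasticity = stochasticity
        self.rstar = rstar
        self.init_params = init_params
        self.seed = seed

    def _transform(self) -> _TDRLTransform:
        return _TDRLTransform(base=TDRLParams(
            stochasticity=self.stochasticity, rstar=self.rstar))

    def _init_params(self) -> TDRLParams:
        return self.init_params or TDRLParams(
            sigma_m=0.3, td_rate=0.5, v_init=(0.5, 0.5),
            stochasticity=self.stochasticity, rstar=self.rstar)


def fit_mle(trials, variant: str = "vector_pg", init=None,
            n_particles: int = 1000, seed: int = 0,
            mask_fraction: float = 0.1, **kwargs):
    """Fit a learning-rule model by particle-filter maximum likelihood.

    Thin wrapper: returns the fitted estimator (``variant="tdrl"`` selects
    :class:`TDRLLearner`), whose attributes carry the parameter estimates,
    posterior trajectories, held-out mask, and log-likelihoods.
    """
    if variant == "tdrl":
        est = TDRLLearner(n_particles=n_particles, seed=seed,
                          heldout_frac=mask_fraction, init_params=init, **kwargs)
    else:
        est = PolicyGradientLearner(variant=variant, n_particles=n_particles,
                                    seed=seed, heldout_frac=mask_fraction,
                                    init_params=init, **kwargs)
    return est.fit(trials)


# ------------------------------------------------------------------ PMMH ---

@dataclass
class MHChain:
    """Metropolis-Hastings draws in unconstrained coordinates."""

    draws: np.ndarray            # S x P
    acceptance_rate: float
    labels: list
    proposal_scale: float

    @property
    def posterior_sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.labels)


def pmmh_sample(trials=None, variant: str = "vector_pg",
                theta_init: PGParams | TDRLParams | None = None,
                n_particles: int = 1000, n_steps: int = 2000, seed: int = 0,
                burn_in: int | None = None, proposal_scale: float = 0.1,
                loglik_fn=None, x0: np.ndarray | None = None,
                labels: list | None = None, mask=None,
                adapt: bool = True) -> MHChain:
    """Particle-marginal Metropolis-Hastings over model parameters.

    Gaussian random-walk proposals in unconstrained coordinates; each
    proposal's log-likelihood is a fresh-randomness particle-filter
    estimate carried with the chain state (pseudo-marginal correctness).
    The scalar proposal scale adapts toward ~25% acceptance during burn-in
    (first quarter by default) and is then frozen; burn-in draws are
    discarded.

    ``loglik_fn(theta_vector) -> float`` bypasses the particle filter
    entirely (analytic targets, sampler validation); then ``x0`` gives the
    initial coordinates.
    """
    rng = np.random.default_rng(seed)
    if loglik_fn is None:
        if trials is None:
            raise ValueError("need trials when no analytic loglik_fn is given")
        regressors = build_regressors(trials) if variant != "tdrl" else None
        tf = _TDRLTransform(theta_init) if variant == "tdrl" else \
            _PGTransform(variant, base=theta_init if isinstance(theta_init, PGParams) else None)
        x0 = tf.to_vector(theta_init) if theta_init is not None else \
            np.zeros(tf.n_free)
        labels = tf.labels()

        def loglik_fn(vec, _seed=None):
            params = tf.to_params(vec)
            mseed = int(rng.integers(2**31)) if _seed is None else _seed
            try:
                post = particle_filter(trials, regressors, params, mask=mask,
                                       n_particles=n_particles, seed=mseed,
                                       store_paths=False)
            except ParticleDegeneracyError:
                return -np.inf
            ll = post.loglik_per_trial
            obs = np.ones(ll.size, bool) if mask is None else ~np.asarray(
                mask.mask if isinstance(mask, HeldoutMask) else mask, bool)
            return float(ll[obs].sum())
    else:
        _user_fn = loglik_fn
        loglik_fn = lambda vec, _seed=None: float(_user_fn(vec))
        if x0 is None:
            raise ValueError("x0 required with an analytic loglik_fn")
    x0 = np.atleast_1d(np.asarray(x0, float))
    P = x0.size
    labels = labels or [f"p{k}" for k in range(P)]
    burn_in = n_steps // 4 if burn_in is None else burn_in

    cur = x0.copy()
    cur_ll = loglik_fn(cur)
    if not np.isfinite(cur_ll):
        raise ValueError("initial point has non-finite likelihood")
    scale = float(proposal_scale)
    draws = np.empty((n_steps, P))
    n_acc = n_acc_post = 0
    window_acc, window = 0, 0
    for s in range(n_steps):
        prop = cur + (rng.standard_normal(P) * scale if scale > 0 else 0.0)
        prop_ll = loglik_fn(prop)
        if np.log(rng.random()) < prop_ll - cur_ll:
            cur, cur_ll = prop, prop_ll
            n_acc += 1
            window_acc += 1
            if s >= burn_in:
                n_acc_post += 1
        elif s >= burn_in:
            pass
        window += 1
        if adapt and s < burn_in and window == 50:
            rate = window_acc / window
            scale *= np.exp(0.5 * (rate - 0.25))
            window_acc = window = 0
        draws[s] = cur
    kept = draws[burn_in:]
    acc_rate = n_acc / n_steps
    if acc_rate < 0.01:
        warnings.warn(f"PMMH acceptance rate {acc_rate:.3f} < 1% after "
                      "adaptation; posterior draws are unreliable")
    return MHChain(draws=kept, acceptance_rate=acc_rate, labels=list(labels),
                   proposal_scale=scale)


# ------------------------------------------------------- model comparison ---

def compare_models(fits: dict, baseline: str) -> pd.DataFrame:
    """Full-trajectory log-likelihood differences against a baseline model.

    ``fits`` maps model names to fitted estimators trained on the same
    trials and held-out mask; positive ``delta_loglik`` means better than
    the baseline.
    """
    if baseline not in fits:
        raise ValueError(f"baseline {baseline!r} not among fitted models")
    masks = [np.asarray(f.mask_.mask) for f in fits.values()]
    if any(not np.array_equal(masks[0], mk) for mk in masks[1:]):
        raise ValueError("fits use different held-out masks; refit with a "
                         "common mask seed")
    base_ll = fits[baseline].loglik_full_
    rows = [{"model": name, "loglik_full": f.loglik_full_,
             "loglik_heldout": f.loglik_heldout_,
             "delta_loglik": f.loglik_full_ - base_ll}
            for name, f in fits.items()]
    return pd.DataFrame(rows).set_index("model")
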