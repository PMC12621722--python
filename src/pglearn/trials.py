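"""Trial tables for two-alternative forced-choice behavior.

A trial table is a :class:`pandas.DataFrame` with one row per trial and the
columns ``session, trial, contrast_left, contrast_right, correct_side,
choice, reward``.  Sides are encoded ``"L"``/``"R"`` on disk; internally
choices and sides map to the signed coding L -> -1, R -> +1, so that the
sign of a choice is the choice itself.

The module also builds the design (regressor) matrix of the Bernoulli-GLM
policy, draws held-out trial masks for cross-validated fitting, and warps
per-animal trial series onto a common grid for cohort averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

TRIAL_COLUMNS = (
    "session",
    "trial",
    "contrast_left",
    "contrast_right",
    "correct_side",
    "choice",
    "reward",
)

#: Signed coding of sides used throughout: left -1, right +1.
SIDE_CODE = {"L": -1, "R": +1}

REGRESSOR_NAMES = ("bias", "stim_left", "stim_right", "prev_choice", "prev_correct_side")


def side_to_sign(labels) -> np.ndarray:
    """Map ``"L"``/``"R"`` labels to the signed -1/+1 coding."""
    arr = np.asarray(labels)
    out = np.where(arr == "R", 1, -1)
    bad = ~np.isin(arr, ["L", "R"])
    if bad.any():
        raise ValueError(f"non-binary side label at row {int(np.flatnonzero(bad)[0])}")
    return out.astype(np.int8)


def validate_trials(trials: pd.DataFrame, rstar: float | None = None) -> pd.DataFrame:
    """Check trial-table invariants, raising ``ValueError`` naming the first bad row.

    Checks: required columns present; side labels binary; session ids
    non-decreasing in trial order; reward positive exactly on correct trials
    (and equal to ``rstar`` if given); contrasts in [0, 1] with at most one
    side non-zero.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {missing}")
    t = trials.reset_index(drop=True)

    for col in ("correct_side", "choice"):
        bad = ~t[col].isin(["L", "R"])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-binary {col} label {t[col][row]!r} at row {row}")

    sess = t["session"].to_numpy()
    if (np.diff(sess) < 0).any():
        row = int(np.flatnonzero(np.diff(sess) < 0)[0]) + 1
        raise ValueError(f"session id decreases at row {row}")

    cl = t["contrast_left"].to_numpy(float)
    cr = t["contrast_right"].to_numpy(float)
    if ((cl < 0) | (cl > 1) | (cr < 0) | (cr > 1)).any():
        row = int(np.flatnonzero((cl < 0) | (cl > 1) | (cr < 0) | (cr > 1))[0])
        raise ValueError(f"contrast outside [0, 1] at row {row}")
    both = (cl > 0) & (cr > 0)
    if both.any():
        row = int(np.flatnonzero(both)[0])
        raise ValueError(f"both contrasts non-zero at row {row}")

    r = t["reward"].to_numpy(float)
    correct = (t["choice"] == t["correct_side"]).to_numpy()
    bad = (r > 0) != correct
    if rstar is not None:
        bad |= correct & (r != rstar)
    if (r < 0).any() or bad.any():
        row = int(np.flatnonzero((r < 0) | bad)[0])
        raise ValueError(f"reward inconsistent with choice/correct_side at row {row}")
    return t


def read_trials(path, rstar: float | None = None) -> pd.DataFrame:
    """Read and validate a comma-delimited trial table."""
    trials = pd.read_csv(path)
    return validate_trials(trials, rstar=rstar)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-delimited text (UTF-8, header row)."""
    trials.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))


def build_regressors(
    trials: pd.DataFrame,
    contrast_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> "RegressorMatrix":
    """Build the T x 5 design matrix of the choice policy.

    Columns are ``(bias, stim_left, stim_right, prev_choice,
    prev_correct_side)``.  The bias column is identically 1; contrasts enter
    untransformed unless ``contrast_transform`` (a monotone elementwise map)
    is given; the history columns carry the previous trial's choice and
    correct side in signed coding, reset to 0 on each session's first trial
    so the matrix stays aligned with the trial table.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    t = trials.reset_index(drop=True)
    T = len(t)
    cl = t["contrast_left"].to_numpy(float)
    cr = t["contrast_right"].to_numpy(float)
    if contrast_transform is not None:
        cl, cr = contrast_transform(cl), contrast_transform(cr)
    choice = side_to_sign(t["choice"]).astype(float)
    side = side_to_sign(t["correct_side"]).astype(float)

    x = np.empty((T, 5))
    x[:, 0] = 1.0
    x[:, 1] = cl
    x[:, 2] = cr
    x[1:, 3] = choice[:-1]
    x[1:, 4] = side[:-1]
    x[0, 3:] = 0.0
    first = np.zeros(T, bool)
    first[0] = True
    first[1:] = np.diff(t["session"].to_numpy()) != 0
    x[first, 3:] = 0.0
    return RegressorMatrix(x=x, names=REGRESSOR_NAMES, session=t["session"].to_numpy())


@dataclass
class RegressorMatrix:
    """Design matrix of the policy plus regressor names and session ids."""

    x: np.ndarray
    names: Sequence[str] = REGRESSOR_NAMES
    session: np.ndarray | None = None

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def session_start(self) -> np.ndarray:
        """Boolean vector marking each session's first trial (False at t=0)."""
        T = len(self)
        out = np.zeros(T, bool)
        if self.session is not None and T > 1:
            out[1:] = np.diff(self.session) != 0
        return out


@dataclass
class HeldoutMask:
    """Trials excluded from the training objective (True = held out)."""

    mask: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)

    def __len__(self) -> int:
        return self.mask.size


def heldout_mask(T: int, fraction: float = 0.1, seed: int = 0) -> HeldoutMask:
    """Draw a uniformly-random held-out subset of ``round(fraction * T)`` trials.

    Rounding is round-half-even; the draw is without replacement and fully
    determined by ``seed``.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"heldout fraction must be in [0, 1), got {fraction}")
    n_out = int(round(fraction * T))
    mask = np.zeros(T, bool)
    if n_out:
        rng = np.random.default_rng(seed)
        mask[rng.choice(T, size=n_out, replace=False)] = True
    return HeldoutMask(mask=mask, fraction=fraction, seed=seed)


def trial_warp(series: Sequence[np.ndarray] | np.ndarray, grid_size: int = 100) -> np.ndarray:
    """Warp trial-indexed series onto a shared [0, 1] grid.

    Each series' trial axis is linearly rescaled to [0, 1] and the values
    linearly interpolated onto ``grid_size`` evenly spaced points, so that
    animals trained for different numbers of trials can be averaged
    pointwise.  Accepts a single 1-D series or a sequence of them; returns
    an array of shape ``(grid_size,)`` or ``(n_series, grid_size)``.
    """
    single = isinstance(series, np.ndarray) and np.ndim(series) == 1
    seq = [series] if single else list(series)
    grid = np.linspace(0.0, 1.0, grid_size)
    out = np.empty((len(seq), grid_size))
    for i, s in enumerate(seq):
        s = np.asarray(s, float)
        if s.ndim != 1 or s.size < 2:
            raise ValueError("each series must be 1-D with at least 2 points")
        out[i] = np.interp(grid, np.linspace(0.0, 1.0, s.size), s)
    return out[0] if single else out
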