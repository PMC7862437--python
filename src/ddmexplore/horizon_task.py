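"""Generative model of the horizon-style bandit task and synthetic behavior.

A game presents two slot machines paying integer rewards in [1, 100], drawn
from Gaussians (SD 8 points) whose means differ by a fixed gap.  One machine
("anchor") has mean 40 or 60; the other sits 4, 8, 12, 20 or 30 points above
or below it.  Four instructed trials establish either an unequal [1 3] or an
equal [2 2] information condition, after which the subject makes 1 (horizon
1) or 6 (horizon 6) free choices.  Only the first free choice is modeled:
its reward difference dR (mean observed left reward minus mean observed
right) and information difference dI (+1 left more informative, -1 right,
0 equal) drive a condition-dependent drift-diffusion response.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ddm_core
from .config import SIM_DT, SIM_MAX_TIME, logger

__all__ = [
    "GameSpec",
    "ANCHOR_MEANS",
    "GAPS",
    "REWARD_SD",
    "TRIAL_COLUMNS",
    "generate_game",
    "draw_reward",
    "draw_rewards",
    "compute_first_choice_features",
    "simulate_dataset",
    "default_coefficients",
]

ANCHOR_MEANS = (40, 60)
GAPS = (4, 8, 12, 20, 30)
REWARD_SD = 8.0
HORIZONS = (1, 6)
INFO_CONDITIONS = ("unequal_13", "equal_22")

#: Column schema of the tidy trial table (one row per modeled trial).
TRIAL_COLUMNS = [
    "subject_id", "game_id", "horizon", "info_condition",
    "trial_index", "is_free", "delta_R", "delta_I", "action", "rt",
]


@dataclass(frozen=True)
class GameSpec:
    """One game: bandit means, horizon, and the four instructed sides."""

    game_id: int
    horizon: int
    info_condition: str
    mean_left: float
    mean_right: float
    instructed_sides: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.horizon not in HORIZONS:
            raise ValueError(f"horizon must be one of {HORIZONS}, got {self.horizon}")
        if self.info_condition not in INFO_CONDITIONS:
            raise ValueError(f"unknown info_condition {self.info_condition!r}")
        means = (self.mean_left, self.mean_right)
        if not any(m in ANCHOR_MEANS for m in means):
            raise ValueError("one bandit mean must be 40 or 60")
        if round(abs(self.mean_left - self.mean_right)) not in GAPS:
            raise ValueError(f"|mean gap| must be in {GAPS}")
        counts = (self.instructed_sides.count("left"), self.instructed_sides.count("right"))
        if len(self.instructed_sides) != 4 or any(
                s not in ("left", "right") for s in self.instructed_sides):
            raise ValueError("instructed_sides must be 4 entries of 'left'/'right'")
        want = {(1, 3), (3, 1)} if self.info_condition == "unequal_13" else {(2, 2)}
        if counts not in want:
            raise ValueError(
                f"instructed side counts {counts} inconsistent with {self.info_condition}")


def generate_game(rng_seed, horizon: int, info_condition: str, game_id: int = 0) -> GameSpec:
    """Draw a game uniformly: anchor mean, anchor side, gap sign and size, and
    the instructed-trial order are each uniform over their admissible sets.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    if horizon not in HORIZONS:
        raise ValueError(f"horizon must be one of {HORIZONS}, got {horizon}")
    if info_condition not in INFO_CONDITIONS:
        raise ValueError(f"unknown info_condition {info_condition!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    anchor = float(rng.choice(ANCHOR_MEANS))
    gap = float(rng.choice(GAPS)) * (1.0 if rng.random() < 0.5 else -1.0)
    other = anchor + gap
    if rng.random() < 0.5:
        mean_left, mean_right = anchor, other
    else:
        mean_left, mean_right = other, anchor
    if info_condition == "unequal_13":
        once = "left" if rng.random() < 0.5 else "right"
        sides = [once] + ["right" if once == "left" else "left"] * 3
    else:
        sides = ["left", "left", "right", "right"]
    order = rng.permutation(4)
    sides = tuple(sides[i] for i in order)
    return GameSpec(game_id=game_id, horizon=horizon, info_condition=info_condition,
                    mean_left=mean_left, mean_right=mean_right, instructed_sides=sides)


def draw_reward(mean: float, rng, sd: float = REWARD_SD, method: str = "resample") -> int:
    """One integer reward in [1, 100] from the truncated, rounded Gaussian.

    ``method="resample"`` (default) samples N(mean, sd^2), rounds to the
    nearest integer and rejects values outside [1, 100] -- i.e. the truncated
    distribution.  ``method="round_clip"`` instead clips out-of-range values
    to the edges (inflates mass at 1 and 100; provided for comparison).
    ``sd=0`` is a degenerate test hook returning round(mean).
    """
    return int(draw_rewards(mean, 1, rng, sd=sd, method=method)[0])


def draw_rewards(mean: float, size: int, rng, sd: float = REWARD_SD,
                 method: str = "resample") -> np.ndarray:
    """Vectorized form of :func:`draw_reward`."""
    if not np.isfinite(mean):
        raise ValueError("mean must be finite")
    if sd == 0:
        r = int(round(mean))
        if not 1 <= r <= 100:
            raise ValueError(f"degenerate sd=0 mean {mean} outside [1, 100]")
        return np.full(size, r, dtype=int)
    if method == "round_clip":
        x = np.rint(rng.normal(mean, sd, size=size))
        return np.clip(x, 1, 100).astype(int)
    if method != "resample":
        raise ValueError(f"unknown rounding method {method!r}")
    out = np.empty(size, dtype=int)
    need = np.arange(size)
    while need.size:
        x = np.rint(rng.normal(mean, sd, size=need.size))
        good = (x >= 1) & (x <= 100)
        out[need[good]] = x[good].astype(int)
        need = need[~good]
    return out


def compute_first_choice_features(game: GameSpec,
                                  instructed_rewards: Sequence[float]) -> tuple[float, int]:
    """(delta_R, delta_I) observable at the first free choice.

    ``instructed_rewards`` are the four instructed-trial payouts in the same
    order as ``game.instructed_sides``.  delta_R is the mean observed left
    reward minus the mean observed right reward; delta_I is +1/-1 for the
    side played once in the unequal condition, 0 in the equal condition.
    """
    if len(instructed_rewards) != len(game.instructed_sides):
        raise ValueError("need exactly one reward per instructed trial")
    left = [r for r, s in zip(instructed_rewards, game.instructed_sides) if s == "left"]
    right = [r for r, s in zip(instructed_rewards, game.instructed_sides) if s == "right"]
    if not left or not right:
        raise ValueError("each side needs at least one instructed observation")
    delta_R = float(np.mean(left) - np.mean(right))
    if game.info_condition == "equal_22":
        delta_I = 0
    else:
        delta_I = 1 if len(left) == 1 else -1
    return delta_R, delta_I


# ----------------------------------------------------------------------
# dataset simulation
# ----------------------------------------------------------------------

def default_coefficients() -> Mapping[int, ddm_core.DDMCoefficients]:
    """Generating coefficients per horizon used as the package's default
    synthetic study conditions.

    Horizon 1: reward-on-drift cR_mu = -0.07 (negative under this package's
    boundary orientation; equivalent logistic noise ~6 points), information
    bonus cI_mu/cR_mu = 3 points, baseline threshold 0.85, T0 = 0.25 s, bias
    and threshold-slope coefficients 0.  Horizon 6 scales cR_mu by 0.645 and
    c0_beta by 0.933 (more random exploration, dominated by the drift change)
    and raises the information bonus to 12 points (more directed exploration).
    """
    h1 = ddm_core.DDMCoefficients(
        c0_mu=0.0, cR_mu=-0.07, cI_mu=-0.21,
        c0_beta=0.85, cR_beta=0.0, cI_beta=0.0,
        c0_alpha=0.0, cR_alpha=0.0, cI_alpha=0.0, T0=0.25)
    h6 = ddm_core.DDMCoefficients(
        c0_mu=0.0, cR_mu=-0.07 * 0.645, cI_mu=-0.07 * 0.645 * 12.0,
        c0_beta=0.85 * 0.933, cR_beta=0.0, cI_beta=0.0,
        c0_alpha=0.0, cR_alpha=0.0, cI_alpha=0.0, T0=0.25)
    return {1: h1, 6: h6}


def simulate_dataset(ddm_coeffs_by_horizon: Mapping[int, ddm_core.DDMCoefficients],
                     n_games_per_cell: int, rng_seed, subject_id: str = "sim00",
                     dt: float = SIM_DT, max_time: float = SIM_MAX_TIME,
                     reward_method: str = "resample",
                     emit_later_trials: bool = False) -> pd.DataFrame:
    """Simulate first-free-choice behavior for one synthetic subject.

    One trial record per game, balanced over 2 horizons x 2 information
    conditions (``n_games_per_cell`` games each).  Games whose resolved
    threshold is non-positive, or whose simulated path is censored at
    ``max_time``, are logged and resampled.  Deterministic given the seed.

    ``emit_later_trials`` is reserved for task-presentation extensions;
    only the first free choice is generated (the analysis surface).
    """
    if emit_later_trials:
        raise NotImplementedError("only first free-choice trials are modeled")
    if n_games_per_cell < 1:
        raise ValueError("n_games_per_cell must be >= 1")
    for h in HORIZONS:
        if h not in ddm_coeffs_by_horizon:
            raise ValueError(f"missing coefficients for horizon {h}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)

    rows: list[dict] = []
    game_id = 0
    n_failures = 0
    for horizon in HORIZONS:
        coeffs = ddm_coeffs_by_horizon[horizon]
        for cond in INFO_CONDITIONS:
            # resample failed games until the cell is filled
            todo = n_games_per_cell
            while todo:
                feats = []
                for _ in range(todo):
                    game = generate_game(rng, horizon, cond, game_id=game_id)
                    game_id += 1
                    rewards = [draw_reward(
                        game.mean_left if s == "left" else game.mean_right,
                        rng, method=reward_method) for s in game.instructed_sides]
                    dR, dI = compute_first_choice_features(game, rewards)
                    feats.append((game.game_id, dR, dI))
                gids = np.array([f[0] for f in feats])
                dR = np.array([f[1] for f in feats])
                dI = np.array([f[2] for f in feats])
                mu, beta, alpha = ddm_core.resolve_linear(coeffs, dR, dI)
                ok = beta > 0
                n_failures += int((~ok).sum())
                if ok.any():
                    act, rt, cen = ddm_core.simulate_paths(
                        mu[ok], beta[ok], alpha[ok], coeffs.T0, rng,
                        dt=dt, max_time=max_time)
                    n_failures += int(cen.sum())
                    for g, r, i, a, t, c in zip(
                            gids[ok], dR[ok], dI[ok], act, rt, cen):
                        if c:
                            continue
                        rows.append(dict(
                            subject_id=subject_id, game_id=int(g), horizon=horizon,
                            info_condition=cond, trial_index=5, is_free=True,
                            delta_R=float(r), delta_I=int(i), action=int(a),
                            rt=float(t)))
                todo = n_games_per_cell - sum(
                    1 for r in rows
                    if r["horizon"] == horizon and r["info_condition"] == cond)
    if n_failures:
        logger.info("simulate_dataset: resampled %d failed games (invalid threshold "
                    "or censored path)", n_failures)
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df.reset_index(drop=True)
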