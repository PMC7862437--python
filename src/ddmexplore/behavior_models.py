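r"""Descriptive models fit alongside the diffusion model.

Logistic choice model (per subject):

    p(choose left) = 1 / (1 + exp(-(dR + A*dI + B) / (sqrt(2) sigma)))

with information bonus A (points, shared across information conditions
within a horizon; it only acts in the unequal condition where dI = +/-1),
spatial bias B (points) and decision-noise SD sigma (points), the latter two
fit per horizon x information condition.  Fitting is maximum a posteriori
with an exponential prior on sigma (mean 20 points) and a Gaussian prior on
A (mean 0, SD 20 points); B carries no prior and is merely bounded.

Linear response-time regression (per subject x horizon x condition):

    RT = beta0 + betaR * a * dR + betaI * a * dI

with the action a coded +1 left / -1 right.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

__all__ = [
    "LogisticParams",
    "RTRegressionParams",
    "MissingCellError",
    "logistic_choice_prob",
    "fit_logistic",
    "fit_rt_regression",
    "SIGMA_PRIOR_MEAN",
    "A_PRIOR_SD",
]

SIGMA_PRIOR_MEAN = 20.0   # points; exponential prior length scale on sigma
A_PRIOR_SD = 20.0         # points; zero-mean Gaussian prior SD on A
_B_BOUND = 100.0          # stability bound; B itself is unpenalized
_A_BOUND = 100.0
_SIGMA_BOUNDS = (1e-3, 200.0)


class MissingCellError(ValueError):
    """A horizon x condition cell required for fitting has no trials."""


@dataclass(frozen=True)
class LogisticParams:
    """Logistic choice parameters for one horizon x information cell."""

    A: float
    B: float
    sigma: float
    converged: bool = True
    log_posterior: float = float("nan")
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class RTRegressionParams:
    """RT regression coefficients for one cell; betaI is NaN where dI never varies."""

    beta0: float
    betaR: float
    betaI: float
    rank_deficient: bool = False
    n_trials: int = 0


def logistic_choice_prob(params: LogisticParams, delta_R, delta_I):
    """p(choose left) under the logistic choice model."""
    z = (np.asarray(delta_R, float) + params.A * np.asarray(delta_I, float)
         + params.B) / (math.sqrt(2.0) * params.sigma)
    return _stable_expit(z)


def _stable_expit(z):
    out = np.empty(np.shape(z) or (1,), float)
    z = np.atleast_1d(np.asarray(z, float))
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.size > 1 else float(out[0])


def _bernoulli_nll(y, dR, dI, A, B, sigma):
    z = (dR + A * dI + B) / (math.sqrt(2.0) * sigma)
    # log(1+e^-z) stable in both tails
    log_p = -np.logaddexp(0.0, -z)
    log_q = -np.logaddexp(0.0, z)
    return -(y * log_p + (1 - y) * log_q).sum()


def _fit_cell(y, dR, dI, fit_A, rng, n_starts):
    """MAP fit of one cell; returns (A, B, sigma, neg_log_post, converged)."""

    def obj(theta):
        if fit_A:
            A, B, sigma = theta
        else:
            A = 0.0
            B, sigma = theta
        nll = _bernoulli_nll(y, dR, dI, A, B, sigma)
        nll += sigma / SIGMA_PRIOR_MEAN            # exponential prior, mean 20
        if fit_A:
            nll += A**2 / (2.0 * A_PRIOR_SD**2)    # Gaussian prior, SD 20
        return nll

    bounds = ([(-_A_BOUND, _A_BOUND)] if fit_A else []) + \
        [(-_B_BOUND, _B_BOUND), _SIGMA_BOUNDS]
    starts = [([0.0] if fit_A else []) + [0.0, 10.0]]
    for _ in range(n_starts - 1):
        s = ([rng.uniform(-25, 25)] if fit_A else []) + \
            [rng.uniform(-8, 8), float(np.exp(rng.uniform(np.log(0.5), np.log(60.0))))]
        starts.append(s)
    best = None
    for s in starts:
        r = minimize(obj, np.asarray(s, float), method="L-BFGS-B", bounds=bounds)
        if best is None or r.fun < best.fun:
            best = r
    theta = best.x
    if fit_A:
        A, B, sigma = theta
    else:
        A, (B, sigma) = 0.0, theta
    return float(A), float(B), float(sigma), float(best.fun), bool(best.success)


def fit_logistic(trials: pd.DataFrame, n_starts: int = 10,
                 seed: int = 1234) -> dict[tuple[int, str], LogisticParams]:
    """MAP fit of the 6-parameter logistic choice model for one subject.

    ``trials`` must hold that subject's first-free-choice rows with columns
    horizon, info_condition, delta_R, delta_I, action.  Within each horizon,
    A is estimated from the unequal cell (jointly with that cell's B, sigma)
    and shared with the equal cell, whose likelihood does not involve A.
    Returns a mapping (horizon, info_condition) -> LogisticParams.  Fitting
    is deterministic given the data, ``n_starts`` and ``seed``.
    """
    out: dict[tuple[int, str], LogisticParams] = {}
    horizons = (1, 6)
    for h in horizons:
        sub_h = trials[trials["horizon"] == h]
        A_shared = 0.0
        for cond in ("unequal_13", "equal_22"):
            cell = sub_h[sub_h["info_condition"] == cond]
            if len(cell) == 0:
                raise MissingCellError(f"no trials in horizon {h}, {cond}")
            rng = np.random.default_rng(seed + 7 * h + (0 if cond == "unequal_13" else 1))
            y = (cell["action"].to_numpy() == 1).astype(float)
            dR = cell["delta_R"].to_numpy(float)
            dI = cell["delta_I"].to_numpy(float)
            fit_A = cond == "unequal_13"
            A, B, sigma, nlp, conv = _fit_cell(y, dR, dI, fit_A, rng, n_starts)
            if fit_A:
                A_shared = A
            out[(h, cond)] = LogisticParams(
                A=A_shared, B=B, sigma=sigma, converged=conv,
                log_posterior=-nlp, n_trials=len(cell))
    return out


def fit_rt_regression(trials: pd.DataFrame) -> RTRegressionParams:
    """Ordinary least squares of RT on (1, a*dR, a*dI) for one cell of trials.

    Columns required: rt, action, delta_R, delta_I.  Regressors that never
    vary (a*dI in the equal condition) are dropped; their coefficient is
    returned as NaN with ``rank_deficient=True``.
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 trials for the RT regression")
    a = trials["action"].to_numpy(float)
    x1 = a * trials["delta_R"].to_numpy(float)
    x2 = a * trials["delta_I"].to_numpy(float)
    rt = trials["rt"].to_numpy(float)
    cols = {"aDR": x1, "aDI": x2}
    use = {k: v for k, v in cols.items() if np.ptp(v) > 0}
    X = sm.add_constant(pd.DataFrame(use), has_constant="add")
    deficient = len(use) < 2 or np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]
    fit = sm.OLS(rt, X).fit()
    params = fit.params
    return RTRegressionParams(
        beta0=float(params.get("const", np.nan)),
        betaR=float(params.get("aDR", np.nan)),
        betaI=float(params.get("aDI", np.nan)),
        rank_deficient=bool(deficient),
        n_trials=len(trials),
    )
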