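r"""Condition-dependent drift-diffusion mathematics.

The decision model is a pure (simple) drift-diffusion process

    dX(t) = mu dt + c dW(t),        c = 1 fixed,

started at X(0) = alpha * beta between absorbing boundaries at +/- beta,
with a non-decision time T0 added to the first-passage time.  On each trial
the three process parameters are linear (drift, threshold) or logistic-linked
linear (bias) functions of the trial's reward difference Delta-R and
information difference Delta-I:

    mu    = c0_mu    + cR_mu    * dR + cI_mu    * dI
    beta  = c0_beta  + cR_beta  * dR + cI_beta  * dI
    alpha = 2 * L(c0_alpha + cR_alpha * dR + cI_alpha * dI) - 1

with L the standard logistic function, so alpha lies in [-1, 1].

Boundary convention: "left" is the boundary whose hitting probability equals
the closed form

    p_left = (exp(-2 a b m) - exp(-2 b m)) / (exp(2 b m) - exp(-2 b m))

(written here with b = beta, m = mu, a = alpha), which at alpha = 0 reduces
to the logistic 1/(1 + exp(2 beta mu)) and therefore *decreases* with drift.
Internally this is the lower-boundary first passage of the process above;
reward-seeking behavior consequently fits a negative cR_mu.  All mirror
symmetries hold under this orientation and only coefficient magnitudes and
ratios are interpreted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .config import (
    DENSITY_FLOOR,
    SIM_DT,
    SIM_MAX_TIME,
    TAYLOR_TOL,
    WFPT_SERIES_ERR,
)

__all__ = [
    "DDMCoefficients",
    "ResolvedDDM",
    "InvalidParameterError",
    "UndefinedExtremumError",
    "PARAM_NAMES",
    "link_L",
    "resolve_parameters",
    "choice_probability",
    "mean_rt",
    "rt_extremum_location",
    "wfpt_density",
    "simulate_response",
    "simulate_paths",
    "logistic_equivalent_sigma",
]

#: Canonical parameter order used everywhere a flat vector is needed.
PARAM_NAMES = (
    "c0_mu", "cR_mu", "cI_mu",
    "c0_beta", "cR_beta", "cI_beta",
    "c0_alpha", "cR_alpha", "cI_alpha",
    "T0",
)


class InvalidParameterError(ValueError):
    """Resolved DDM parameters are outside the model's domain (beta <= 0)."""


class UndefinedExtremumError(ValueError):
    """The requested response-time extremum does not exist (zero slope)."""


@dataclass(frozen=True)
class DDMCoefficients:
    """The 10 per-horizon parameters: 9 linear coefficients + non-decision time."""

    c0_mu: float = 0.0
    cR_mu: float = 0.0
    cI_mu: float = 0.0
    c0_beta: float = 1.0
    cR_beta: float = 0.0
    cI_beta: float = 0.0
    c0_alpha: float = 0.0
    cR_alpha: float = 0.0
    cI_alpha: float = 0.0
    T0: float = 0.3

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all DDM coefficients must be finite")
        if self.T0 < 0:
            raise ValueError(f"non-decision time T0 must be >= 0, got {self.T0}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "DDMCoefficients":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))


@dataclass(frozen=True)
class ResolvedDDM:
    """Per-trial process parameters (mu, beta, alpha, T0), diffusion c = 1."""

    mu: float
    beta: float
    alpha: float
    T0: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.mu, self.beta, self.alpha, self.T0))):
            raise InvalidParameterError("resolved parameters must be finite")
        if self.beta <= 0:
            raise InvalidParameterError(
                f"threshold beta must be > 0, got {self.beta} (model undefined)")
        if not (-1.0 <= self.alpha <= 1.0):
            raise InvalidParameterError(f"bias alpha must lie in [-1, 1], got {self.alpha}")
        if self.T0 < 0:
            raise InvalidParameterError(f"T0 must be >= 0, got {self.T0}")


def link_L(x):
    """Logistic link L(x) = 1 / (1 + exp(-x)); maps R onto (0, 1), saturates stably."""
    return expit(x)


def resolve_linear(coeffs: DDMCoefficients, delta_R, delta_I):
    """Vectorized linear maps -> (mu, beta, alpha) arrays; no validity check."""
    dR = np.asarray(delta_R, dtype=float)
    dI = np.asarray(delta_I, dtype=float)
    mu = coeffs.c0_mu + coeffs.cR_mu * dR + coeffs.cI_mu * dI
    beta = coeffs.c0_beta + coeffs.cR_beta * dR + coeffs.cI_beta * dI
    alpha = 2.0 * link_L(coeffs.c0_alpha + coeffs.cR_alpha * dR + coeffs.cI_alpha * dI) - 1.0
    return mu, beta, alpha


def resolve_parameters(coeffs: DDMCoefficients, delta_R: float, delta_I: int) -> ResolvedDDM:
    """Map per-horizon coefficients and a trial's (dR, dI) to process parameters.

    Raises
    ------
    InvalidParameterError
        If the resolved threshold is non-positive, for which the model's
        behavior is undefined.
    ValueError
        If delta_I is not one of {-1, 0, +1}.
    """
    if delta_I not in (-1, 0, 1):
        raise ValueError(f"delta_I must be in {{-1, 0, +1}}, got {delta_I}")
    if not math.isfinite(delta_R):
        raise ValueError("delta_R must be finite")
    mu, beta, alpha = resolve_linear(coeffs, delta_R, delta_I)
    return ResolvedDDM(mu=float(mu), beta=float(beta), alpha=float(alpha), T0=coeffs.T0)


# ----------------------------------------------------------------------
# closed forms
# ----------------------------------------------------------------------

def _choice_prob_arrays(mu, beta, alpha):
    """p(left) for arrays; beta > 0 assumed."""
    mu = np.asarray(mu, float)
    beta = np.asarray(beta, float)
    alpha = np.asarray(alpha, float)
    z = beta * mu
    out = np.empty(np.broadcast(mu, beta, alpha).shape, float)
    z, alpha = np.broadcast_arrays(z, np.broadcast_to(alpha, out.shape))

    small = np.abs(z) < TAYLOR_TOL
    # p = (1-alpha)/2 - z(1-alpha^2)/2 + O(z^2)
    out[small] = (1.0 - alpha[small]) / 2.0 - z[small] * (1.0 - alpha[small] ** 2) / 2.0

    big = ~small
    zb, ab = z[big], alpha[big]
    pos = zb > 0
    pb = np.empty_like(zb)
    # z > 0: scale by exp(-2z):  (e^{-2z(1+a)} - e^{-4z}) / (1 - e^{-4z})
    zp, ap = zb[pos], ab[pos]
    pb[pos] = (np.exp(-2.0 * zp * (1.0 + ap)) - np.exp(-4.0 * zp)) / (-np.expm1(-4.0 * zp))
    # z < 0: scale by exp(+2z):  (e^{2z(1-a)} - 1) / (e^{4z} - 1)
    zn, an = zb[~pos], ab[~pos]
    pb[~pos] = np.expm1(2.0 * zn * (1.0 - an)) / np.expm1(4.0 * zn)
    out[big] = pb
    return np.clip(out, 0.0, 1.0)


def choice_probability(resolved: ResolvedDDM) -> float:
    r"""Probability of choosing left, closed form.

    Evaluates

        p_left = 1/(1+exp(2 b m)) - (1 - exp(-2 a b m)) / (exp(2 b m) - exp(-2 b m))

    with (m, b, a) = (mu, beta, alpha), using a Taylor branch when
    |beta*mu| < TAYLOR_TOL (limit (1-alpha)/2 at mu -> 0).
    """
    return float(_choice_prob_arrays(resolved.mu, resolved.beta, resolved.alpha))


def _mean_decision_time_arrays(mu, beta, alpha):
    """Unconditional mean decision time (no T0) for arrays; beta > 0 assumed."""
    mu = np.asarray(mu, float)
    beta = np.asarray(beta, float)
    alpha = np.asarray(alpha, float)
    shape = np.broadcast(mu, beta, alpha).shape
    mu, beta, alpha = (np.broadcast_to(a, shape).astype(float) for a in (mu, beta, alpha))
    z = beta * mu
    out = np.empty(shape, float)

    small = np.abs(z) < TAYLOR_TOL
    bs, as_, zs = beta[small], alpha[small], z[small]
    out[small] = bs * bs * (1.0 - as_ * as_) * (1.0 - 2.0 * as_ * zs / 3.0)

    huge = (~small) & (np.abs(z) > 50.0)
    # drift dominates: DT -> beta*(1 - sign(z)*alpha)/|mu|
    bh, ah, zh, mh = beta[huge], alpha[huge], z[huge], mu[huge]
    out[huge] = bh * (1.0 - np.sign(zh) * ah) / np.abs(mh)

    mid = (~small) & (~huge)
    bm, am, zm = beta[mid], alpha[mid], z[mid]
    b2_over_z = bm * bm / zm
    t1 = b2_over_z * np.tanh(zm)
    # 2(1 - e^{-2 a z}) / (e^{2z} - e^{-2z}), scaled for stability
    num = 2.0 * (1.0 - np.exp(-2.0 * am * zm))
    den = np.exp(2.0 * zm) - np.exp(-2.0 * zm)
    t2 = b2_over_z * (num / den - am)
    out[mid] = t1 + t2
    return out


def mean_rt(resolved: ResolvedDDM) -> float:
    r"""Mean response time: T0 plus the unconditional mean first-passage time.

        RT = T0 + (b/m) tanh(b m)
                + (b/m) * 2(1 - exp(-2 a b m)) / (exp(2 b m) - exp(-2 b m))
                - a b / m

    At alpha = 0 this reduces to T0 + (beta/mu) tanh(beta*mu); as mu -> 0 it
    tends to T0 + beta^2 (1 - alpha^2).
    """
    return float(resolved.T0 + _mean_decision_time_arrays(
        resolved.mu, resolved.beta, resolved.alpha))


def rt_extremum_location(coeffs: DDMCoefficients, delta_I: int, which_special_case: str) -> float:
    """Location dR* of the RT extremum in the two logistic-reducible cases.

    ``threshold_fixed`` (threshold independent of dR, dI): RT has a global
    maximum at dR* = -(cI_mu * dI + c0_mu) / cR_mu.
    ``drift_fixed`` (drift independent of dR, dI): RT has a global minimum at
    dR* = -(cI_beta * dI + c0_beta) / cR_beta.
    """
    if delta_I not in (-1, 0, 1):
        raise ValueError(f"delta_I must be in {{-1, 0, +1}}, got {delta_I}")
    if which_special_case == "threshold_fixed":
        if coeffs.cR_mu == 0:
            raise UndefinedExtremumError("cR_mu = 0: RT does not vary with delta_R")
        return -(coeffs.cI_mu * delta_I + coeffs.c0_mu) / coeffs.cR_mu
    if which_special_case == "drift_fixed":
        if coeffs.cR_beta == 0:
            raise UndefinedExtremumError("cR_beta = 0: RT does not vary with delta_R")
        return -(coeffs.cI_beta * delta_I + coeffs.c0_beta) / coeffs.cR_beta
    raise ValueError(f"unknown special case {which_special_case!r}")


def logistic_equivalent_sigma(coeffs: DDMCoefficients, case: str = "threshold_fixed") -> float:
    """Decision-noise SD (points) of the equivalent logistic choice model.

    In the two exactly-reducible regimes the diffusion choice curve is
    logistic in dR with standard deviation

        sigma = 1 / (2 sqrt(2) cR_mu c0_beta)    (threshold_fixed)
        sigma = 1 / (2 sqrt(2) c0_mu cR_beta)    (drift_fixed)

    The magnitude is returned: sigma is a standard deviation, and the sign of
    the drift coefficients is an artifact of the boundary orientation (under
    this package's convention reward-seeking fits have cR_mu < 0).
    """
    if case == "threshold_fixed":
        denom = coeffs.cR_mu * coeffs.c0_beta
    elif case == "drift_fixed":
        denom = coeffs.c0_mu * coeffs.cR_beta
    else:
        raise ValueError(f"unknown case {case!r}")
    if denom == 0:
        raise UndefinedExtremumError("sigma undefined: zero coefficient in denominator")
    return abs(1.0 / (2.0 * math.sqrt(2.0) * denom))


# ----------------------------------------------------------------------
# first-passage-time densities (small-time / large-time series pair)
# ----------------------------------------------------------------------

def _wfpt_lower(td, v, a, w, err=WFPT_SERIES_ERR):
    """Lower-boundary Wiener FPT density, boundary separation ``a``, drift ``v``,
    relative start ``w`` in (0, 1), unit diffusion; vectorized over all inputs.

    Uses the small-time and large-time expansions, choosing per element the
    branch that needs fewer terms for truncation error < ``err``.
    """
    td = np.asarray(td, float)
    v = np.asarray(v, float)
    a = np.asarray(a, float)
    w = np.asarray(w, float)
    shape = np.broadcast(td, v, a, w).shape
    td, v, a, w = (np.broadcast_to(x, shape).astype(float).ravel() for x in (td, v, a, w))
    out = np.zeros(td.shape, float)

    ok = td > 0
    if not ok.any():
        return out.reshape(shape)
    t, vv, aa, ww = td[ok], v[ok], a[ok], w[ok]
    tt = t / aa**2  # normalized time

    # terms needed for each expansion (Navarro & Fuss 2009 bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * tt) * err
        ks = np.where(arg_s < 1.0,
                      2.0 + np.sqrt(np.maximum(-2.0 * tt * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
                      2.0)
        ks = np.maximum(ks, np.sqrt(tt) + 1.0)
        arg_l = np.pi * tt * err
        kl = np.where(arg_l < 1.0,
                      np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0)
                              / (np.pi**2 * tt)),
                      0.0)
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tt)))

    use_small = ks < kl
    f = np.zeros(tt.shape, float)

    if use_small.any():
        tts, wws = tt[use_small], ww[use_small]
        K = int(np.ceil(ks[use_small].max()))
        ksum = np.zeros(tts.shape, float)
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + 2):
            x = wws + 2.0 * k
            ksum += x * np.exp(-x * x / (2.0 * tts))
        f[use_small] = ksum / np.sqrt(2.0 * np.pi * tts**3)

    use_large = ~use_small
    if use_large.any():
        ttl, wwl = tt[use_large], ww[use_large]
        K = int(np.ceil(kl[use_large].max()))
        ksum = np.zeros(ttl.shape, float)
        for k in range(1, K + 1):
            ksum += k * np.exp(-(k**2) * np.pi**2 * ttl / 2.0) * np.sin(k * np.pi * wwl)
        f[use_large] = np.pi * ksum

    # scale back from normalized time and attach the drift factor
    with np.errstate(over="ignore", invalid="ignore"):
        dens = f * np.exp(-vv * aa * ww - vv * vv * t / 2.0) / aa**2
    # 0 * inf can only arise where the series factor underflowed, i.e. where
    # the true density is far below any floor we use: treat as 0
    dens = np.nan_to_num(dens, nan=0.0, posinf=0.0)
    out[ok] = np.maximum(dens, 0.0)
    return out.reshape(shape)


def wfpt_density(t, resolved: ResolvedDDM, boundary: str, err: float = WFPT_SERIES_ERR):
    """First-passage density (1/s) at the named boundary, shifted by T0.

    ``boundary`` is "left" or "right".  Zero for t <= T0.  The left density is
    the lower-boundary Wiener density with drift mu, separation 2*beta and
    relative start (1+alpha)/2; the right density follows by mirror symmetry
    f_right(t; mu, alpha) = f_left(t; -mu, -alpha).
    """
    t = np.asarray(t, float)
    td = t - resolved.T0
    a = 2.0 * resolved.beta
    if boundary == "left":
        v, w = resolved.mu, (1.0 + resolved.alpha) / 2.0
    elif boundary == "right":
        v, w = -resolved.mu, (1.0 - resolved.alpha) / 2.0
    else:
        raise ValueError(f"boundary must be 'left' or 'right', got {boundary!r}")
    # degenerate starts on a boundary: all mass leaves instantly through it
    if w <= 0.0 or w >= 1.0:
        return np.zeros(td.shape) if td.shape else 0.0
    res = _wfpt_lower(td, v, a, w, err=err)
    if res.shape == ():
        return float(res)
    return res


def nll_densities(rt, action, mu, beta, alpha, T0, err=WFPT_SERIES_ERR):
    """Vectorized per-trial first-passage densities at the observed boundary.

    ``action`` is +1 (left) or -1 (right).  Invalid thresholds (beta <= 0)
    yield density 0 (callers apply the floor).  Used by the fitting module.
    """
    rt = np.asarray(rt, float)
    action = np.asarray(action)
    mu = np.asarray(mu, float)
    beta = np.asarray(beta, float)
    alpha = np.asarray(alpha, float)
    left = action == 1
    v = np.where(left, mu, -mu)
    w = np.where(left, (1.0 + alpha) / 2.0, (1.0 - alpha) / 2.0)
    valid = (beta > 0) & (w > 0) & (w < 1)
    td = rt - T0
    dens = np.zeros(rt.shape, float)
    if valid.any():
        dens[valid] = _wfpt_lower(td[valid], v[valid], 2.0 * beta[valid], w[valid], err=err)
    return dens, valid


# ----------------------------------------------------------------------
# path simulation (validation oracle and data generator)
# ----------------------------------------------------------------------

def simulate_paths(mu, beta, alpha, T0, rng, dt: float = SIM_DT,
                   max_time: float = SIM_MAX_TIME, bridge: bool = True):
    """Euler-Maruyama simulation of many first passages at once.

    Parameters are arrays broadcast to a common length n.  Returns
    ``(action, rt, censored)``: action +1 for a left response (the boundary
    whose probability is given by the closed form), -1 for right; rt includes
    T0; paths still active at ``max_time`` are flagged censored (action 0).

    With ``bridge=True`` (default) each step additionally samples the
    Brownian-bridge probability of an intra-step boundary crossing, removing
    the O(sqrt(dt)) boundary bias of naive discrete crossing checks.
    """
    mu, beta, alpha = np.broadcast_arrays(
        np.asarray(mu, float), np.asarray(beta, float), np.asarray(alpha, float))
    n = mu.size
    mu = mu.ravel().astype(float)
    beta = beta.ravel().astype(float)
    alpha = alpha.ravel().astype(float)
    if np.any(beta <= 0):
        raise InvalidParameterError("all thresholds must be > 0 for simulation")

    # internal orientation: simulate dX = mu dt + dW from x0 = alpha*beta;
    # the LOWER boundary (-beta) is "left" (matches the closed forms).
    x = alpha * beta
    idx = np.arange(n)
    action = np.zeros(n, dtype=int)
    rt = np.full(n, np.nan)
    sqdt = math.sqrt(dt)
    max_steps = int(math.ceil(max_time / dt))
    near = 5.0 * sqdt  # bridge crossings beyond this gap have prob < exp(-50)

    # crossed paths are only swept out of the working arrays every
    # `compact_every` steps; between sweeps they keep evolving but their
    # first crossing is already recorded and later ones are ignored.
    compact_every = 64
    step = 0
    while idx.size and step < max_steps:
        crossed = np.zeros(idx.size, bool)
        dir_left = np.zeros(idx.size, bool)
        when = np.zeros(idx.size, np.int64)
        mudt = mu * dt
        for _ in range(compact_every):
            if step >= max_steps:
                break
            step += 1
            x_new = x + mudt + sqdt * rng.standard_normal(x.size)
            hit_up = x_new >= beta
            hit_dn = x_new <= -beta
            if bridge:
                cand = np.flatnonzero(
                    ~(hit_up | hit_dn) & ~crossed
                    & ((beta - np.maximum(x, x_new) < near)
                       | (np.minimum(x, x_new) + beta < near)))
                if cand.size:
                    xo, xn, bi = x[cand], x_new[cand], beta[cand]
                    p_up = np.exp(-2.0 * (bi - xo) * (bi - xn) / dt)
                    p_dn = np.exp(-2.0 * (xo + bi) * (xn + bi) / dt)
                    u = rng.random(cand.size)
                    hit_up[cand[u < p_up]] = True
                    hit_dn[cand[(u >= p_up) & (u < p_up + p_dn)]] = True
            new = (hit_up | hit_dn) & ~crossed
            if new.any():
                dir_left[new] = hit_dn[new]  # lower boundary = left
                when[new] = step
                crossed |= new
            x = x_new
        if crossed.any():
            gi = idx[crossed]
            action[gi] = np.where(dir_left[crossed], 1, -1)
            rt[gi] = when[crossed] * dt
            keep = ~crossed
            idx, x, mu, beta = idx[keep], x[keep], mu[keep], beta[keep]

    censored = np.zeros(n, bool)
    censored[idx] = True
    rt = rt + np.broadcast_to(np.asarray(T0, float), (n,))
    rt[censored] = np.nan
    return action, rt, censored


def simulate_response(resolved: ResolvedDDM, rng, dt: float = SIM_DT,
                      max_time: float = SIM_MAX_TIME, bridge: bool = True):
    """Single-trial forward simulation; returns ``(action, rt, censored)``."""
    a, t, c = simulate_paths(
        resolved.mu, resolved.beta, resolved.alpha, resolved.T0, rng,
        dt=dt, max_time=max_time, bridge=bridge)
    return int(a[0]), float(t[0]), bool(c[0])
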