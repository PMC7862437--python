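"""Numerical constants and the pipeline configuration object.

All tolerances, floors and simulator settings used by the package live in
one place so that a run can log them up front and a reader can audit them.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("ddmexplore")

#: Per-evaluation truncation error of the first-passage-time series.
WFPT_SERIES_ERR = 1e-6

#: |beta*mu| below which Taylor branches replace the exact expressions
#: for choice probability and mean response time (avoids 0/0).
TAYLOR_TOL = 1e-5

#: Densities are clamped at this floor inside likelihoods so that a single
#: impossible datum (e.g. rt <= T0) cannot produce an infinite objective.
DENSITY_FLOOR = 1e-29

#: Euler-Maruyama step (seconds) and path cap (seconds) for the simulator.
SIM_DT = 1e-4
SIM_MAX_TIME = 20.0

#: Boundary convention.  "Left" is the boundary whose hitting probability is
#: the printed closed form p_left = 1/(1+exp(2*beta*mu)) - ... , i.e. the
#: probability of choosing left DEcreases with drift mu.  Internally the left
#: first-passage density is the lower-boundary Wiener density with drift +mu,
#: separation 2*beta and relative start w = (1+alpha)/2.  Under this
#: orientation reward-seeking behavior corresponds to a NEGATIVE
#: reward-on-drift coefficient; only magnitudes and ratios of coefficients
#: carry scientific meaning.
BOUNDARY_CONVENTION = "left=closed-form boundary (p_left decreasing in mu)"


def log_numerics() -> None:
    """Log the numeric configuration once at run start."""
    logger.info(
        "numerics: wfpt_err=%g taylor_tol=%g density_floor=%g dt=%g cap=%gs; %s",
        WFPT_SERIES_ERR, TAYLOR_TOL, DENSITY_FLOOR, SIM_DT, SIM_MAX_TIME,
        BOUNDARY_CONVENTION,
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    seed: int = 0
    mode: str = "simulate"              # "simulate" or "file"
    input_path: str | None = None       # trial CSV when mode == "file"
    out_dir: str = "out"

    # simulate mode
    n_games_per_cell: int = 40
    n_subjects: int = 1
    coefficients: dict[str, dict[str, float]] | None = None  # per horizon "1"/"6"
    reward_rounding: str = "resample"   # or "round_clip"

    # exclusions
    rt_min: float = 0.1
    rt_max: float = 3.0
    min_trials_per_horizon: int = 131

    # optimizer
    n_starts: int = 10
    optimizer_seed: int = 1234
    maxiter: int = 500

    # simulator
    dt: float = SIM_DT
    path_cap: float = SIM_MAX_TIME

    # analysis
    correction_factor: int = 10
    summary_stat: str = "median"
    alpha_level: float = 0.05

    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "file"):
            raise ValueError(f"mode must be 'simulate' or 'file', got {self.mode!r}")
        if self.reward_rounding not in ("resample", "round_clip"):
            raise ValueError(f"unknown reward_rounding {self.reward_rounding!r}")
        if self.summary_stat not in ("median", "mean"):
            raise ValueError(f"summary_stat must be median or mean")
        for name, val, lo in [
            ("n_games_per_cell", self.n_games_per_cell, 1),
            ("n_subjects", self.n_subjects, 1),
            ("n_starts", self.n_starts, 1),
            ("correction_factor", self.correction_factor, 1),
            ("min_trials_per_horizon", self.min_trials_per_horizon, 0),
        ]:
            if val < lo:
                raise ValueError(f"{name} must be >= {lo}, got {val}")
        if not (0 <= self.rt_min < self.rt_max):
            raise ValueError("need 0 <= rt_min < rt_max")
        if not (0 < self.dt <= 0.1) or self.path_cap <= 0:
            raise ValueError("dt must be in (0, 0.1], path_cap > 0")
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must lie in (0, 1)")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
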