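import numpy as np
import pandas as pd
import pytest

from ddmexplore import horizon_task


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    """One synthetic subject, 12 games per cell, coarse simulator step."""
    return horizon_task.simulate_dataset(
        horizon_task.default_coefficients(), n_games_per_cell=12,
        rng_seed=7, subject_id="s01", dt=1e-3)


def make_trials(rows, subject_id="s01"):
    """Build a schema-complete trial table from (horizon, cond, dR, dI, action, rt)."""
    recs = []
    for i, (h, cond, dR, dI, a, rt) in enumerate(rows):
        recs.append(dict(subject_id=subject_id, game_id=i, horizon=h,
                         info_condition=cond, trial_index=5, is_free=True,
                         delta_R=dR, delta_I=dI, action=a, rt=rt))
    return pd.DataFrame(recs, columns=horizon_task.TRIAL_COLUMNS)


@pytest.fixture
def trials_factory():
    return make_trials
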