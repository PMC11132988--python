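import numpy as np
import pandas as pd
import pytest

from dynaphen.hier.fit import HierarchicalFit
from dynaphen.hier.logjoint import SessionIndex


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_session_index(part_idx, week):
    part_idx = np.asarray(part_idx, int)
    ids = [f"p{i:03d}" for i in range(part_idx.max() + 1)]
    return SessionIndex(
        participant_ids=ids, part_idx=part_idx, week=np.asarray(week, int)
    )


def make_fit(task, y_draws, obs, param_names, variant="independent",
             extra_draws=None, diagnostics=None):
    """Assemble a HierarchicalFit directly from draw arrays.

    ``y_draws`` has shape (chains, draws, n_obs, P).
    """
    draws = dict(y=np.asarray(y_draws, float))
    if extra_draws:
        draws.update({k: np.asarray(v, float) for k, v in extra_draws.items()})
    if diagnostics is None:
        diagnostics = dict(
            max_rhat=1.0, min_ess=1000.0, n_divergent=0,
            n_chains=y_draws.shape[0],
        )
    return HierarchicalFit(
        variant=variant, task=task, param_names=tuple(param_names), obs=obs,
        draws=draws, diagnostics=diagnostics, seed=0,
    )


@pytest.fixture
def gng_table():
    """Two participants, one week of well-formed gng rows."""
    from dynaphen.tasks import simulate_task

    frames = [
        simulate_task("gng", (0.2, 0.3, 0.2, 3.0, 1.2, 0.1), seed=s,
                      participant_id=f"p{s}", week=1)
        for s in (1, 2)
    ]
    return pd.concat(frames, ignore_index=True)
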