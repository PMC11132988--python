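"""Trial-level likelihood models and matched simulators for the battery.

Each task module exposes the same surface: ``PARAM_NAMES``,
``TRANSFORM_NAMES``, ``PRIOR_LOC`` (unconstrained prior centers),
``Design``/``default_design``, ``prepare``, ``loglik``, ``loglik_grad``,
``trial_probs`` and ``simulate``. ``TASK_MODELS`` maps task codes to
modules; :func:`simulate_task` is the uniform entry point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..transforms import get_transform
from . import cd, gng, itc, lt, nc, rdm, tab

TASK_MODELS = {m.NAME: m for m in (gng, cd, rdm, lt, itc, tab, nc)}

__all__ = [
    "TASK_MODELS",
    "get_model",
    "simulate_task",
    "constrain_theta",
    "unconstrain_theta",
    "n_params",
]


def get_model(task: str):
    try:
        return TASK_MODELS[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}") from None


def n_params(task: str) -> int:
    return len(get_model(task).PARAM_NAMES)


def constrain_theta(task: str, u: np.ndarray) -> np.ndarray:
    """Map an unconstrained parameter vector to the task's natural space."""
    m = get_model(task)
    u = np.asarray(u, float)
    return np.array(
        [get_transform(t).constrain(u[..., j]) for j, t in enumerate(m.TRANSFORM_NAMES)]
    ).T if u.ndim > 1 else np.array(
        [get_transform(t).constrain(u[j]) for j, t in enumerate(m.TRANSFORM_NAMES)]
    )


def unconstrain_theta(task: str, theta: np.ndarray) -> np.ndarray:
    m = get_model(task)
    theta = np.asarray(theta, float)
    return np.array(
        [get_transform(t).unconstrain(theta[j]) for j, t in enumerate(m.TRANSFORM_NAMES)]
    )


def simulate_task(task: str, theta, design=None, seed: int | np.random.Generator = 0,
                  participant_id: str = "sim", week: int = 1) -> pd.DataFrame:
    """Simulate one session of ``task`` at constrained parameters ``theta``."""
    m = get_model(task)
    design = design or m.default_design()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return m.simulate(theta, design, rng, participant_id=participant_id, week=week)
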