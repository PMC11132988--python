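"""Numerosity comparison: Weber-scaled Gaussian estimation noise.

The count of each cluster is encoded as Normal(a, a^2 w^2), where w is the
Weber fraction. Choosing the cluster with the larger noisy estimate gives

    p(choose cluster 1) = Phi((a1 - a2) / (w * sqrt(a1^2 + a2^2))).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr

NAME = "nc"
PARAM_NAMES = ("w",)
TRANSFORM_NAMES = ("log",)
PRIOR_LOC = (-1.39,)


@dataclasses.dataclass
class Design:
    n_trials: int = 160
    a_min: int = 5
    a_max: int = 50
    ratios: tuple = (1.08, 1.15, 1.25, 1.4, 1.6, 1.9)


def default_design() -> Design:
    return Design()


def prepare(df: pd.DataFrame, design: Design | None = None) -> dict:
    df = df.sort_values(["block", "trial"])
    ok = df["response"].notna()
    d = df.loc[ok]
    a1 = d["a1"].to_numpy(float)
    a2 = d["a2"].to_numpy(float)
    if (a1 <= 0).any() or (a2 <= 0).any():
        raise ValueError("non-positive counts")
    if (a1 == a2).any():
        raise ValueError("equal cluster counts")
    return dict(a1=a1, a2=a2, resp=d["response"].to_numpy(int),
                n_dropped=int((~ok).sum()))


def _z(w, a1, a2):
    return (a1 - a2) / (w * np.sqrt(a1**2 + a2**2))


def trial_probs(theta, data) -> np.ndarray:
    return ndtr(_z(float(theta[0]), data["a1"], data["a2"]))


def loglik(theta, data) -> float:
    return loglik_grad(theta, data)[0]


def loglik_grad(theta, data):
    w = float(theta[0])
    z = _z(w, data["a1"], data["a2"])
    sgn = np.where(data["resp"] == 1, 1.0, -1.0)
    zz = sgn * z
    ll = float(np.sum(log_ndtr(zz)))
    mills = np.exp(-0.5 * zz**2 - 0.5 * np.log(2 * np.pi) - log_ndtr(zz))
    # dz/dw = -z / w
    grad = np.array([float(np.sum(mills * sgn * (-z / w)))])
    return ll, grad


def simulate(theta, design: Design, rng: np.random.Generator,
             participant_id: str = "sim", week: int = 1) -> pd.DataFrame:
    w = float(theta[0])
    rows = []
    for tr in range(1, design.n_trials + 1):
        a = int(rng.integers(design.a_min, design.a_max + 1))
        ratio = float(rng.choice(design.ratios))
        other = max(int(round(a * ratio)), a + 1)
        if rng.random() < 0.5:
            a1, a2 = a, other
        else:
            a1, a2 = other, a
        p1 = ndtr(_z(w, a1, a2))
        resp = int(rng.random() < p1)
        correct = int((resp == 1) == (a1 > a2))
        rt = float(np.exp(rng.normal(np.log(900.0), 0.3)))
        rows.append((participant_id, week, 1, tr, resp, rt, correct, a1, a2))
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "a1", "a2",
        ],
    )
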