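"""Intertemporal choice: hyperbolic discounting with softmax.

The delayed amount A at delay D (days) is valued V(A, D) = A / (1 + k D);
the immediate amount has D = 0 and is taken at face value. The probability
of choosing the delayed option is logistic(beta * (V(A_D, D) - A_0)).
Larger k means steeper discounting (greater impulsivity).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.special import expit

NAME = "itc"
PARAM_NAMES = ("k", "beta")
TRANSFORM_NAMES = ("log", "log")
PRIOR_LOC = (-3.9, -1.2)


@dataclasses.dataclass
class Design:
    delayed_amounts: tuple = (12.0, 30.0, 55.0)  # small / medium / large
    immediate_fractions: tuple = (0.45, 0.7, 0.9)
    delays_days: tuple = (7.0, 30.0, 90.0)

    def menu(self):
        """The full crossed menu (27 trials by default)."""
        return [
            (round(a * f, 2), a, d)
            for a, f, d in itertools.product(
                self.delayed_amounts, self.immediate_fractions, self.delays_days
            )
        ]


def default_design() -> Design:
    return Design()


def prepare(df: pd.DataFrame, design: Design | None = None) -> dict:
    df = df.sort_values(["block", "trial"])
    ok = df["response"].notna()
    d = df.loc[ok]
    a0 = d["amount_now"].to_numpy(float)
    aD = d["amount_later"].to_numpy(float)
    D = d["delay_days"].to_numpy(float)
    if (a0 < 0).any() or (aD < 0).any() or (D < 0).any():
        raise ValueError("negative amounts or delays")
    return dict(a0=a0, aD=aD, D=D, resp=d["response"].to_numpy(int),
                n_dropped=int((~ok).sum()))


def trial_probs(theta, data) -> np.ndarray:
    k, beta = (float(v) for v in theta)
    v = data["aD"] / (1.0 + k * data["D"])
    return expit(beta * (v - data["a0"]))


def loglik(theta, data) -> float:
    return loglik_grad(theta, data)[0]


def loglik_grad(theta, data):
    k, beta = (float(v) for v in theta)
    denom = 1.0 + k * data["D"]
    v = data["aD"] / denom
    dv_dk = -data["aD"] * data["D"] / denom**2
    margin = v - data["a0"]
    p1 = expit(beta * margin)
    r = data["resp"]
    p_obs = np.clip(np.where(r == 1, p1, 1.0 - p1), 1e-300, None)
    ll = float(np.sum(np.log(p_obs)))
    sgn = np.where(r == 1, 1.0, -1.0)
    w = sgn * p1 * (1.0 - p1) / p_obs
    grad = np.array(
        [float(np.sum(w * beta * dv_dk)), float(np.sum(w * margin))]
    )
    return ll, grad


def simulate(theta, design: Design, rng: np.random.Generator,
             participant_id: str = "sim", week: int = 1) -> pd.DataFrame:
    k, beta = (float(v) for v in theta)
    menu = design.menu()
    order = rng.permutation(len(menu))
    rows = []
    for tr, j in enumerate(order, start=1):
        a0, aD, D = menu[j]
        v = aD / (1.0 + k * D)
        p = expit(beta * (v - a0))
        resp = int(rng.random() < p)
        rt = float(np.exp(rng.normal(np.log(1500.0), 0.3)))
        rows.append((participant_id, week, 1, tr, resp, rt, np.nan, a0, aD, D))
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "amount_now", "amount_later", "delay_days",
        ],
    )
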