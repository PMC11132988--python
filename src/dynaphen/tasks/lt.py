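"""Lottery ticket: risk-sensitive utility with softmax choice.

Each ticket is a two-outcome gamble sharing its odds with the alternative.
Perceived utility is U(ticket) = sum_j p_j * x_j^rho, and the probability
of choosing the risky ticket is logistic(beta * (U_risky - U_safe)).
rho > 1 is risk seeking, rho < 1 risk averse. Certain (p = 1) trials are
removed before modelling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

NAME = "lt"
PARAM_NAMES = ("rho_risk", "beta")
TRANSFORM_NAMES = ("log", "log")
PRIOR_LOC = (-0.105, -0.69)

#: base ticket values (win probability p applies to the *_hi outcome)
BASE_SAFE = (2.00, 1.60)
BASE_RISKY = (3.85, 0.10)


@dataclasses.dataclass
class Design:
    n_blocks: int = 3
    trials_per_block: int = 10
    # expected-value scale of each block (low / medium / high menus)
    block_scales: tuple = (1.0, 25.0, 100.0)
    p_levels: tuple = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


def default_design() -> Design:
    return Design()


def prepare(df: pd.DataFrame, design: Design | None = None) -> dict:
    df = df.sort_values(["block", "trial"])
    ok = df["response"].notna() & (df["p"] < 1.0)
    d = df.loc[ok]
    x = d[["risky_hi", "risky_lo", "safe_hi", "safe_lo"]].to_numpy(float)
    if (x < 0).any():
        raise ValueError("negative payoffs")
    return dict(
        p=d["p"].to_numpy(float),
        amounts=x,
        resp=d["response"].to_numpy(int),  # 1 = risky
        n_dropped=int((~ok).sum()),
    )


def _utilities(rho, p, amounts):
    xp = np.where(amounts > 0, amounts, 1.0) ** rho
    xp = np.where(amounts > 0, xp, 0.0)
    u_r = p * xp[:, 0] + (1.0 - p) * xp[:, 1]
    u_s = p * xp[:, 2] + (1.0 - p) * xp[:, 3]
    # d utility / d rho uses x^rho * ln x (0 for zero payoffs)
    lx = np.where(amounts > 0, np.log(np.where(amounts > 0, amounts, 1.0)), 0.0)
    du_r = p * xp[:, 0] * lx[:, 0] + (1.0 - p) * xp[:, 1] * lx[:, 1]
    du_s = p * xp[:, 2] * lx[:, 2] + (1.0 - p) * xp[:, 3] * lx[:, 3]
    return u_r - u_s, du_r - du_s


def trial_probs(theta, data) -> np.ndarray:
    rho, beta = (float(v) for v in theta)
    du, _ = _utilities(rho, data["p"], data["amounts"])
    return expit(beta * du)


def loglik(theta, data) -> float:
    return loglik_grad(theta, data)[0]


def loglik_grad(theta, data):
    rho, beta = (float(v) for v in theta)
    du, ddu_drho = _utilities(rho, data["p"], data["amounts"])
    x = beta * du
    p1 = expit(x)
    r = data["resp"]
    p_obs = np.clip(np.where(r == 1, p1, 1.0 - p1), 1e-300, None)
    ll = float(np.sum(np.log(p_obs)))
    sgn = np.where(r == 1, 1.0, -1.0)
    w = sgn * p1 * (1.0 - p1) / p_obs  # d ll / d x
    grad = np.array([float(np.sum(w * beta * ddu_drho)), float(np.sum(w * du))])
    return ll, grad


def simulate(theta, design: Design, rng: np.random.Generator,
             participant_id: str = "sim", week: int = 1) -> pd.DataFrame:
    rho, beta = (float(v) for v in theta)
    rows = []
    for blk, scale in enumerate(design.block_scales[: design.n_blocks], start=1):
        ps = list(design.p_levels)[: design.trials_per_block]
        rng.shuffle(ps)
        for tr, p in enumerate(ps, start=1):
            r_hi, r_lo = (v * scale for v in BASE_RISKY)
            s_hi, s_lo = (v * scale for v in BASE_SAFE)
            if p < 1.0:
                du = (p * r_hi**rho + (1 - p) * r_lo**rho) - (
                    p * s_hi**rho + (1 - p) * s_lo**rho
                )
                p_risky = expit(beta * du)
            else:
                # certain trials: pick the larger sure amount
                p_risky = float(r_hi > s_hi)
            resp = int(rng.random() < p_risky)
            rt = float(np.exp(rng.normal(np.log(1200.0), 0.3)))
            rows.append(
                (participant_id, week, blk, tr, resp, rt, np.nan, p, r_hi, r_lo, s_hi, s_lo)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "p", "risky_hi", "risky_lo", "safe_hi", "safe_lo",
        ],
    )
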