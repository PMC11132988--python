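"""Two-armed bandit: Kalman-filter learner with hybrid-exploration probit.

Each arm's reward mean is tracked by a Kalman filter (prior mean m0,
variance s0^2; observation-noise variance tau_R^2 for risky arms and a
numerically tiny tau_S^2 for safe arms). With V = m1 - m2,
RU = s1 - s2 and TU = sqrt(s1^2 + s2^2), the choice rule is

    p(choose arm 1) = Phi(w_V * V + w_RU * RU + w_sTU * sign(V) / TU)

(sign(0) = 0). w_V weights exploitation, w_RU directed exploration and
w_sTU signed-total-uncertainty (random) exploration. Because the Kalman
trajectory depends only on the observed choices and rewards, the features
are precomputed once per session and the likelihood is an ordinary probit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr

NAME = "tab"
PARAM_NAMES = ("w_V", "w_RU", "w_sTU")
TRANSFORM_NAMES = ("identity", "identity", "identity")
PRIOR_LOC = (0.15, 0.15, 2.0)


@dataclasses.dataclass
class Design:
    n_blocks: int = 30
    trials_per_block: int = 10
    conditions: tuple = ("SS", "RR", "RS", "SR")  # cycled over blocks
    mean_sd: float = 10.0  # arm means drawn N(0, mean_sd) per block
    risky_sd: float = 4.0  # reward noise of risky arms (tau_R)
    m0: float = 0.0
    s0sq: float = 100.0
    tau_s_sq: float = 1e-6  # numerical stand-in for a deterministic arm


def default_design() -> Design:
    return Design()


def _kalman_features(block, labels1, labels2, choice, reward, design: Design):
    """Pre-choice V, RU, sign(V)/TU per trial; state resets at block bounds."""
    n = len(block)
    V = np.empty(n)
    RU = np.empty(n)
    sTU = np.empty(n)
    cur = None
    m = s2 = tau2 = None
    for i in range(n):
        if block[i] != cur:
            cur = block[i]
            m = [design.m0, design.m0]
            s2 = [design.s0sq, design.s0sq]
            tau2 = [
                design.risky_sd**2 if labels1[i] == "R" else design.tau_s_sq,
                design.risky_sd**2 if labels2[i] == "R" else design.tau_s_sq,
            ]
        v = m[0] - m[1]
        s = [np.sqrt(s2[0]), np.sqrt(s2[1])]
        tu = np.sqrt(s2[0] + s2[1])
        V[i] = v
        RU[i] = s[0] - s[1]
        sTU[i] = np.sign(v) / tu
        c = int(choice[i])  # 1 -> arm 1 (index 0), 0 -> arm 2 (index 1)
        arm = 0 if c == 1 else 1
        if np.isfinite(reward[i]):
            k = s2[arm] / (s2[arm] + tau2[arm])
            m[arm] = m[arm] + k * (reward[i] - m[arm])
            s2[arm] = (1.0 - k) * s2[arm]
    return V, RU, sTU


def prepare(df: pd.DataFrame, design: Design | None = None) -> dict:
    design = design or default_design()
    df = df.sort_values(["block", "trial"])
    ok = df["response"].notna()
    d = df.loc[ok]
    if len(d) == 0:
        raise ValueError("empty block/session")
    lab1 = d["arm1_label"].to_numpy(str)
    lab2 = d["arm2_label"].to_numpy(str)
    if not (np.isin(lab1, ["R", "S"]).all() and np.isin(lab2, ["R", "S"]).all()):
        raise ValueError("unlabelled arms")
    V, RU, sTU = _kalman_features(
        d["block"].to_numpy(int), lab1, lab2,
        d["response"].to_numpy(int), d["reward"].to_numpy(float), design,
    )
    return dict(V=V, RU=RU, sTU=sTU, resp=d["response"].to_numpy(int),
                n_dropped=int((~ok).sum()))


def _margin(theta, data):
    w_v, w_ru, w_stu = (float(v) for v in theta)
    return w_v * data["V"] + w_ru * data["RU"] + w_stu * data["sTU"]


def trial_probs(theta, data) -> np.ndarray:
    return ndtr(_margin(theta, data))


def loglik(theta, data) -> float:
    x = _margin(theta, data)
    sgn = np.where(data["resp"] == 1, 1.0, -1.0)
    return float(np.sum(log_ndtr(sgn * x)))


def loglik_grad(theta, data):
    x = _margin(theta, data)
    sgn = np.where(data["resp"] == 1, 1.0, -1.0)
    z = sgn * x
    ll = float(np.sum(log_ndtr(z)))
    # stable inverse Mills ratio
    w = sgn * np.exp(-0.5 * z**2 - 0.5 * np.log(2 * np.pi) - log_ndtr(z))
    grad = np.array(
        [
            float(np.sum(w * data["V"])),
            float(np.sum(w * data["RU"])),
            float(np.sum(w * data["sTU"])),
        ]
    )
    return ll, grad


def simulate(theta, design: Design, rng: np.random.Generator,
             participant_id: str = "sim", week: int = 1) -> pd.DataFrame:
    w_v, w_ru, w_stu = (float(v) for v in theta)
    rows = []
    for blk in range(1, design.n_blocks + 1):
        cond = design.conditions[(blk - 1) % len(design.conditions)]
        labels = (cond[0], cond[1])
        means = rng.normal(0.0, design.mean_sd, size=2)
        tau2 = [
            design.risky_sd**2 if labels[0] == "R" else design.tau_s_sq,
            design.risky_sd**2 if labels[1] == "R" else design.tau_s_sq,
        ]
        m = [design.m0, design.m0]
        s2 = [design.s0sq, design.s0sq]
        for tr in range(1, design.trials_per_block + 1):
            v = m[0] - m[1]
            ru = np.sqrt(s2[0]) - np.sqrt(s2[1])
            stu = np.sign(v) / np.sqrt(s2[0] + s2[1])
            p1 = ndtr(w_v * v + w_ru * ru + w_stu * stu)
            resp = int(rng.random() < p1)
            arm = 0 if resp == 1 else 1
            if labels[arm] == "R":
                reward = float(rng.normal(means[arm], design.risky_sd))
            else:
                reward = float(means[arm])
            k = s2[arm] / (s2[arm] + tau2[arm])
            m[arm] = m[arm] + k * (reward - m[arm])
            s2[arm] = (1.0 - k) * s2[arm]
            rt = float(np.exp(rng.normal(np.log(700.0), 0.3)))
            rows.append(
                (participant_id, week, blk, tr, resp, rt, reward, labels[0], labels[1], reward)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "arm1_label", "arm2_label", "reward",
        ],
    )
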