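"""Pavlovian Go/No-go reinforcement-learning model.

Four stimuli per block prescribe Go/No-go responses in win or
avoid-punishment contexts. Instrumental values Q(a, s) and a Pavlovian
stimulus value V(s) are learned by Rescorla-Wagner updates of the
*effective* outcome: rewards count +rho_rp, punishments -rho_rp, and
neutral outcomes are context-coded (-rho_neut in win conditions,
+rho_neut in avoid conditions). Action weights are

    W(go)   = Q(go, s) + b + pi * V(s)
    W(nogo) = Q(nogo, s)

and p(Go) = (1 - xi) * logistic(W(go) - W(nogo)) + xi / 2, with lapse xi.
V(s) is updated on every trial of stimulus s regardless of the action;
only the taken action's Q is updated.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

NAME = "gng"
PARAM_NAMES = ("b", "pi", "eps", "rho_rp", "rho_neut", "xi")
TRANSFORM_NAMES = ("identity", "identity", "logit", "log", "log", "logit")
#: unconstrained prior/initialization centers (b, pi, logit eps, log rho_rp,
#: log rho_neut, logit xi)
PRIOR_LOC = (0.2, 0.3, -1.4, 1.1, 0.18, -2.2)

CONDITIONS = ("go_win", "go_avoid", "nogo_win", "nogo_avoid")


@dataclasses.dataclass
class Design:
    n_blocks: int = 3
    trials_per_block: int = 80  # 4 stimuli x 20 presentations
    p_outcome: float = 0.8  # chance the prescribed feedback contingency fires


def default_design() -> Design:
    return Design()


def prepare(df: pd.DataFrame, design: Design | None = None) -> dict:
    """Pack one session's rows (ordered by block, trial) into arrays.

    Trials with a missing response are retained in files but excluded here
    (their count is reported under ``n_dropped``).
    """
    df = df.sort_values(["block", "trial"])
    ok = df["response"].notna() & df["outcome"].notna()
    d = df.loc[ok]
    return dict(
        block=d["block"].to_numpy(int),
        stim=d["stimulus"].to_numpy(int),
        win=(d["condition"].isin(["go_win", "nogo_win"])).to_numpy(),
        resp=d["response"].to_numpy(int),
        outcome=d["outcome"].to_numpy(int),  # +1 reward, 0 neutral, -1 punishment
        n_dropped=int((~ok).sum()),
    )


def _effective_outcome(outcome: int, win: bool, rho_rp: float, rho_neut: float):
    """Effective reinforcement and its (d/d rho_rp, d/d rho_neut)."""
    if outcome == 1:
        return rho_rp, 1.0, 0.0
    if outcome == -1:
        return -rho_rp, -1.0, 0.0
    # neutral: punishment-flavoured in win conditions, reward-flavoured in avoid
    if win:
        return -rho_neut, 0.0, -1.0
    return rho_neut, 0.0, 1.0


def loglik(theta, data) -> float:
    return _forward(theta, data, with_grad=False)[0]


def trial_probs(theta, data) -> np.ndarray:
    return _forward(theta, data, with_grad=False)[2]


def loglik_grad(theta, data):
    ll, grad, _ = _forward(theta, data, with_grad=True)
    return ll, grad


def _forward(theta, data, with_grad: bool = True):
    """Summed log-likelihood, gradient in constrained space, per-trial p(Go)."""
    b, pi, eps, rho_rp, rho_neut, xi = (float(v) for v in theta)
    block = data["block"]
    stim = data["stim"]
    win = data["win"]
    resp = data["resp"]
    outcome = data["outcome"]
    n = len(block)

    ll = 0.0
    grad = np.zeros(6)
    pgo = np.empty(n)

    Q = {}  # (stim, action) -> value
    V = {}
    dQ = {}  # (stim, action) -> [d/deps, d/drho_rp, d/drho_neut]
    dV = {}
    cur_block = None
    for i in range(n):
        if block[i] != cur_block:
            cur_block = block[i]
            Q.clear()
            V.clear()
            dQ.clear()
            dV.clear()
        s = stim[i]
        q_go = Q.get((s, 1), 0.0)
        q_ng = Q.get((s, 0), 0.0)
        v_s = V.get(s, 0.0)
        L = q_go + b + pi * v_s - q_ng
        if L >= 0:
            sig = 1.0 / (1.0 + math.exp(-L))
        else:
            e = math.exp(L)
            sig = e / (1.0 + e)
        p = (1.0 - xi) * sig + xi / 2.0
        a = resp[i]
        p_obs = p if a == 1 else 1.0 - p
        p_obs = max(p_obs, 1e-300)
        ll += math.log(p_obs)
        pgo[i] = p

        if with_grad:
            sgn = 1.0 if a == 1 else -1.0
            dp_dL = (1.0 - xi) * sig * (1.0 - sig)
            dq_go = dQ.get((s, 1), (0.0, 0.0, 0.0))
            dq_ng = dQ.get((s, 0), (0.0, 0.0, 0.0))
            dv_s = dV.get(s, (0.0, 0.0, 0.0))
            c = sgn * dp_dL / p_obs
            grad[0] += c  # b
            grad[1] += c * v_s  # pi
            for j in range(3):  # eps, rho_rp, rho_neut via learned values
                grad[2 + j] += c * (dq_go[j] + pi * dv_s[j] - dq_ng[j])
            grad[5] += sgn * (0.5 - sig) / p_obs  # xi

        # learning update (taken action's Q; stimulus value V always)
        r, dr_rp, dr_nt = _effective_outcome(outcome[i], win[i], rho_rp, rho_neut)
        q_a = Q.get((s, a), 0.0)
        dq_a = dQ.get((s, a), (0.0, 0.0, 0.0))
        Q[(s, a)] = q_a + eps * (r - q_a)
        dQ[(s, a)] = (
            (1.0 - eps) * dq_a[0] + (r - q_a),
            (1.0 - eps) * dq_a[1] + eps * dr_rp,
            (1.0 - eps) * dq_a[2] + eps * dr_nt,
        )
        dv = dV.get(s, (0.0, 0.0, 0.0))
        V[s] = v_s + eps * (r - v_s)
        dV[s] = (
            (1.0 - eps) * dv[0] + (r - v_s),
            (1.0 - eps) * dv[1] + eps * dr_rp,
            (1.0 - eps) * dv[2] + eps * dr_nt,
        )
    return ll, grad, pgo


def simulate(theta, design: Design, rng: np.random.Generator,
             participant_id: str = "sim", week: int = 1) -> pd.DataFrame:
    """Simulate one session from the same generative process the likelihood scores."""
    b, pi, eps, rho_rp, rho_neut, xi = (float(v) for v in theta)
    rows = []
    n_per_stim = design.trials_per_block // 4
    for blk in range(1, design.n_blocks + 1):
        stims = np.repeat(np.arange(4), n_per_stim)
        rng.shuffle(stims)
        Q = np.zeros((4, 2))
        V = np.zeros(4)
        for tr, s in enumerate(stims, start=1):
            cond = CONDITIONS[s]
            win = cond.endswith("win")
            go_correct = cond.startswith("go")
            L = Q[s, 1] + b + pi * V[s] - Q[s, 0]
            if L >= 0:
                sig = 1.0 / (1.0 + math.exp(-L))
            else:
                e = math.exp(L)
                sig = e / (1.0 + e)
            p = (1.0 - xi) * sig + xi / 2.0
            a = int(rng.random() < p)
            correct = (a == 1) == go_correct
            fires = rng.random() < design.p_outcome
            if win:
                outcome = 1 if (correct == fires) else 0
            else:
                outcome = 0 if (correct == fires) else -1
            r = (
                rho_rp
                if outcome == 1
                else (-rho_rp if outcome == -1 else (-rho_neut if win else rho_neut))
            )
            Q[s, a] += eps * (r - Q[s, a])
            V[s] += eps * (r - V[s])
            rt = float(np.exp(rng.normal(np.log(500.0), 0.25))) if a == 1 else np.nan
            rows.append(
                (participant_id, week, blk, tr, a, rt, outcome, s, cond)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "stimulus", "condition",
        ],
    )
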