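"""Random dot motion: drift diffusion model with coherence-scaled drift.

Accuracy coding with an unbiased start: the upper boundary is the correct
response, trial drift is delta * coherence. RTs are decision time plus the
non-decision time tau (seconds). Trials with no response within 1,500 ms
are excluded from the likelihood, as are (with a steep smooth penalty
during optimization) trials whose RT does not exceed tau.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import ddm

NAME = "rdm"
PARAM_NAMES = ("alpha", "tau", "delta")
TRANSFORM_NAMES = ("log", "log", "log")
PRIOR_LOC = (0.47, -1.05, 1.79)

COHERENCES = (0.05, 0.10, 0.35, 0.50)
RT_DEADLINE_MS = 1500.0
_T_FLOOR = 1e-4
_PENALTY = 1e4  # per second of tau excess over an observed RT


@dataclasses.dataclass
class Design:
    n_blocks: int = 4
    trials_per_block: int = 96
    coherences: tuple = COHERENCES
    deadline_ms: float = RT_DEADLINE_MS


def default_design() -> Design:
    return Design()


def prepare(df: pd.DataFrame, design: Design | None = None) -> dict:
    deadline = design.deadline_ms if design is not None else RT_DEADLINE_MS
    df = df.sort_values(["block", "trial"])
    ok = df["response"].notna() & df["rt_ms"].notna() & (df["rt_ms"] < deadline)
    d = df.loc[ok]
    return dict(
        coh=d["coherence"].to_numpy(float),
        correct=d["response"].to_numpy(int),  # 1 correct / 0 error
        rt=d["rt_ms"].to_numpy(float) / 1000.0,  # seconds inside the likelihood
        n_dropped=int((~ok).sum()),
    )


def loglik(theta, data) -> float:
    return loglik_grad(theta, data)[0]


def trial_probs(theta, data) -> np.ndarray:
    """Model probability of a correct response per trial (choice margin)."""
    alpha, tau, delta = (float(v) for v in theta)
    return ddm.prob_upper(delta * data["coh"], alpha)


def loglik_grad(theta, data):
    alpha, tau, delta = (float(v) for v in theta)
    coh = data["coh"]
    rt = data["rt"]
    correct = data["correct"]
    t_dec = rt - tau
    valid = t_dec > _T_FLOOR
    grad = np.zeros(3)
    ll = 0.0
    if (~valid).any():
        # smooth hinge keeps the objective differentiable while pushing tau
        # back below the smallest fitted RT
        excess = np.clip(tau + _T_FLOOR - rt[~valid], 0.0, None)
        ll -= float(np.sum(_PENALTY * excess + 30.0))
        grad[1] -= _PENALTY * (~valid).sum()
    if valid.any():
        v = delta * coh[valid]
        # correct -> upper boundary == lower boundary under flipped drift
        drift = np.where(correct[valid] == 1, -v, v)
        logf, d_v, d_a, d_t = ddm.logpdf_lower_grad(t_dec[valid], drift, alpha)
        sgn = np.where(correct[valid] == 1, -1.0, 1.0)
        ll += float(np.sum(logf))
        grad[0] += float(np.sum(d_a))
        grad[1] += float(np.sum(-d_t))
        grad[2] += float(np.sum(sgn * d_v * coh[valid]))
    return ll, grad


def simulate(theta, design: Design, rng: np.random.Generator,
             participant_id: str = "sim", week: int = 1,
             method: str = "exact", dt: float = 2.5e-4) -> pd.DataFrame:
    """Simulate a session. ``method='exact'`` inverts the first-passage CDF
    per coherence; ``method='euler'`` integrates sample paths."""
    alpha, tau, delta = (float(v) for v in theta)
    rows = []
    for blk in range(1, design.n_blocks + 1):
        cohs = np.tile(
            np.asarray(design.coherences),
            int(np.ceil(design.trials_per_block / len(design.coherences))),
        )[: design.trials_per_block]
        rng.shuffle(cohs)
        if method == "euler":
            upper, t_dec = _simulate_block(cohs * delta, alpha, rng, dt)
        else:
            upper = np.empty(len(cohs), dtype=bool)
            t_dec = np.empty(len(cohs))
            for c in np.unique(cohs):
                sel = cohs == c
                upper[sel], t_dec[sel] = ddm.sample_fpt(
                    delta * c, alpha, int(sel.sum()), rng
                )
        rt_ms = (t_dec + tau) * 1000.0
        for tr in range(design.trials_per_block):
            if rt_ms[tr] >= design.deadline_ms:
                rows.append(
                    (participant_id, week, blk, tr + 1, np.nan, np.nan, np.nan, cohs[tr])
                )
            else:
                corr = int(upper[tr])
                rows.append(
                    (participant_id, week, blk, tr + 1, corr, rt_ms[tr], corr, cohs[tr])
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "coherence",
        ],
    )


def _simulate_block(drifts, alpha, rng, dt):
    """Vectorized Euler first-passage simulation, one drift per trial."""
    n = len(drifts)
    x = np.full(n, alpha / 2.0)
    t = np.zeros(n)
    upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    sdt = np.sqrt(dt)
    step = 0
    max_steps = int(10.0 / dt)
    while active.size and step < max_steps:
        step += 1
        x[active] += drifts[active] * dt + sdt * rng.standard_normal(active.size)
        up = x[active] >= alpha
        lo = x[active] <= 0.0
        done = up | lo
        if done.any():
            idx = active[done]
            t[idx] = step * dt
            upper[idx] = up[done]
            active = active[~done]
    if active.size:
        t[active] = 10.0
        upper[active] = x[active] > alpha / 2.0
    return upper, t
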