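"""Change detection: maximum-absolute-difference (MAD) observer.

Each of the N items in the display is compared with its probe counterpart
on a noise-corrupted circular-hue axis. The encoded difference of item i is
D_i = d_i + eta with eta ~ Normal(0, 2 sigma(N)^2) (two noisy encodings per
item), and the item is flagged when |D_i| exceeds a threshold theta(N).
Both sigma and theta grow linearly with set size. The observer reports
"different" when any item is flagged:

    P(flag_i) = 1 - [Phi((theta - d_i)/(sqrt2 sigma)) - Phi((-theta - d_i)/(sqrt2 sigma))]
    p(different) = 1 - prod_i (1 - P(flag_i))

Hue distances are circular (degrees, in [0, 180]) but treated as linear
magnitudes inside the Gaussian flag rule; the multiple-target block (0-4
changed items) uses the same per-item rule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm

NAME = "cd"
PARAM_NAMES = ("sigma0", "theta0", "sigma_slope", "theta_slope")
TRANSFORM_NAMES = ("log", "log", "log", "log")
#: reference parameters give realistic psychophysics: per-item false-alarm
#: rates of a few percent (trial-level FA ~5-25% across set sizes) with
#: hits well off ceiling: sigma(N) = 4 + 0.5 N, theta(N) = 17 + 0.9 N (deg)
PRIOR_LOC = (1.39, 2.83, -0.69, -0.105)

SET_SIZES = (3, 4, 6, 8)
_SQRT2 = np.sqrt(2.0)
_MAX_ITEMS = 8
_PCLIP = 1e-12


@dataclasses.dataclass
class Design:
    trials_per_block: int = 40
    # four single-target blocks at fixed set size + one multiple-target block
    set_sizes: tuple = (3, 4, 6, 8, 8)
    multi_target_block: int = 5  # 1-based index into set_sizes
    p_change: float = 0.5
    # random recoloring on the hue circle: |hue difference| ~ U(0, 180)
    d_min: float = 0.0
    d_max: float = 180.0


def default_design() -> Design:
    return Design()


def prepare(df: pd.DataFrame, design: Design | None = None) -> dict:
    df = df.sort_values(["block", "trial"])
    ok = df["response"].notna()
    d = df.loc[ok]
    N = d["set_size"].to_numpy(int)
    bad = ~np.isin(N, SET_SIZES)
    if bad.any():
        raise ValueError(f"set_size outside {SET_SIZES}")
    dmat = d[[f"d{i}" for i in range(1, _MAX_ITEMS + 1)]].to_numpy(float)
    mask = np.arange(_MAX_ITEMS)[None, :] < N[:, None]
    dvals = np.where(mask, np.nan_to_num(dmat, nan=0.0), 0.0)
    if (dvals < 0).any():
        raise ValueError("negative colour differences")
    return dict(
        N=N,
        d=dvals,
        mask=mask,
        resp=d["response"].to_numpy(int),  # 1 = "different"
        n_dropped=int((~ok).sum()),
    )


def _p_same_terms(theta, data):
    sigma0, theta0, s_slope, t_slope = (float(v) for v in theta)
    N = data["N"].astype(float)
    sigN = sigma0 + s_slope * N
    thN = theta0 + t_slope * N
    s = _SQRT2 * sigN  # per-trial encoded-difference s.d.
    d = data["d"]
    u1 = (thN[:, None] - d) / s[:, None]
    u2 = (-thN[:, None] - d) / s[:, None]
    q = norm.cdf(u1) - norm.cdf(u2)  # per-item P(not flagged)
    q = np.where(data["mask"], np.clip(q, _PCLIP, 1.0), 1.0)
    return q, u1, u2, s, N


def trial_probs(theta, data) -> np.ndarray:
    q, *_ = _p_same_terms(theta, data)
    return 1.0 - q.prod(axis=1)  # p("different")


def loglik(theta, data) -> float:
    p_diff = np.clip(trial_probs(theta, data), _PCLIP, 1.0 - _PCLIP)
    r = data["resp"]
    return float(np.sum(np.where(r == 1, np.log(p_diff), np.log1p(-p_diff))))


def loglik_grad(theta, data):
    q, u1, u2, s, N = _p_same_terms(theta, data)
    mask = data["mask"]
    r = data["resp"]
    p_same = q.prod(axis=1)
    p_diff = np.clip(1.0 - p_same, _PCLIP, 1.0 - _PCLIP)

    phi1 = norm.pdf(u1)
    phi2 = norm.pdf(u2)
    s_col = s[:, None]
    # partials of q wrt theta(N) and s
    dq_dth = (phi1 + phi2) / s_col
    dq_ds = -(phi1 * u1 - phi2 * u2) / s_col
    dq_dth = np.where(mask, dq_dth, 0.0)
    dq_ds = np.where(mask, dq_ds, 0.0)

    # d log p_same / d(.) = sum_i dq_i/d(.) / q_i
    inv_q = np.where(mask, 1.0 / q, 0.0)
    dlps_dth = (dq_dth * inv_q).sum(axis=1)
    dlps_ds = (dq_ds * inv_q).sum(axis=1)

    # response weighting: d ll / d log p_same
    w = np.where(r == 1, -p_same / p_diff, 1.0)
    ll = float(np.sum(np.where(r == 1, np.log(p_diff), np.log(np.clip(p_same, _PCLIP, 1.0)))))

    g_th = w * dlps_dth
    g_s = w * dlps_ds
    Nf = N.astype(float)
    grad = np.array(
        [
            np.sum(g_s) * _SQRT2,  # sigma0 (through s = sqrt2 * sigma(N))
            np.sum(g_th),  # theta0
            np.sum(g_s * Nf) * _SQRT2,  # sigma_slope
            np.sum(g_th * Nf),  # theta_slope
        ]
    )
    return ll, grad


def simulate(theta, design: Design, rng: np.random.Generator,
             participant_id: str = "sim", week: int = 1) -> pd.DataFrame:
    sigma0, theta0, s_slope, t_slope = (float(v) for v in theta)
    rows = []
    for blk, N in enumerate(design.set_sizes, start=1):
        sigN = sigma0 + s_slope * N
        thN = theta0 + t_slope * N
        for tr in range(1, design.trials_per_block + 1):
            d = np.zeros(_MAX_ITEMS)
            if blk == design.multi_target_block:
                n_changed = int(rng.integers(0, 5))
            else:
                n_changed = int(rng.random() < design.p_change)
            if n_changed:
                idx = rng.choice(N, size=n_changed, replace=False)
                d[idx] = rng.uniform(design.d_min, design.d_max, size=n_changed)
            enc = d[:N] + rng.normal(0.0, _SQRT2 * sigN, size=N)
            resp = int(np.any(np.abs(enc) > thN))
            correct = int(resp == int(n_changed > 0))
            rt = float(np.exp(rng.normal(np.log(800.0), 0.3)))
            dcols = [d[i] if i < N else np.nan for i in range(_MAX_ITEMS)]
            rows.append(
                (participant_id, week, blk, tr, resp, rt, correct, N, *dcols)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "set_size", *[f"d{i}" for i in range(1, _MAX_ITEMS + 1)],
        ],
    )
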