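"""Psychometric statistics over the fitted phenotype.

* ICC(2,1) — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation, with a participant bootstrap (1,000 resamples)
  and complete-case or first-N_max session filtering.
* Relative contribution (RC) — a dynamic term's s.d. across sessions
  divided by the summed s.d. of all terms, per participant.
* Probability of direction (PD) — the percentage of a posterior that
  shares the sign of its median, with the graded existence labels.
* Practice curves — saturating power-law fits y(t) = A - B t^-C with a
  session-order permutation test on adjusted R^2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .hier.fit import ChainConfig, HierarchicalFit, fit_model
from .tasks import constrain_theta, get_model, simulate_task

__all__ = [
    "N_MAX_SESSIONS",
    "icc_2_1",
    "bootstrap_icc",
    "IccResult",
    "icc_ceiling_experiment",
    "relative_contributions",
    "SourceDecomposition",
    "probability_of_direction",
    "DirectionResult",
    "fit_practice_curve",
    "PracticeCurveFit",
]

#: largest session count available for every participant, per task
N_MAX_SESSIONS = {"gng": 9, "cd": 8, "lt": 8, "tab": 8, "rdm": 9, "itc": 7, "nc": 8}


# ---------------------------------------------------------------------------
# ICC(2,1)


def icc_2_1(matrix: np.ndarray) -> float:
    """Two-way random effects, absolute agreement, single measurement.

    ``matrix`` is participants x sessions and must be complete.
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 matrix")
    if not np.isfinite(x).all():
        raise ValueError("ICC requires a complete matrix; filter first")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


@dataclasses.dataclass
class IccResult:
    parameter: str
    icc_point: float
    bootstrap: np.ndarray  # (n_boot,)
    n_participants: int
    n_sessions: int
    variant: str  # complete_case | nmax

    @property
    def median(self) -> float:
        return float(np.median(self.bootstrap))

    @property
    def iqr(self) -> tuple:
        q1, q3 = np.percentile(self.bootstrap, [25, 75])
        return (float(q1), float(q3))


def bootstrap_icc(
    matrix: np.ndarray | pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    variant: str = "complete_case",
    n_max: int | None = None,
    parameter: str = "",
) -> IccResult:
    """Participant bootstrap of ICC(2,1).

    ``complete_case`` keeps participants with no missing sessions;
    ``nmax`` truncates everyone to their first ``n_max`` observed sessions
    and keeps participants with at least that many.
    """
    x = np.asarray(matrix, float)
    if variant == "complete_case":
        x = x[np.isfinite(x).all(axis=1)]
    elif variant == "nmax":
        if n_max is None:
            raise ValueError("nmax variant requires n_max")
        rows = []
        for r in x:
            obs = r[np.isfinite(r)]
            if len(obs) >= n_max:
                rows.append(obs[:n_max])
        x = np.asarray(rows) if rows else np.empty((0, n_max))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 complete-case participants")
    point = icc_2_1(x)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = icc_2_1(x[rng.integers(0, n, size=n)])
    return IccResult(
        parameter=parameter,
        icc_point=point,
        bootstrap=boot,
        n_participants=n,
        n_sessions=x.shape[1],
        variant=variant,
    )


def icc_ceiling_experiment(
    task: str,
    n_agents: int = 20,
    n_weeks: int = 12,
    seed: int = 0,
    chains: ChainConfig | None = None,
    spread: float = 0.4,
    n_boot: int = 1000,
    two_stage: bool = True,
) -> dict:
    """Reliability ceiling under a phenotype that is perfectly stable in time.

    Agents draw a single unconstrained phenotype from the task's reference
    distribution and keep it fixed across all simulated sessions. The
    independent and reduced models are both fitted; the returned dict maps
    parameter -> (independent IccResult, reduced IccResult). With zero true
    temporal variability the independent fit should approach ICC = 1, and
    the reduced fit (no participant level) should fall below it.
    """
    from .data import TrialTable

    m = get_model(task)
    P = len(m.PARAM_NAMES)
    loc = np.asarray(m.PRIOR_LOC, float)
    rng = np.random.default_rng([seed, 11])
    u = loc + spread * rng.standard_normal((n_agents, P))
    frames = []
    for s in range(n_agents):
        theta = constrain_theta(task, u[s])
        for t in range(1, n_weeks + 1):
            frames.append(
                simulate_task(
                    task, theta, seed=np.random.default_rng([seed, 13, s, t]),
                    participant_id=f"a{s:03d}", week=t,
                )
            )
    trials = TrialTable(task=task, df=pd.concat(frames, ignore_index=True))
    chains = chains or ChainConfig.scaled_down()
    out = {}
    fits = {
        v: fit_model(v, task, trials, seed=seed + 1, chains=chains, two_stage=two_stage)
        for v in ("independent", "reduced")
    }
    for j, pname in enumerate(m.PARAM_NAMES):
        pair = []
        for v in ("independent", "reduced"):
            fit = fits[v]
            est = fit.posterior_mean("y")[:, j]
            mat = np.full((n_agents, n_weeks), np.nan)
            for i in range(fit.obs.n_obs):
                mat[fit.obs.part_idx[i], int(fit.obs.week[i]) - 1] = est[i]
            pair.append(
                bootstrap_icc(mat, n_boot=n_boot, seed=seed + 2, parameter=pname)
            )
        out[pname] = tuple(pair)
    return out


# ---------------------------------------------------------------------------
# relative contributions


@dataclasses.dataclass
class SourceDecomposition:
    """Per-participant share of temporal variability per dynamic source."""

    rc: pd.DataFrame  # participant_id, parameter, term, sd, rc

    def median_rc(self, parameter: str) -> pd.Series:
        d = self.rc[self.rc["parameter"] == parameter]
        return d.groupby("term")["rc"].median()


TERMS = ("practice", "valence", "arousal", "noise")


def relative_contributions(fit: HierarchicalFit) -> SourceDecomposition:
    """RC_k = s.d. of term k across observed sessions / sum over terms.

    Uses posterior-mean term time series per participant (unconstrained
    space); participants observed in fewer than 2 sessions are dropped.
    """
    if fit.variant != "dynamic":
        raise ValueError("relative contributions require a dynamic fit")
    terms = {t: fit.posterior_mean(f"term_{t}") for t in TERMS}  # (n_obs, P)
    rows = []
    part = fit.obs.part_idx
    for s, pid in enumerate(fit.obs.participant_ids):
        sel = part == s
        if sel.sum() < 2:
            continue
        for j, pname in enumerate(fit.param_names):
            sds = {t: float(np.std(terms[t][sel, j], ddof=0)) for t in TERMS}
            total = sum(sds.values())
            for t in TERMS:
                rc = sds[t] / total if total > 0 else np.nan
                rows.append(
                    dict(participant_id=pid, parameter=pname, term=t, sd=sds[t], rc=rc)
                )
    return SourceDecomposition(rc=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# probability of direction


_PD_LABELS = (
    (99.9, "certainly existing"),
    (99.0, "probably existing"),
    (97.0, "likely existing"),
    (95.0, "possibly existing"),
)


@dataclasses.dataclass
class DirectionResult:
    name: str
    pd: float  # percentage in [50, 100]
    median_sign: int
    label: str


def probability_of_direction(draws: np.ndarray, name: str = "") -> DirectionResult:
    """Percentage of the posterior sharing the sign of its median."""
    x = np.asarray(draws, float).ravel()
    if len(x) < 100:
        raise ValueError("need at least 100 draws")
    frac_pos = np.mean(x >= 0)
    frac_neg = np.mean(x <= 0)
    pd_pct = 100.0 * max(frac_pos, frac_neg)
    med = float(np.median(x))
    label = "uncertain"
    for thr, lab in _PD_LABELS:
        if pd_pct >= thr:
            label = lab
            break
    return DirectionResult(
        name=name, pd=float(pd_pct), median_sign=int(np.sign(med)), label=label
    )


# ---------------------------------------------------------------------------
# behavioural practice curves


@dataclasses.dataclass
class PracticeCurveFit:
    a: float
    b: float
    c: float
    r2_adj: float
    p_perm: float
    n_perm: int
    degenerate: bool = False


_C_GRID = np.geomspace(0.05, 8.0, 60)


def _grid_r2(t: np.ndarray, y: np.ndarray) -> float:
    """max over the C grid of the linear-fit R^2 of y on t^-C."""
    return float(_grid_r2_many(t, y[None, :]).max())


def _grid_r2_many(t: np.ndarray, Y: np.ndarray) -> np.ndarray:
    X = t[None, :] ** (-_C_GRID[:, None])  # (C, T)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=1))
    yn = np.sqrt((Yc**2).sum(axis=1))
    yn = np.where(yn == 0, np.inf, yn)
    corr = (Xc @ Yc.T) / (xn[:, None] * yn[None, :])
    return (corr**2).max(axis=0)  # per permutation


def fit_practice_curve(
    series: np.ndarray,
    weeks: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> PracticeCurveFit:
    """Fit y(t) = A - B t^-C and permutation-test the session ordering.

    The permutation statistic is the grid-maximized R^2, identical for the
    observed and permuted orderings (exchangeable by construction); the
    reported parameters and adjusted R^2 come from a polished
    least-squares fit. p uses add-one smoothing:
    p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    y = np.asarray(series, float)
    t = (
        np.arange(1, len(y) + 1, dtype=float)
        if weeks is None
        else np.asarray(weeks, float)
    )
    if len(y) < 4:
        raise ValueError("need at least 4 observed weeks")
    if np.std(y) < 1e-15:
        return PracticeCurveFit(
            a=float(y[0]), b=0.0, c=1.0, r2_adj=-np.inf, p_perm=1.0,
            n_perm=n_perm, degenerate=True,
        )

    # polished fit from the best grid C
    grid_best = _C_GRID[
        int(np.argmax(_grid_r2_many(t, y[None, :])))
    ]

    def ab_for(c):
        x = t**-c
        B = -np.polyfit(x, y, 1)[0]
        A = y.mean() + B * x.mean()
        return A, B

    A0, B0 = ab_for(grid_best)

    def resid(p):
        a, b, logc = p
        return a - b * t ** (-np.exp(logc)) - y

    sol = least_squares(resid, x0=[A0, B0, np.log(grid_best)])
    a, b, logc = sol.x
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    n, p_fit = len(y), 3
    denom = n - p_fit - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else r2

    obs_stat = _grid_r2(t, y)
    rng = np.random.default_rng(seed)
    perms = np.stack([y[rng.permutation(n)] for _ in range(n_perm)])
    perm_stats = _grid_r2_many(t, perms)
    p_perm = (1.0 + np.sum(perm_stats >= obs_stat - 1e-12)) / (1.0 + n_perm)
    return PracticeCurveFit(
        a=float(a), b=float(b), c=float(np.exp(logc)), r2_adj=float(r2_adj),
        p_perm=float(p_perm), n_perm=n_perm,
    )
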