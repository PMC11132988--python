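"""Fitting contract: MAP session estimates, HMC chains and diagnostics.

``fit_model`` fits one task under one statistical model variant. Two paths
are available:

* ``two_stage=True`` (default) — each observed session is first summarized
  by a penalized maximum a posteriori estimate of its unconstrained
  phenotype with a Laplace standard error; the hierarchy is then sampled
  by HMC with the Gaussian pseudo-likelihood ``y_hat ~ N(y, se)``. This is
  an accurate approximation whenever the per-session likelihood is
  informative, and is orders of magnitude faster than the joint fit.
* ``two_stage=False`` — session phenotypes are latent and the trial
  likelihoods enter the sampler directly (the full joint model).

The default chain contract is 4 chains x 1,000 warmup + 1,000 kept draws,
group-level means initialized at their prior centers and every other
quantity at zero in the unconstrained space.
"""

from __future__ import annotations

import dataclasses

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from ..data import TrialTable
from ..tasks import get_model
from ..transforms import get_transform
from .hmc import sample_hmc
from .logjoint import (
    DynamicProblem,
    IndependentProblem,
    ReducedProblem,
    SessionIndex,
    TrialObsLik,
)

__all__ = [
    "ChainConfig",
    "HierarchicalFit",
    "fit_model",
    "map_fit_session",
    "convergence_diagnostics",
]

VARIANTS = ("independent", "reduced", "dynamic")


@dataclasses.dataclass
class ChainConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    max_leapfrog: int = 64
    target_accept: float = 0.8

    @classmethod
    def scaled_down(cls) -> "ChainConfig":
        """2 chains x 500/500 — the reduced contract used in simulations."""
        return cls(chains=2, warmup=500, samples=500)


@dataclasses.dataclass
class HierarchicalFit:
    """Posterior draws plus convergence metadata for one task and variant."""

    variant: str
    task: str
    param_names: tuple
    obs: SessionIndex
    draws: dict  # name -> array with leading (chain, draw) axes
    diagnostics: dict
    seed: int
    states: tuple | None = None  # (valence, arousal) aligned with obs rows

    def posterior_mean(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:]).mean(axis=0)

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])


def map_fit_session(task: str, data, prior_sd: float = 2.5):
    """Penalized MAP of one session's unconstrained phenotype + Laplace s.e.

    The penalty is a weak Normal(prior center, prior_sd) on each
    unconstrained entry; it regularizes sessions that barely identify a
    parameter without materially biasing informative ones.
    """
    m = get_model(task)
    loc = np.asarray(m.PRIOR_LOC, float)
    trs = [get_transform(t) for t in m.TRANSFORM_NAMES]
    P = len(loc)

    def obj(u):
        # L-BFGS probes extreme points; transient overflow is rejected by
        # the line search and carries no signal
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            theta = np.array([tr.constrain(u[j]) for j, tr in enumerate(trs)])
            ll, g = m.loglik_grad(theta, data)
            jac = np.array([tr.dconstrain_du(u[j]) for j, tr in enumerate(trs)])
            f = -(ll - 0.5 * np.sum(((u - loc) / prior_sd) ** 2))
            grad = -(g * jac - (u - loc) / prior_sd**2)
            if not np.isfinite(f):
                return 1e12, np.zeros_like(u)
            return f, np.nan_to_num(grad)

    res = minimize(obj, loc.copy(), jac=True, method="L-BFGS-B")
    u_hat = res.x
    # central-difference Hessian of the objective (P is tiny)
    h = 1e-4
    H = np.zeros((P, P))
    for j in range(P):
        e = np.zeros(P)
        e[j] = h
        H[:, j] = (obj(u_hat + e)[1] - obj(u_hat - e)[1]) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov = np.eye(P)
    # keep the full correlation structure, but bound the spectrum so a flat
    # or ill-conditioned session cannot destabilize the second stage
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    w = np.clip(w, 4e-4, 25.0)
    cov = (V * w) @ V.T
    return u_hat, cov


def _build_sessions(trials: TrialTable, design=None):
    m = get_model(trials.task)
    pids, parts, weeks, datas = [], [], [], []
    index = {}
    for pid, week, g in trials.sessions():
        data = m.prepare(g, design)
        if pid not in index:
            index[pid] = len(index)
            pids.append(pid)
        parts.append(index[pid])
        weeks.append(week)
        datas.append(data)
    obs = SessionIndex(
        participant_ids=pids,
        part_idx=np.asarray(parts, int),
        week=np.asarray(weeks, int),
    )
    return obs, datas


def _align_states(states: pd.DataFrame, obs: SessionIndex):
    """states: DataFrame (participant_id, week, valence, arousal) -> arrays."""
    key = states.set_index(["participant_id", "week"])
    v = np.zeros(obs.n_obs)
    a = np.zeros(obs.n_obs)
    for i in range(obs.n_obs):
        pid = obs.participant_ids[obs.part_idx[i]]
        wk = int(obs.week[i])
        try:
            row = key.loc[(pid, wk)]
            v[i] = float(row["valence"])
            a[i] = float(row["arousal"])
        except KeyError:
            pass  # missing state stays 0 (participant baseline)
    return v, a


def fit_model(
    variant: str,
    task: str,
    trials: TrialTable,
    states: pd.DataFrame | None = None,
    seed: int = 0,
    chains: ChainConfig | None = None,
    two_stage: bool = True,
    design=None,
    prior_sd: float = 2.5,
) -> HierarchicalFit:
    """Fit one statistical model variant to one task's trial table."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "dynamic" and states is None:
        raise ValueError("dynamic variant requires state series")
    chains = chains or ChainConfig()
    m = get_model(task)
    P = len(m.PARAM_NAMES)
    obs, datas = _build_sessions(trials, design)

    loc = np.asarray(m.PRIOR_LOC, float)
    if two_stage:
        from .marginal import (
            MarginalDynamicProblem,
            MarginalIndependentProblem,
            MarginalReducedProblem,
        )

        y_hat = np.empty((obs.n_obs, P))
        cov = np.empty((obs.n_obs, P, P))
        for i, data in enumerate(datas):
            y_hat[i], cov[i] = map_fit_session(task, data, prior_sd=prior_sd)
        if variant == "independent":
            problem = MarginalIndependentProblem(obs, y_hat, cov, P, prior_loc=loc)
        elif variant == "reduced":
            problem = MarginalReducedProblem(obs, y_hat, cov, P, prior_loc=loc)
        else:
            va = _align_states(states, obs)
            problem = MarginalDynamicProblem(obs, y_hat, cov, P, va, prior_loc=loc)
    else:
        lik = TrialObsLik(task, datas)
        if variant == "independent":
            problem = IndependentProblem(obs, lik, P, prior_loc=loc)
        elif variant == "reduced":
            problem = ReducedProblem(obs, lik, P, prior_loc=loc)
        else:
            va = _align_states(states, obs)
            problem = DynamicProblem(obs, lik, P, va, prior_loc=loc)

    results = []
    for c in range(chains.chains):
        rng = np.random.default_rng([seed, c])
        results.append(
            sample_hmc(
                problem.logp_grad,
                problem.init(),
                chains.warmup,
                chains.samples,
                rng,
                target_accept=chains.target_accept,
                max_leapfrog=chains.max_leapfrog,
            )
        )
    packed = np.stack([r.draws for r in results])  # (chains, draws, dim)
    if two_stage:
        draws = problem.unpack_draws(packed, seed=seed)
    else:
        draws = problem.unpack_draws(packed)
    n_div = int(sum(r.n_divergent for r in results))
    diagnostics = _diagnose(draws, n_div, chains.chains)
    return HierarchicalFit(
        variant=variant,
        task=task,
        param_names=m.PARAM_NAMES,
        obs=obs,
        draws=draws,
        diagnostics=diagnostics,
        seed=seed,
        states=(problem.v, problem.a) if isinstance(problem, DynamicProblem) else None,
    )


_DIAG_KEYS = ("mu_g", "sigma", "eta_g", "delta_p", "delta_v", "delta_a")


def _diagnose(draws: dict, n_divergent: int, n_chains: int) -> dict:
    rhats, esss = [], []
    if n_chains >= 2:
        for k in _DIAG_KEYS:
            if k not in draws:
                continue
            arr = draws[k]  # (chains, draws, P)
            for j in range(arr.shape[-1]):
                rhats.append(float(az.rhat(arr[..., j])))
                esss.append(float(az.ess(arr[..., j])))
    return dict(
        max_rhat=max(rhats) if rhats else np.nan,
        min_ess=min(esss) if esss else np.nan,
        n_divergent=n_divergent,
        n_chains=n_chains,
    )


def convergence_diagnostics(
    fit: HierarchicalFit, rhat_max: float = 1.01, allow_divergences: int = 0
) -> dict:
    """Split R-hat / ESS / divergence report with a pass flag."""
    if fit.diagnostics["n_chains"] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    d = dict(fit.diagnostics)
    d["pass"] = bool(
        np.isfinite(d["max_rhat"])
        and d["max_rhat"] <= rhat_max
        and d["n_divergent"] <= allow_divergences
    )
    d["thresholds"] = dict(rhat_max=rhat_max, allow_divergences=allow_divergences)
    return d
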