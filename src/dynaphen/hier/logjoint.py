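"""Log-joint densities of the three statistical models over session phenotypes.

All models live in unconstrained phenotype space; each task parameter has
its own hierarchy (the phenotype is a vector, one hierarchy per entry):

* independent — y_t^s ~ N(mu^s, sigma); mu^s ~ N(mu^g, eta_g);
  sigma, eta_g ~ HalfNormal(0, 1), mu^g ~ N(loc, 1);
* reduced — y_t^s ~ N(mu^g, sigma), no participant level;
* dynamic — y_t^s ~ N(mu^s (1 + delta_p (1 - t^-b^s) + delta_v v_t^s
  + delta_a a_t^s), sigma), with population fractions
  delta_i = 2 Phi(delta_i^prior) - 1 in (-1, 1) and the practice exponent
  b^s = exp(-2 + 3 logistic(z^s)) kept inside (e^-2, e), z^s partially
  pooled with a Normal population prior.

Two layers are provided. The ``log_joint_*`` functions are direct,
hand-checkable evaluators over explicit spec dataclasses. The ``*Problem``
classes expose the same models in the non-centered sampling
parameterization with packed analytic gradients for HMC and MAP.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "SessionIndex",
    "IndependentModelSpec",
    "ReducedModelSpec",
    "DynamicModelSpec",
    "log_joint_independent",
    "log_joint_reduced",
    "log_joint_dynamic",
    "GaussianObsLik",
    "TrialObsLik",
    "IndependentProblem",
    "ReducedProblem",
    "DynamicProblem",
]

_L2PI = np.log(2.0 * np.pi)


def _norm_lp(x, mu=0.0, sd=1.0):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _L2PI


def _halfnorm_lp(x):
    x = np.asarray(x, float)
    if np.any(x <= 0):
        return -np.inf
    return np.sum(np.log(2.0) - 0.5 * x**2 - 0.5 * _L2PI)


@dataclasses.dataclass
class SessionIndex:
    """Maps observed (participant, week) sessions onto array rows."""

    participant_ids: list
    part_idx: np.ndarray  # (n_obs,) int index into participant_ids
    week: np.ndarray  # (n_obs,) calendar week 1..12

    @property
    def n_obs(self) -> int:
        return len(self.part_idx)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)


# ---------------------------------------------------------------------------
# spec dataclasses + direct evaluators


@dataclasses.dataclass
class IndependentModelSpec:
    mu_g: np.ndarray  # (P,)
    eta_g: np.ndarray  # (P,)
    sigma: np.ndarray  # (P,)
    mu_s: np.ndarray  # (S, P)
    prior_loc: np.ndarray | None = None  # hyperprior center of mu_g (default 0)


@dataclasses.dataclass
class ReducedModelSpec:
    mu_g: np.ndarray
    sigma: np.ndarray
    prior_loc: np.ndarray | None = None


@dataclasses.dataclass
class DynamicModelSpec(IndependentModelSpec):
    # population-level raw effects, one per task parameter
    delta_p_prior: np.ndarray = None  # (P,)
    delta_v_prior: np.ndarray = None
    delta_a_prior: np.ndarray = None
    kappa_b: np.ndarray = None  # (P,) population mean of the exponent score
    omega_b: np.ndarray = None  # (P,) population s.d. (> 0)
    b_z: np.ndarray = None  # (S, P) per-participant raw exponent scores


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def practice_exponent(b_z):
    """b = exp(-2 + 3 logistic(z)), bounded inside (e^-2, e)."""
    return np.exp(-2.0 + 3.0 * _sigmoid(np.asarray(b_z, float)))


def delta_fraction(delta_prior):
    """delta = 2 Phi(delta_prior) - 1 in (-1, 1)."""
    return 2.0 * ndtr(np.asarray(delta_prior, float)) - 1.0


def _lik_sum(loglik_fn, y):
    if loglik_fn is None:
        return 0.0
    return float(sum(loglik_fn(i, y[i]) for i in range(len(y))))


def log_joint_independent(spec: IndependentModelSpec, y: np.ndarray,
                          obs: SessionIndex, loglik_fn=None) -> float:
    """Trial likelihood + Normal hierarchy + hyper-priors; -inf off support."""
    if np.any(np.asarray(spec.sigma) <= 0) or np.any(np.asarray(spec.eta_g) <= 0):
        return -np.inf
    loc = 0.0 if spec.prior_loc is None else np.asarray(spec.prior_loc, float)
    lp = _lik_sum(loglik_fn, y)
    lp += float(np.sum(_norm_lp(y, spec.mu_s[obs.part_idx], spec.sigma)))
    lp += float(np.sum(_norm_lp(spec.mu_s, spec.mu_g, spec.eta_g)))
    lp += float(np.sum(_norm_lp(np.asarray(spec.mu_g), loc, 1.0)))
    lp += _halfnorm_lp(spec.sigma) + _halfnorm_lp(spec.eta_g)
    return lp


def log_joint_reduced(spec: ReducedModelSpec, y: np.ndarray,
                      obs: SessionIndex, loglik_fn=None) -> float:
    if np.any(np.asarray(spec.sigma) <= 0):
        return -np.inf
    loc = 0.0 if spec.prior_loc is None else np.asarray(spec.prior_loc, float)
    lp = _lik_sum(loglik_fn, y)
    lp += float(np.sum(_norm_lp(y, np.asarray(spec.mu_g), spec.sigma)))
    lp += float(np.sum(_norm_lp(np.asarray(spec.mu_g), loc, 1.0)))
    lp += _halfnorm_lp(spec.sigma)
    return lp


def log_joint_dynamic(spec: DynamicModelSpec, states, y: np.ndarray,
                      obs: SessionIndex, loglik_fn=None) -> float:
    """states: (valence, arousal) arrays aligned with obs rows, in [-1, 1]."""
    if np.any(np.asarray(spec.sigma) <= 0) or np.any(np.asarray(spec.eta_g) <= 0):
        return -np.inf
    if np.any(np.asarray(spec.omega_b) <= 0):
        return -np.inf
    v, a = (np.asarray(s, float) for s in states)
    b = practice_exponent(spec.b_z)  # (S, P)
    dp = delta_fraction(spec.delta_p_prior)
    dv = delta_fraction(spec.delta_v_prior)
    da = delta_fraction(spec.delta_a_prior)
    t = np.asarray(obs.week, float)[:, None]
    fpr = 1.0 - t ** (-b[obs.part_idx])  # practice curve, exactly 0 at t = 1
    mu_s_obs = spec.mu_s[obs.part_idx]
    mean = mu_s_obs * (1.0 + dp * fpr + dv * v[:, None] + da * a[:, None])
    loc = 0.0 if spec.prior_loc is None else np.asarray(spec.prior_loc, float)

    lp = _lik_sum(loglik_fn, y)
    lp += float(np.sum(_norm_lp(y, mean, spec.sigma)))
    lp += float(np.sum(_norm_lp(spec.mu_s, spec.mu_g, spec.eta_g)))
    lp += float(np.sum(_norm_lp(np.asarray(spec.mu_g), loc, 1.0)))
    lp += _halfnorm_lp(spec.sigma) + _halfnorm_lp(spec.eta_g)
    for d in (spec.delta_p_prior, spec.delta_v_prior, spec.delta_a_prior):
        lp += float(np.sum(_norm_lp(np.asarray(d))))
    lp += float(np.sum(_norm_lp(np.asarray(spec.kappa_b))))
    lp += _halfnorm_lp(spec.omega_b)
    lp += float(np.sum(_norm_lp(spec.b_z, spec.kappa_b, spec.omega_b)))
    return lp


# ---------------------------------------------------------------------------
# observation likelihoods for the sampling problems


class GaussianObsLik:
    """Two-stage pseudo-likelihood: y_hat ~ N(y, se) per session and entry."""

    def __init__(self, y_hat: np.ndarray, se: np.ndarray):
        self.y_hat = np.asarray(y_hat, float)
        self.se = np.asarray(se, float)

    def value_grad(self, y: np.ndarray):
        with np.errstate(over="ignore"):
            r = (y - self.y_hat) / self.se
            lp = float(np.sum(-0.5 * r**2 - np.log(self.se) - 0.5 * _L2PI))
            return lp, -r / self.se


class TrialObsLik:
    """Joint path: the real trial likelihood of each session, with gradients
    chained through the per-parameter constraining transforms."""

    def __init__(self, task: str, session_data: list):
        from ..tasks import get_model
        from ..transforms import get_transform

        self.model = get_model(task)
        self.data = session_data
        self.transforms = [get_transform(t) for t in self.model.TRANSFORM_NAMES]

    def value_grad(self, y: np.ndarray):
        total = 0.0
        grad = np.zeros_like(y)
        for i, data in enumerate(self.data):
            u = y[i]
            theta = np.array([tr.constrain(u[j]) for j, tr in enumerate(self.transforms)])
            ll, g = self.model.loglik_grad(theta, data)
            jac = np.array([tr.dconstrain_du(u[j]) for j, tr in enumerate(self.transforms)])
            total += ll
            grad[i] = g * jac
        return total, grad


# ---------------------------------------------------------------------------
# packed sampling problems (non-centered parameterization)


def _scatter_rows(values: np.ndarray, idx: np.ndarray, n_rows: int) -> np.ndarray:
    out = np.zeros((n_rows, values.shape[1]))
    np.add.at(out, idx, values)
    return out


class IndependentProblem:
    """Non-centered independent model: x = [mu_g, log eta, log sigma,
    mtilde (S*P), ytilde (n*P)]."""

    def __init__(self, obs: SessionIndex, lik, n_params: int, prior_loc=None):
        self.obs = obs
        self.lik = lik
        self.P = n_params
        self.S = obs.n_participants
        self.n = obs.n_obs
        self.loc = np.zeros(n_params) if prior_loc is None else np.asarray(prior_loc, float)
        self.dim = 3 * self.P + self.S * self.P + self.n * self.P

    def init(self) -> np.ndarray:
        x = np.zeros(self.dim)
        x[: self.P] = self.loc  # group means start at their prior centers
        return x

    def _split(self, x):
        P, S, n = self.P, self.S, self.n
        mu_g = x[:P]
        log_eta = x[P: 2 * P]
        log_sigma = x[2 * P: 3 * P]
        mt = x[3 * P: 3 * P + S * P].reshape(S, P)
        yt = x[3 * P + S * P:].reshape(n, P)
        return mu_g, log_eta, log_sigma, mt, yt

    def logp_grad(self, x):
        mu_g, log_eta, log_sigma, mt, yt = self._split(x)
        eta = np.exp(log_eta)
        sigma = np.exp(log_sigma)
        mu_s = mu_g + eta * mt
        y = mu_s[self.obs.part_idx] + sigma * yt

        lp, G = self.lik.value_grad(y)
        lp += float(np.sum(-0.5 * mt**2) + np.sum(-0.5 * yt**2))
        lp += float(np.sum(-0.5 * (mu_g - self.loc) ** 2))
        lp += float(np.sum(-0.5 * eta**2 + log_eta))
        lp += float(np.sum(-0.5 * sigma**2 + log_sigma))

        A = _scatter_rows(G, self.obs.part_idx, self.S)
        g_mu_g = A.sum(axis=0) - (mu_g - self.loc)
        g_log_eta = (A * mt).sum(axis=0) * eta + 1.0 - eta**2
        g_log_sigma = (G * yt).sum(axis=0) * sigma + 1.0 - sigma**2
        g_mt = A * eta - mt
        g_yt = G * sigma - yt
        grad = np.concatenate(
            [g_mu_g, g_log_eta, g_log_sigma, g_mt.ravel(), g_yt.ravel()]
        )
        return lp, grad

    def unpack_draws(self, draws: np.ndarray) -> dict:
        """draws (..., dim) -> named arrays in natural (centered) space."""
        P, S, n = self.P, self.S, self.n
        mu_g = draws[..., :P]
        eta = np.exp(draws[..., P: 2 * P])
        sigma = np.exp(draws[..., 2 * P: 3 * P])
        mt = draws[..., 3 * P: 3 * P + S * P].reshape(*draws.shape[:-1], S, P)
        yt = draws[..., 3 * P + S * P:].reshape(*draws.shape[:-1], n, P)
        mu_s = mu_g[..., None, :] + eta[..., None, :] * mt
        y = np.take(mu_s, self.obs.part_idx, axis=-2) + sigma[..., None, :] * yt
        return dict(mu_g=mu_g, eta_g=eta, sigma=sigma, mu_s=mu_s, y=y)


class ReducedProblem:
    """x = [mu_g, log sigma, ytilde (n*P)] — no participant level."""

    def __init__(self, obs: SessionIndex, lik, n_params: int, prior_loc=None):
        self.obs = obs
        self.lik = lik
        self.P = n_params
        self.n = obs.n_obs
        self.loc = np.zeros(n_params) if prior_loc is None else np.asarray(prior_loc, float)
        self.dim = 2 * self.P + self.n * self.P

    def init(self):
        x = np.zeros(self.dim)
        x[: self.P] = self.loc
        return x

    def logp_grad(self, x):
        P, n = self.P, self.n
        mu_g = x[:P]
        log_sigma = x[P: 2 * P]
        yt = x[2 * P:].reshape(n, P)
        sigma = np.exp(log_sigma)
        y = mu_g + sigma * yt
        lp, G = self.lik.value_grad(y)
        lp += float(np.sum(-0.5 * yt**2) + np.sum(-0.5 * (mu_g - self.loc) ** 2))
        lp += float(np.sum(-0.5 * sigma**2 + log_sigma))
        g_mu_g = G.sum(axis=0) - (mu_g - self.loc)
        g_log_sigma = (G * yt).sum(axis=0) * sigma + 1.0 - sigma**2
        g_yt = G * sigma - yt
        return lp, np.concatenate([g_mu_g, g_log_sigma, g_yt.ravel()])

    def unpack_draws(self, draws: np.ndarray) -> dict:
        P, n = self.P, self.n
        mu_g = draws[..., :P]
        sigma = np.exp(draws[..., P: 2 * P])
        yt = draws[..., 2 * P:].reshape(*draws.shape[:-1], n, P)
        y = mu_g[..., None, :] + sigma[..., None, :] * yt
        return dict(mu_g=mu_g, sigma=sigma, y=y)


class DynamicProblem:
    """x = [mu_g, log eta, log sigma, dp_pr, dv_pr, da_pr, kappa_b,
    log omega_b (each P), bz_tilde (S*P), mtilde (S*P), ytilde (n*P)]."""

    def __init__(self, obs: SessionIndex, lik, n_params: int, states, prior_loc=None):
        self.obs = obs
        self.lik = lik
        self.P = n_params
        self.S = obs.n_participants
        self.n = obs.n_obs
        self.v = np.asarray(states[0], float)
        self.a = np.asarray(states[1], float)
        self.loc = np.zeros(n_params) if prior_loc is None else np.asarray(prior_loc, float)
        self.dim = 8 * self.P + 2 * self.S * self.P + self.n * self.P

    def init(self):
        x = np.zeros(self.dim)
        x[: self.P] = self.loc
        return x

    def _split(self, x):
        P, S, n = self.P, self.S, self.n
        o = 0
        def take(k):
            nonlocal o
            v = x[o: o + k]
            o += k
            return v
        mu_g = take(P)
        log_eta = take(P)
        log_sigma = take(P)
        dp_pr = take(P)
        dv_pr = take(P)
        da_pr = take(P)
        kappa = take(P)
        log_omega = take(P)
        bzt = take(S * P).reshape(S, P)
        mt = take(S * P).reshape(S, P)
        yt = take(n * P).reshape(n, P)
        return mu_g, log_eta, log_sigma, dp_pr, dv_pr, da_pr, kappa, log_omega, bzt, mt, yt

    def _forward(self, x):
        mu_g, log_eta, log_sigma, dp_pr, dv_pr, da_pr, kappa, log_omega, bzt, mt, yt = (
            self._split(x)
        )
        eta = np.exp(log_eta)
        sigma = np.exp(log_sigma)
        omega = np.exp(log_omega)
        mu_s = mu_g + eta * mt
        bz = kappa + omega * bzt
        sb = _sigmoid(bz)
        b = np.exp(-2.0 + 3.0 * sb)  # (S, P)
        dp = delta_fraction(dp_pr)
        dv = delta_fraction(dv_pr)
        da = delta_fraction(da_pr)
        t = self.obs.week.astype(float)[:, None]
        logt = np.log(t)
        tb = np.exp(-b[self.obs.part_idx] * logt)  # t^-b
        fpr = 1.0 - tb
        C = 1.0 + dp * fpr + dv * self.v[:, None] + da * self.a[:, None]
        mu_s_obs = mu_s[self.obs.part_idx]
        mean = mu_s_obs * C
        y = mean + sigma * yt
        return locals()

    def logp_grad(self, x):
        f = self._forward(x)
        obs = self.obs
        lp, G = self.lik.value_grad(f["y"])
        for z in ("mt", "yt", "bzt", "dp_pr", "dv_pr", "da_pr", "kappa"):
            lp += float(np.sum(-0.5 * f[z] ** 2))
        lp += float(np.sum(-0.5 * (f["mu_g"] - self.loc) ** 2))
        for s, ls in (("eta", "log_eta"), ("sigma", "log_sigma"), ("omega", "log_omega")):
            lp += float(np.sum(-0.5 * f[s] ** 2 + f[ls]))

        eta, sigma, omega = f["eta"], f["sigma"], f["omega"]
        mu_s_obs, C, fpr, tb = f["mu_s_obs"], f["C"], f["fpr"], f["tb"]
        dp, dv, da = f["dp"], f["dv"], f["da"]

        # through the observation mean
        A = _scatter_rows(G * C, obs.part_idx, self.S)  # d/d mu_s
        g_mu_g = A.sum(axis=0) - (f["mu_g"] - self.loc)
        g_log_eta = (A * f["mt"]).sum(axis=0) * eta + 1.0 - eta**2
        g_log_sigma = (G * f["yt"]).sum(axis=0) * sigma + 1.0 - sigma**2
        g_mt = A * eta - f["mt"]
        g_yt = G * sigma - f["yt"]

        # population fractions delta_i = 2 Phi(pr) - 1
        Gm = G * mu_s_obs
        phi = lambda u: np.exp(-0.5 * u**2) / np.sqrt(2.0 * np.pi)
        g_dp_pr = (Gm * fpr).sum(axis=0) * 2.0 * phi(f["dp_pr"]) - f["dp_pr"]
        g_dv_pr = (Gm * self.v[:, None]).sum(axis=0) * 2.0 * phi(f["dv_pr"]) - f["dv_pr"]
        g_da_pr = (Gm * self.a[:, None]).sum(axis=0) * 2.0 * phi(f["da_pr"]) - f["da_pr"]

        # practice exponent: d mean / d b = mu_s * dp * t^-b * log t
        logt = np.log(obs.week.astype(float))[:, None]
        B = _scatter_rows(Gm * dp * tb * logt, obs.part_idx, self.S)  # d/d b
        sb = f["sb"]
        db_dbz = f["b"] * 3.0 * sb * (1.0 - sb)
        g_bzt = B * db_dbz * omega - f["bzt"]
        g_kappa = (B * db_dbz).sum(axis=0) - f["kappa"]
        g_log_omega = (B * db_dbz * f["bzt"]).sum(axis=0) * omega + 1.0 - omega**2

        grad = np.concatenate(
            [
                g_mu_g, g_log_eta, g_log_sigma, g_dp_pr, g_dv_pr, g_da_pr,
                g_kappa, g_log_omega, g_bzt.ravel(), g_mt.ravel(), g_yt.ravel(),
            ]
        )
        return lp, grad

    def unpack_draws(self, draws: np.ndarray) -> dict:
        P, S, n = self.P, self.S, self.n
        out = {}
        o = 0
        def take(k, shape=None):
            nonlocal o
            v = draws[..., o: o + k]
            o += k
            if shape:
                v = v.reshape(*draws.shape[:-1], *shape)
            return v
        mu_g = take(P)
        eta = np.exp(take(P))
        sigma = np.exp(take(P))
        dp = delta_fraction(take(P))
        dv = delta_fraction(take(P))
        da = delta_fraction(take(P))
        kappa = take(P)
        omega = np.exp(take(P))
        bzt = take(S * P, (S, P))
        mt = take(S * P, (S, P))
        yt = take(n * P, (n, P))
        mu_s = mu_g[..., None, :] + eta[..., None, :] * mt
        bz = kappa[..., None, :] + omega[..., None, :] * bzt
        b = np.exp(-2.0 + 3.0 * _sigmoid(bz))
        t = self.obs.week.astype(float)[:, None]
        fpr = 1.0 - t ** (-np.take(b, self.obs.part_idx, axis=-2))
        mu_s_obs = np.take(mu_s, self.obs.part_idx, axis=-2)
        practice = mu_s_obs * dp[..., None, :] * fpr
        valence = mu_s_obs * dv[..., None, :] * self.v[:, None]
        arousal = mu_s_obs * da[..., None, :] * self.a[:, None]
        noise = sigma[..., None, :] * yt
        y = mu_s_obs + practice + valence + arousal + noise
        out.update(
            mu_g=mu_g, eta_g=eta, sigma=sigma, delta_p=dp, delta_v=dv,
            delta_a=da, b=b, mu_s=mu_s, y=y, term_practice=practice,
            term_valence=valence, term_arousal=arousal, term_noise=noise,
        )
        return out
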