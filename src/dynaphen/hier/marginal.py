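"""Marginalized two-stage posteriors.

With the Gaussian session pseudo-likelihood y_hat_i ~ N(y_i, Sigma_i)
(Sigma_i the full stage-1 Laplace covariance), the latent session
phenotypes are conjugate and can be integrated out exactly:

    y_hat_i ~ N(mean_i, Sigma_i + diag(sigma^2)),

where mean_i is the model's session mean (participant baseline, plus the
practice/state terms in the dynamic variant). HMC then runs over the
hyper-level quantities only — a few hundred dimensions at most, with no
funnel geometry — and the session phenotypes are recovered afterwards by
exact conditional draws. The results are draws from the same joint
posterior as the un-marginalized formulation.
"""

from __future__ import annotations

import numpy as np

from .logjoint import SessionIndex, _scatter_rows, _sigmoid, delta_fraction

__all__ = [
    "MarginalIndependentProblem",
    "MarginalReducedProblem",
    "MarginalDynamicProblem",
]

_L2PI = np.log(2.0 * np.pi)


class _MarginalBase:
    """Shared machinery: batched Gaussian marginal terms and y recovery."""

    def __init__(self, obs: SessionIndex, y_hat, cov, n_params, prior_loc=None):
        self.obs = obs
        self.P = n_params
        self.S = obs.n_participants
        self.n = obs.n_obs
        self.y_hat = np.asarray(y_hat, float)
        self.cov = np.asarray(cov, float)  # (n, P, P)
        self.prec = np.linalg.inv(self.cov)
        self.loc = np.zeros(n_params) if prior_loc is None else np.asarray(prior_loc, float)

    def _marginal_terms(self, mean, sigma):
        """log N(y_hat | mean, cov + diag(sigma^2)) summed over sessions,
        with d/dmean (n, P) and d/dsigma (P,)."""
        if self.P == 1:  # scalar fast path (no batched linalg)
            a = self.cov[:, 0, 0] + sigma[0] ** 2
            r = (self.y_hat - mean)[:, 0]
            s = r / a
            lp = float(-0.5 * np.sum(np.log(a)) - 0.5 * np.sum(r * s)
                       - 0.5 * self.n * _L2PI)
            d_sigma = sigma * np.array([np.sum(s**2 - 1.0 / a)])
            return lp, s[:, None], d_sigma
        A = self.cov + np.diag(sigma**2)[None]
        r = self.y_hat - mean
        Ainv = np.linalg.inv(A)
        s = np.einsum("nij,nj->ni", Ainv, r)
        sign, logdet = np.linalg.slogdet(A)
        lp = float(-0.5 * np.sum(logdet) - 0.5 * np.sum(r * s)
                   - 0.5 * self.n * self.P * _L2PI)
        d_mean = s
        diagAinv = np.einsum("njj->nj", Ainv)
        d_sigma = sigma * np.sum(s**2 - diagAinv, axis=0)
        return lp, d_mean, d_sigma

    def conditional_y(self, mean, sigma, rng=None):
        """Exact conditional of the latent sessions given the fit level.

        Returns the conditional means (n, P) and, when ``rng`` is given,
        a draw around them.
        """
        if self.P == 1:
            prec = self.prec[:, 0, 0] + 1.0 / sigma[0] ** 2
            mu_post = (self.prec[:, 0, 0] * self.y_hat[:, 0]
                       + mean[:, 0] / sigma[0] ** 2) / prec
            if rng is None:
                return mu_post[:, None]
            return (mu_post + rng.standard_normal(self.n) / np.sqrt(prec))[:, None]
        D_inv = np.diag(1.0 / sigma**2)[None]
        Q = self.prec + D_inv  # (n, P, P) posterior precision
        cov_post = np.linalg.inv(Q)
        b = np.einsum("nij,nj->ni", self.prec, self.y_hat) + mean / sigma**2
        mu_post = np.einsum("nij,nj->ni", cov_post, b)
        if rng is None:
            return mu_post
        L = np.linalg.cholesky(cov_post)
        z = rng.standard_normal((self.n, self.P))
        return mu_post + np.einsum("nij,nj->ni", L, z)


class MarginalIndependentProblem(_MarginalBase):
    """x = [mu_g, log eta, log sigma, mtilde (S*P)]."""

    def __init__(self, obs, y_hat, cov, n_params, prior_loc=None):
        super().__init__(obs, y_hat, cov, n_params, prior_loc)
        self.dim = 3 * self.P + self.S * self.P

    def init(self):
        x = np.zeros(self.dim)
        x[: self.P] = self.loc
        return x

    def _split(self, x):
        P, S = self.P, self.S
        return (x[:P], x[P: 2 * P], x[2 * P: 3 * P],
                x[3 * P:].reshape(S, P))

    def logp_grad(self, x):
        mu_g, log_eta, log_sigma, mt = self._split(x)
        eta, sigma = np.exp(log_eta), np.exp(log_sigma)
        mu_s = mu_g + eta * mt
        mean = mu_s[self.obs.part_idx]
        lp, d_mean, d_sigma = self._marginal_terms(mean, sigma)
        lp += float(np.sum(-0.5 * mt**2) + np.sum(-0.5 * (mu_g - self.loc) ** 2))
        lp += float(np.sum(-0.5 * eta**2 + log_eta))
        lp += float(np.sum(-0.5 * sigma**2 + log_sigma))
        A = _scatter_rows(d_mean, self.obs.part_idx, self.S)
        g_mu_g = A.sum(axis=0) - (mu_g - self.loc)
        g_log_eta = (A * mt).sum(axis=0) * eta + 1.0 - eta**2
        g_log_sigma = d_sigma * sigma + 1.0 - sigma**2
        g_mt = A * eta - mt
        return lp, np.concatenate([g_mu_g, g_log_eta, g_log_sigma, g_mt.ravel()])

    def unpack_draws(self, draws, seed=0):
        P, S = self.P, self.S
        shape = draws.shape[:-1]
        mu_g = draws[..., :P]
        eta = np.exp(draws[..., P: 2 * P])
        sigma = np.exp(draws[..., 2 * P: 3 * P])
        mt = draws[..., 3 * P:].reshape(*shape, S, P)
        mu_s = mu_g[..., None, :] + eta[..., None, :] * mt
        y = _draw_sessions(self, mu_s, sigma, seed)
        return dict(mu_g=mu_g, eta_g=eta, sigma=sigma, mu_s=mu_s, y=y)

    def session_mean(self, mu_s_flat, extras=None):
        return mu_s_flat[self.obs.part_idx]


class MarginalReducedProblem(_MarginalBase):
    """x = [mu_g, log sigma] — every session an independent draw."""

    def __init__(self, obs, y_hat, cov, n_params, prior_loc=None):
        super().__init__(obs, y_hat, cov, n_params, prior_loc)
        self.dim = 2 * self.P

    def init(self):
        x = np.zeros(self.dim)
        x[: self.P] = self.loc
        return x

    def logp_grad(self, x):
        P = self.P
        mu_g, log_sigma = x[:P], x[P:]
        sigma = np.exp(log_sigma)
        mean = np.tile(mu_g, (self.n, 1))
        lp, d_mean, d_sigma = self._marginal_terms(mean, sigma)
        lp += float(np.sum(-0.5 * (mu_g - self.loc) ** 2))
        lp += float(np.sum(-0.5 * sigma**2 + log_sigma))
        g_mu_g = d_mean.sum(axis=0) - (mu_g - self.loc)
        g_log_sigma = d_sigma * sigma + 1.0 - sigma**2
        return lp, np.concatenate([g_mu_g, g_log_sigma])

    def unpack_draws(self, draws, seed=0):
        P = self.P
        shape = draws.shape[:-1]
        mu_g = draws[..., :P]
        sigma = np.exp(draws[..., P:])
        mean = np.broadcast_to(
            mu_g[..., None, :], (*shape, self.n, P)
        )
        y = _draw_sessions_from_means(self, mean, sigma, seed)
        return dict(mu_g=mu_g, sigma=sigma, y=y)


class MarginalDynamicProblem(_MarginalBase):
    """x = [mu_g, log eta, log sigma, dp_pr, dv_pr, da_pr, kappa_b,
    log omega_b (each P), bz_tilde (S*P), mtilde (S*P)]."""

    def __init__(self, obs, y_hat, cov, n_params, states, prior_loc=None):
        super().__init__(obs, y_hat, cov, n_params, prior_loc)
        self.v = np.asarray(states[0], float)
        self.a = np.asarray(states[1], float)
        self.dim = 8 * self.P + 2 * self.S * self.P

    def init(self):
        x = np.zeros(self.dim)
        x[: self.P] = self.loc
        return x

    def _split(self, x):
        P, S = self.P, self.S
        o = 0

        def take(k, shape=None):
            nonlocal o
            v = x[o: o + k]
            o += k
            return v.reshape(shape) if shape else v

        return (take(P), take(P), take(P), take(P), take(P), take(P), take(P),
                take(P), take(S * P, (S, P)), take(S * P, (S, P)))

    def _mean_parts(self, mu_g, eta, mt, dp_pr, dv_pr, da_pr, kappa, omega, bzt):
        mu_s = mu_g + eta * mt
        bz = kappa + omega * bzt
        sb = _sigmoid(bz)
        b = np.exp(-2.0 + 3.0 * sb)
        dp, dv, da = (delta_fraction(z) for z in (dp_pr, dv_pr, da_pr))
        t = self.obs.week.astype(float)[:, None]
        tb = np.exp(-b[self.obs.part_idx] * np.log(t))
        fpr = 1.0 - tb
        C = 1.0 + dp * fpr + dv * self.v[:, None] + da * self.a[:, None]
        return mu_s, b, sb, tb, fpr, C, dp, dv, da

    def logp_grad(self, x):
        (mu_g, log_eta, log_sigma, dp_pr, dv_pr, da_pr, kappa, log_omega,
         bzt, mt) = self._split(x)
        eta, sigma, omega = np.exp(log_eta), np.exp(log_sigma), np.exp(log_omega)
        mu_s, b, sb, tb, fpr, C, dp, dv, da = self._mean_parts(
            mu_g, eta, mt, dp_pr, dv_pr, da_pr, kappa, omega, bzt
        )
        mu_s_obs = mu_s[self.obs.part_idx]
        mean = mu_s_obs * C
        lp, G, d_sigma = self._marginal_terms(mean, sigma)

        for z in (mt, bzt, dp_pr, dv_pr, da_pr, kappa):
            lp += float(np.sum(-0.5 * z**2))
        lp += float(np.sum(-0.5 * (mu_g - self.loc) ** 2))
        for sc, lsc in ((eta, log_eta), (sigma, log_sigma), (omega, log_omega)):
            lp += float(np.sum(-0.5 * sc**2 + lsc))

        A = _scatter_rows(G * C, self.obs.part_idx, self.S)
        g_mu_g = A.sum(axis=0) - (mu_g - self.loc)
        g_log_eta = (A * mt).sum(axis=0) * eta + 1.0 - eta**2
        g_log_sigma = d_sigma * sigma + 1.0 - sigma**2
        g_mt = A * eta - mt

        Gm = G * mu_s_obs
        phi = lambda u: np.exp(-0.5 * u**2) / np.sqrt(2.0 * np.pi)
        g_dp = (Gm * fpr).sum(axis=0) * 2.0 * phi(dp_pr) - dp_pr
        g_dv = (Gm * self.v[:, None]).sum(axis=0) * 2.0 * phi(dv_pr) - dv_pr
        g_da = (Gm * self.a[:, None]).sum(axis=0) * 2.0 * phi(da_pr) - da_pr

        logt = np.log(self.obs.week.astype(float))[:, None]
        B = _scatter_rows(Gm * dp * tb * logt, self.obs.part_idx, self.S)
        db_dbz = b * 3.0 * sb * (1.0 - sb)
        g_bzt = B * db_dbz * omega - bzt
        g_kappa = (B * db_dbz).sum(axis=0) - kappa
        g_log_omega = (B * db_dbz * bzt).sum(axis=0) * omega + 1.0 - omega**2

        return lp, np.concatenate(
            [g_mu_g, g_log_eta, g_log_sigma, g_dp, g_dv, g_da, g_kappa,
             g_log_omega, g_bzt.ravel(), g_mt.ravel()]
        )

    def unpack_draws(self, draws, seed=0):
        P, S = self.P, self.S
        shape = draws.shape[:-1]
        o = 0

        def take(k, sh=None):
            nonlocal o
            v = draws[..., o: o + k]
            o += k
            return v.reshape(*shape, *sh) if sh else v

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
        mu_s = mu_g[..., None, :] + eta[..., None, :] * mt
        bz = kappa[..., None, :] + omega[..., None, :] * bzt
        b = np.exp(-2.0 + 3.0 * _sigmoid(bz))
        t = self.obs.week.astype(float)[:, None]
        fpr = 1.0 - t ** (-np.take(b, self.obs.part_idx, axis=-2))
        mu_s_obs = np.take(mu_s, self.obs.part_idx, axis=-2)
        practice = mu_s_obs * dp[..., None, :] * fpr
        valence = mu_s_obs * dv[..., None, :] * self.v[:, None]
        arousal = mu_s_obs * da[..., None, :] * self.a[:, None]
        mean = mu_s_obs + practice + valence + arousal
        y = _draw_sessions_from_means(self, mean, sigma, seed)
        noise = y - mean
        return dict(
            mu_g=mu_g, eta_g=eta, sigma=sigma, delta_p=dp, delta_v=dv,
            delta_a=da, b=b, mu_s=mu_s, y=y, term_practice=practice,
            term_valence=valence, term_arousal=arousal, term_noise=noise,
        )


def _draw_sessions(problem, mu_s, sigma, seed):
    mean = np.take(mu_s, problem.obs.part_idx, axis=-2)
    return _draw_sessions_from_means(problem, mean, sigma, seed)


def _draw_sessions_from_means(problem, mean, sigma, seed):
    """Exact conditional draws of the session phenotypes, one per kept draw."""
    rng = np.random.default_rng([seed, 97])
    shape = mean.shape[:-2]  # (chains, draws)
    flat_mean = mean.reshape(-1, problem.n, problem.P)
    flat_sigma = sigma.reshape(-1, problem.P)
    out = np.empty_like(flat_mean)
    for i in range(flat_mean.shape[0]):
        out[i] = problem.conditional_y(flat_mean[i], flat_sigma[i], rng)
    return out.reshape(*shape, problem.n, problem.P)
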