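"""Hierarchical models: log-joints vs hand sums, gradients, sampler, fits."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_fit, make_session_index
from dynaphen.hier.fit import (
    ChainConfig,
    HierarchicalFit,
    convergence_diagnostics,
    fit_model,
)
from dynaphen.hier.hmc import sample_hmc
from dynaphen.hier.logjoint import (
    DynamicModelSpec,
    DynamicProblem,
    GaussianObsLik,
    IndependentModelSpec,
    IndependentProblem,
    ReducedModelSpec,
    ReducedProblem,
    SessionIndex,
    TrialObsLik,
    log_joint_dynamic,
    log_joint_independent,
    log_joint_reduced,
    practice_exponent,
)
from dynaphen.phenotype import to_phenotype_matrix
from dynaphen.tasks import get_model, simulate_task


def _halfnorm(x):
    return float(np.log(2.0) + norm.logpdf(x))


# ---------------------------------------------------------------------------
# direct evaluators vs hand-summed densities


def test_independent_toy_matches_hand_sum():
    # 1 participant, 1 session, stubbed likelihood, y = mu_s = mu_g = 0,
    # sigma = eta = 1
    obs = make_session_index([0], [1])
    spec = IndependentModelSpec(
        mu_g=np.zeros(1), eta_g=np.ones(1), sigma=np.ones(1), mu_s=np.zeros((1, 1))
    )
    got = log_joint_independent(spec, np.zeros((1, 1)), obs)
    expected = (
        float(norm.logpdf(0.0))  # y | mu_s
        + float(norm.logpdf(0.0))  # mu_s | mu_g
        + float(norm.logpdf(0.0))  # mu_g prior
        + _halfnorm(1.0)  # sigma
        + _halfnorm(1.0)  # eta_g
    )
    assert got == pytest.approx(expected, abs=1e-12)


def test_independent_two_participant_toy_matches_hand_sum():
    obs = make_session_index([0, 0, 1], [1, 2, 1])
    y = np.array([[0.3], [-0.2], [0.5]])
    spec = IndependentModelSpec(
        mu_g=np.array([0.1]), eta_g=np.array([0.7]), sigma=np.array([0.4]),
        mu_s=np.array([[0.2], [-0.1]]),
    )
    got = log_joint_independent(spec, y, obs)
    expected = (
        norm.logpdf(0.3, 0.2, 0.4) + norm.logpdf(-0.2, 0.2, 0.4)
        + norm.logpdf(0.5, -0.1, 0.4)
        + norm.logpdf(0.2, 0.1, 0.7) + norm.logpdf(-0.1, 0.1, 0.7)
        + norm.logpdf(0.1)
        + _halfnorm(0.4) + _halfnorm(0.7)
    )
    assert got == pytest.approx(float(expected), abs=1e-10)


def test_y_at_baseline_maximizes_session_terms():
    obs = make_session_index([0, 0, 0], [1, 2, 3])
    spec = IndependentModelSpec(
        mu_g=np.zeros(1), eta_g=np.ones(1), sigma=np.ones(1),
        mu_s=np.full((1, 1), 0.4),
    )
    best = log_joint_independent(spec, np.full((3, 1), 0.4), obs)
    for shift in (0.1, -0.3, 1.0):
        assert best > log_joint_independent(spec, np.full((3, 1), 0.4 + shift), obs)


def test_doubling_the_dataset_doubles_only_the_data_terms():
    obs1 = make_session_index([0, 0], [1, 2])
    y1 = np.array([[0.3], [-0.4]])
    spec1 = IndependentModelSpec(
        mu_g=np.array([0.2]), eta_g=np.array([0.8]), sigma=np.array([0.5]),
        mu_s=np.array([[0.1]]),
    )
    obs2 = make_session_index([0, 0, 1, 1], [1, 2, 1, 2])
    spec2 = IndependentModelSpec(
        mu_g=spec1.mu_g, eta_g=spec1.eta_g, sigma=spec1.sigma,
        mu_s=np.array([[0.1], [0.1]]),
    )
    lp1 = log_joint_independent(spec1, y1, obs1)
    lp2 = log_joint_independent(spec2, np.vstack([y1, y1]), obs2)
    hyper = (
        float(norm.logpdf(0.2)) + _halfnorm(0.5) + _halfnorm(0.8)
    )
    assert lp2 - hyper == pytest.approx(2.0 * (lp1 - hyper), abs=1e-10)


def test_off_support_scale_parameters_give_minus_inf():
    obs = make_session_index([0], [1])
    spec = IndependentModelSpec(
        mu_g=np.zeros(1), eta_g=np.array([-1.0]), sigma=np.ones(1),
        mu_s=np.zeros((1, 1)),
    )
    assert log_joint_independent(spec, np.zeros((1, 1)), obs) == -np.inf


def test_reduced_single_session_and_exchangeability():
    obs = make_session_index([0], [1])
    spec = ReducedModelSpec(mu_g=np.zeros(1), sigma=np.ones(1))
    got = log_joint_reduced(spec, np.zeros((1, 1)), obs)
    expected = float(norm.logpdf(0.0)) * 2 + _halfnorm(1.0)
    assert got == pytest.approx(expected, abs=1e-12)

    obs2 = make_session_index([0, 1, 2], [1, 1, 1])
    y = np.array([[0.3], [-0.2], [0.9]])
    a = log_joint_reduced(spec, y, obs2)
    b = log_joint_reduced(spec, y[::-1], make_session_index([2, 1, 0], [1, 1, 1]))
    assert a == pytest.approx(b, abs=1e-12)


def test_reduced_is_independent_in_the_collapsed_limit():
    # with mu_s == mu_g, the models differ exactly by the participant-level
    # density terms and the eta prior
    obs = make_session_index([0, 0, 1], [1, 2, 1])
    y = np.array([[0.3], [-0.2], [0.5]])
    mu_g, sigma, eta = np.array([0.1]), np.array([0.4]), np.array([0.05])
    ind = log_joint_independent(
        IndependentModelSpec(
            mu_g=mu_g, eta_g=eta, sigma=sigma, mu_s=np.tile(mu_g, (2, 1))
        ),
        y, obs,
    )
    red = log_joint_reduced(ReducedModelSpec(mu_g=mu_g, sigma=sigma), y, obs)
    extra = 2 * float(norm.logpdf(0.0, scale=eta[0])) + _halfnorm(eta[0])
    assert ind - red == pytest.approx(extra, abs=1e-10)


def _dyn_spec(delta=0.0, S=2, P=1):
    return DynamicModelSpec(
        mu_g=np.full(P, 0.3), eta_g=np.full(P, 0.6), sigma=np.full(P, 0.4),
        mu_s=np.full((S, P), 0.5),
        delta_p_prior=np.full(P, delta), delta_v_prior=np.full(P, delta),
        delta_a_prior=np.full(P, delta),
        kappa_b=np.zeros(P), omega_b=np.ones(P), b_z=np.full((S, P), 0.3),
    )


def test_dynamic_reduces_to_independent_when_deltas_vanish():
    obs = make_session_index([0, 0, 1], [1, 3, 2])
    y = np.array([[0.4], [0.1], [-0.2]])
    states = (np.array([0.5, -1.0, 0.2]), np.array([-0.3, 0.8, 0.0]))
    dyn = log_joint_dynamic(_dyn_spec(0.0), states, y, obs)
    spec = _dyn_spec(0.0)
    ind = log_joint_independent(
        IndependentModelSpec(
            mu_g=spec.mu_g, eta_g=spec.eta_g, sigma=spec.sigma, mu_s=spec.mu_s
        ),
        y, obs,
    )
    const = (
        3 * float(norm.logpdf(0.0))  # the three delta priors at zero
        + float(norm.logpdf(0.0))  # kappa_b
        + _halfnorm(1.0)  # omega_b
        + 2 * float(norm.logpdf(0.3, 0.0, 1.0))  # b_z population terms
    )
    assert dyn - ind == pytest.approx(const, abs=1e-10)


def test_practice_term_is_zero_at_week_one_and_saturates():
    b = practice_exponent(np.array([-1.0, 0.0, 2.0]))
    assert np.all((b > np.exp(-2)) & (b < np.exp(1)))
    t = np.array([1.0])
    assert np.all(1.0 - t ** (-b) == 0.0)
    # monotone in t, approaching the asymptote (the full effect delta_p^s)
    grid = np.array([1.0, 2.0, 5.0, 20.0, 1e4])
    curve = 1.0 - grid[:, None] ** (-b[None, :])
    assert np.all(np.diff(curve, axis=0) > 0)
    assert np.all(1.0 - np.array([1e300]) ** (-b) == 1.0)


def test_dynamic_exponent_bound_is_respected_in_draws():
    z = np.linspace(-50, 50, 101)
    b = practice_exponent(z)
    assert b.min() >= np.exp(-2) and b.max() <= np.exp(1)


# ---------------------------------------------------------------------------
# packed problems: gradient checks against central finite differences


def _fd_check(problem, x, rel_tol=1e-4, h=1e-5):
    lp, g = problem.logp_grad(x)
    fd = np.empty_like(x)
    for j in range(len(x)):
        e = np.zeros_like(x)
        e[j] = h
        fd[j] = (problem.logp_grad(x + e)[0] - problem.logp_grad(x - e)[0]) / (2 * h)
    denom = np.maximum(np.abs(fd), 1.0)
    assert np.max(np.abs(g - fd) / denom) < rel_tol


def _toy_obs():
    return make_session_index([0, 0, 1, 1], [1, 2, 2, 4])


def test_independent_problem_gradient_vs_fd(rng):
    obs = _toy_obs()
    lik = GaussianObsLik(rng.normal(size=(4, 2)), 0.3 + rng.random((4, 2)))
    prob = IndependentProblem(obs, lik, 2)
    _fd_check(prob, 0.3 * rng.standard_normal(prob.dim))


def test_reduced_problem_gradient_vs_fd(rng):
    obs = _toy_obs()
    lik = GaussianObsLik(rng.normal(size=(4, 2)), 0.3 + rng.random((4, 2)))
    prob = ReducedProblem(obs, lik, 2)
    _fd_check(prob, 0.3 * rng.standard_normal(prob.dim))


def test_dynamic_problem_gradient_vs_fd(rng):
    obs = _toy_obs()
    lik = GaussianObsLik(rng.normal(size=(4, 2)), 0.3 + rng.random((4, 2)))
    states = (rng.uniform(-1, 1, 4), rng.uniform(-1, 1, 4))
    prob = DynamicProblem(obs, lik, 2, states)
    _fd_check(prob, 0.3 * rng.standard_normal(prob.dim))


@pytest.mark.parametrize("task", ["nc", "itc", "lt", "tab", "gng"])
def test_joint_problem_gradient_vs_fd_with_real_likelihood(task, rng):
    m = get_model(task)
    theta = {
        "nc": (0.25,), "itc": (0.02, 0.3), "lt": (0.9, 0.5),
        "tab": (0.15, 0.15, 2.0), "gng": (0.2, 0.3, 0.2, 3.0, 1.2, 0.1),
    }[task]
    small_kw = {
        "nc": dict(n_trials=40), "itc": dict(), "lt": dict(),
        "tab": dict(n_blocks=5), "gng": dict(n_blocks=1, trials_per_block=40),
    }[task]
    small = m.Design(**small_kw)
    datas = [
        m.prepare(simulate_task(task, theta, design=small, seed=s), small)
        for s in (1, 2)
    ]
    obs = make_session_index([0, 1], [1, 2])
    lik = TrialObsLik(task, datas)
    prob = IndependentProblem(obs, lik, len(m.PARAM_NAMES),
                              prior_loc=np.asarray(m.PRIOR_LOC))
    x = prob.init() + 0.05 * rng.standard_normal(prob.dim)
    _fd_check(prob, x, rel_tol=1e-4)


# ---------------------------------------------------------------------------
# HMC sampler


def test_hmc_recovers_gaussian_moments():
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    prec = np.linalg.inv(cov)

    def lp(x):
        return -0.5 * x @ prec @ x, -prec @ x

    res = sample_hmc(lp, np.zeros(2), 500, 2000, np.random.default_rng(0))
    assert np.allclose(res.draws.mean(axis=0), [0, 0], atol=0.12)
    assert np.allclose(np.cov(res.draws.T), cov, atol=0.2)
    assert res.n_divergent == 0


def test_hmc_is_deterministic_under_seed():
    def lp(x):
        return -0.5 * float(x @ x), -x

    a = sample_hmc(lp, np.zeros(3), 100, 100, np.random.default_rng(5))
    b = sample_hmc(lp, np.zeros(3), 100, 100, np.random.default_rng(5))
    assert np.array_equal(a.draws, b.draws)


# ---------------------------------------------------------------------------
# fit contract and diagnostics


def _fake_fit(chain_arrays):
    obs = make_session_index([0], [1])
    draws = dict(
        mu_g=np.stack(chain_arrays)[..., None],
        y=np.zeros((len(chain_arrays), len(chain_arrays[0]), 1, 1)),
    )
    import arviz as az

    rhat = float(az.rhat(draws["mu_g"][..., 0]))
    diag = dict(max_rhat=rhat, min_ess=100.0, n_divergent=0,
                n_chains=len(chain_arrays))
    return HierarchicalFit(
        variant="independent", task="nc", param_names=("w",), obs=obs,
        draws=draws, diagnostics=diag, seed=0,
    )


def test_rhat_near_one_for_identical_sampling_and_large_for_disjoint(rng):
    x = rng.standard_normal(2000)
    good = _fake_fit([x, x.copy()])
    assert convergence_diagnostics(good)["max_rhat"] < 1.01
    bad = _fake_fit([rng.standard_normal(2000), 10 + rng.standard_normal(2000)])
    rep = convergence_diagnostics(bad)
    assert rep["max_rhat"] > 1.1 and not rep["pass"]


def test_single_chain_refuses_rhat(rng):
    fit = _fake_fit([rng.standard_normal(100)])
    with pytest.raises(ValueError, match="2 chains"):
        convergence_diagnostics(fit)


def test_fit_model_is_deterministic_under_seed():
    from dynaphen.cohort import CohortConfig, generate_cohort

    c = generate_cohort(CohortConfig(n_participants=4, n_weeks=6, tasks=("nc",)), seed=2)
    cfg = ChainConfig(chains=2, warmup=100, samples=100)
    f1 = fit_model("independent", "nc", c["trials"]["nc"], seed=9, chains=cfg)
    f2 = fit_model("independent", "nc", c["trials"]["nc"], seed=9, chains=cfg)
    assert np.array_equal(f1.draws["y"], f2.draws["y"])


def test_joint_and_two_stage_fits_agree_on_group_mean():
    from dynaphen.cohort import CohortConfig, generate_cohort
    from dynaphen.tasks.nc import Design as NcDesign

    c = generate_cohort(
        CohortConfig(n_participants=4, n_weeks=3, tasks=("nc",),
                     designs={"nc": NcDesign(n_trials=60)}),
        seed=6,
    )
    cfg = ChainConfig(chains=2, warmup=120, samples=120, max_leapfrog=24)
    two = fit_model("independent", "nc", c["trials"]["nc"], seed=3, chains=cfg)
    joint = fit_model(
        "independent", "nc", c["trials"]["nc"], seed=3, chains=cfg, two_stage=False
    )
    mu2 = float(two.posterior_mean("mu_g")[0])
    muj = float(joint.posterior_mean("mu_g")[0])
    sd = float(joint.flat("mu_g")[:, 0].std())
    assert abs(mu2 - muj) < 4 * sd + 0.05


# ---------------------------------------------------------------------------
# phenotype extraction


def test_single_draw_phenotype_equals_that_draw():
    obs = make_session_index([0, 1], [1, 1])
    y = np.array([[[[-1.0], [0.5]]]])  # (1 chain, 1 draw, 2 obs, 1 param)
    fit = make_fit("nc", y, obs, ("w",), diagnostics=dict(
        max_rhat=1.0, min_ess=1.0, n_divergent=0, n_chains=2))
    mat = to_phenotype_matrix(fit, constrained=False)
    est = mat.df.set_index("participant_id")["estimate"]
    assert est["p000"] == -1.0 and est["p001"] == 0.5


def test_symmetric_draws_average_to_zero_unconstrained():
    obs = make_session_index([0], [1])
    y = np.array([[[[0.7]], [[-0.7]]]])  # two draws v and -v
    fit = make_fit("nc", y, obs, ("w",), diagnostics=dict(
        max_rhat=1.0, min_ess=1.0, n_divergent=0, n_chains=2))
    mat = to_phenotype_matrix(fit, constrained=False)
    assert mat.df["estimate"].iloc[0] == 0.0


def test_many_draws_recover_the_sampling_mean(rng):
    obs = make_session_index([0], [1])
    y = rng.normal(1.5, 0.1, size=(4, 1000, 1, 1))
    fit = make_fit("nc", y, obs, ("w",), diagnostics=dict(
        max_rhat=1.0, min_ess=1.0, n_divergent=0, n_chains=4))
    mat = to_phenotype_matrix(fit, constrained=False)
    assert mat.df["estimate"].iloc[0] == pytest.approx(1.5, abs=0.01)


def test_failed_diagnostics_refuse_without_override():
    obs = make_session_index([0], [1])
    y = np.zeros((2, 5, 1, 1))
    fit = make_fit("nc", y, obs, ("w",), diagnostics=dict(
        max_rhat=1.5, min_ess=1.0, n_divergent=3, n_chains=2))
    with pytest.raises(RuntimeError, match="diagnostics"):
        to_phenotype_matrix(fit)
    to_phenotype_matrix(fit, override=True)  # override path succeeds
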