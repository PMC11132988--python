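"""Task likelihoods against hand-evaluated formulas and their simulators."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from scipy.special import expit
from scipy.stats import norm

from dynaphen.tasks import (
    TASK_MODELS,
    constrain_theta,
    get_model,
    simulate_task,
    unconstrain_theta,
)
from dynaphen.tasks import ddm

THETA = {
    "gng": (0.2, 0.3, 0.2, 3.0, 1.2, 0.1),
    "cd": (8.0, 18.0, 0.8, 1.0),
    "rdm": (1.6, 0.35, 6.0),
    "lt": (0.9, 0.5),
    "itc": (0.02, 0.3),
    "tab": (0.15, 0.15, 2.0),
    "nc": (0.25,),
}

BIG_DESIGN = {
    "gng": dict(n_blocks=42),  # ~10^4 trials
    "cd": dict(trials_per_block=500),
    "rdm": dict(trials_per_block=625),
    "lt": dict(trials_per_block=10, n_blocks=3),
    "itc": dict(),
    "tab": dict(n_blocks=300),
    "nc": dict(n_trials=10000),
}


def _big_design(task):
    m = get_model(task)
    return m.Design(**BIG_DESIGN[task])


# ---------------------------------------------------------------------------
# gng


def _gng_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "stimulus", "condition",
        ],
    )


def test_gng_pure_lapse_gives_T_log_half():
    df = simulate_task("gng", THETA["gng"], seed=0)
    data = get_model("gng").prepare(df)
    T = len(df)
    ll = get_model("gng").loglik((0.7, -0.4, 0.3, 2.0, 1.0, 1.0), data)
    assert ll == pytest.approx(T * np.log(0.5), abs=1e-12)


def test_gng_first_trial_go_bias_ln2_gives_two_thirds():
    df = _gng_df([("p", 1, 1, 1, 1, 400.0, 1, 0, "go_win")])
    data = get_model("gng").prepare(df)
    p = get_model("gng").trial_probs((np.log(2.0), 0.0, 0.5, 1.0, 1.0, 0.0), data)
    assert p[0] == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_gng_single_rescorla_wagner_step():
    # after one rewarded Go with rho_rp=2, eps=0.5: Q(go,s)=1 and V(s)=1,
    # so the second trial's action weight difference is Q + pi*V = 1 + pi
    pi = 0.5
    df = _gng_df(
        [
            ("p", 1, 1, 1, 1, 400.0, 1, 0, "go_win"),
            ("p", 1, 1, 2, 1, 400.0, 1, 0, "go_win"),
        ]
    )
    data = get_model("gng").prepare(df)
    p = get_model("gng").trial_probs((0.0, pi, 0.5, 2.0, 1.0, 0.0), data)
    assert p[1] == pytest.approx(expit(1.0 + pi * 1.0), abs=1e-12)


def test_gng_neutral_outcomes_are_context_coded():
    # neutral in a win condition punishes: V moves down by eps*rho_neut
    df = _gng_df(
        [
            ("p", 1, 1, 1, 1, 400.0, 0, 0, "go_win"),
            ("p", 1, 1, 2, 1, 400.0, 0, 0, "go_win"),
        ]
    )
    data = get_model("gng").prepare(df)
    eps, rho_neut, pi = 0.5, 1.5, 1.0
    p = get_model("gng").trial_probs((0.0, pi, eps, 2.0, rho_neut, 0.0), data)
    q = v = -eps * rho_neut
    assert p[1] == pytest.approx(expit(q + pi * v), abs=1e-12)
    # neutral in an avoid condition rewards
    df2 = _gng_df(
        [
            ("p", 1, 1, 1, 1, 400.0, 0, 0, "go_avoid"),
            ("p", 1, 1, 2, 1, 400.0, 0, 0, "go_avoid"),
        ]
    )
    p2 = get_model("gng").trial_probs(
        (0.0, pi, eps, 2.0, rho_neut, 0.0), get_model("gng").prepare(df2)
    )
    assert p2[1] == pytest.approx(expit(eps * rho_neut * 2.0), abs=1e-12)


def test_gng_lapse_bounds_probabilities():
    xi = 0.3
    df = simulate_task("gng", THETA["gng"], seed=2)
    p = get_model("gng").trial_probs(
        (0.2, 0.3, 0.2, 3.0, 1.2, xi), get_model("gng").prepare(df)
    )
    assert np.all(p >= xi / 2 - 1e-12) and np.all(p <= 1 - xi / 2 + 1e-12)


def test_gng_random_responder_simulates_at_half():
    df = simulate_task("gng", (0.2, 0.3, 0.2, 3.0, 1.2, 1.0),
                       design=_big_design("gng"), seed=3)
    p_go = (df["response"] == 1).mean()
    assert p_go == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# cd


def _cd_df(set_size, d, resp=1):
    row = dict(
        participant_id="p", week=1, block=1, trial=1, response=resp,
        rt_ms=600.0, outcome=1, set_size=set_size,
    )
    for i in range(8):
        row[f"d{i+1}"] = d[i] if i < len(d) else np.nan
    return pd.DataFrame([row])


def test_cd_flag_rule_matches_hand_computation():
    sigma0, theta0, s_sl, t_sl = 5.0, 15.0, 0.5, 1.0
    N, d = 3, [20.0, 0.0, 0.0]
    sigN, thN = sigma0 + s_sl * N, theta0 + t_sl * N
    s = np.sqrt(2) * sigN
    q = [norm.cdf((thN - di) / s) - norm.cdf((-thN - di) / s) for di in d]
    expected = 1.0 - np.prod(q)
    data = get_model("cd").prepare(_cd_df(N, d))
    p = get_model("cd").trial_probs((sigma0, theta0, s_sl, t_sl), data)
    assert p[0] == pytest.approx(expected, abs=1e-10)


def test_cd_single_item_threshold_identity():
    # with d = theta the flag probability is 0.5 + Phi(-sqrt2 theta/sigma)
    sigma, theta = 6.0, 12.0
    data = get_model("cd").prepare(_cd_df(3, [theta, 0.0, 0.0]))
    p = get_model("cd").trial_probs((sigma, theta, 0.0, 0.0), data)
    s = np.sqrt(2) * sigma
    p_flag = 0.5 + norm.cdf(-np.sqrt(2) * theta / sigma)
    q0 = norm.cdf(theta / s) - norm.cdf(-theta / s)
    assert p[0] == pytest.approx(1 - (1 - p_flag) * q0**2, abs=1e-10)


def test_cd_no_change_high_threshold_never_responds_different():
    data = get_model("cd").prepare(_cd_df(4, [0.0] * 4))
    p = get_model("cd").trial_probs((1.0, 500.0, 0.0, 0.0), data)
    assert p[0] < 1e-8


def test_cd_zero_slopes_make_set_size_irrelevant():
    # with zero slopes, sigma(N) and theta(N) do not vary with set size:
    # a single changed item at threshold yields the same p("different")
    # whenever the unchanged items are far inside the no-flag region
    theta = (1.0, 50.0, 1e-12, 1e-12)
    ps = []
    for N in (3, 4, 6, 8):
        d = [50.0] + [0.0] * (N - 1)
        data = get_model("cd").prepare(_cd_df(N, d))
        ps.append(get_model("cd").trial_probs(theta, data)[0])
    assert np.ptp(ps) < 1e-10
    assert 0.4 < ps[0] < 0.6  # the threshold item flags about half the time


# ---------------------------------------------------------------------------
# rdm


def test_rdm_choice_probability_closed_form():
    assert ddm.prob_upper(1.0, 2.0) == pytest.approx(0.88080, abs=5e-6)
    assert ddm.prob_upper(0.0, 2.0) == 0.5


def test_rdm_mean_rt_closed_form():
    # (alpha/2v) tanh(alpha v/2) + tau at alpha=2, v=1, tau=0.3
    assert ddm.mean_decision_time(1.0, 2.0) + 0.3 == pytest.approx(1.06159, abs=5e-6)


def test_rdm_simulated_accuracy_matches_logistic_per_coherence():
    alpha, tau, delta = 1.6, 0.3, 6.0
    design = get_model("rdm").Design(n_blocks=1, trials_per_block=2000,
                                     deadline_ms=1e6)
    df = simulate_task("rdm", (alpha, tau, delta), design=design, seed=9)
    for c, g in df.groupby("coherence"):
        expected = float(ddm.prob_upper(delta * c, alpha))
        acc = (g["response"] == 1).mean()
        se = np.sqrt(expected * (1 - expected) / len(g))
        assert abs(acc - expected) < 4 * se + 0.01


def test_rdm_trials_at_or_below_tau_are_dropped_not_fatal():
    df = simulate_task("rdm", THETA["rdm"], seed=4)
    data = get_model("rdm").prepare(df)
    ll_ok, _ = get_model("rdm").loglik_grad((1.6, 0.35, 6.0), data)
    # huge tau: every trial violates rt > tau and is penalized
    ll_bad, g = get_model("rdm").loglik_grad((1.6, 5.0, 6.0), data)
    assert np.isfinite(ll_ok) and ll_bad < ll_ok
    assert g[1] < 0  # pushes tau back down


# ---------------------------------------------------------------------------
# lt


def _lt_df(p, risky, safe):
    return pd.DataFrame(
        [
            dict(
                participant_id="p", week=1, block=1, trial=1, response=1,
                rt_ms=500.0, outcome=np.nan, p=p, risky_hi=risky[0],
                risky_lo=risky[1], safe_hi=safe[0], safe_lo=safe[1],
            )
        ]
    )


def test_lt_printed_menu_example():
    # safe {0.2: $2.00, 0.8: $1.60}, risky {0.2: $3.85, 0.8: $0.10}
    data = get_model("lt").prepare(_lt_df(0.2, (3.85, 0.10), (2.00, 1.60)))
    p = get_model("lt").trial_probs((1.0, 1.0), data)
    assert p[0] == pytest.approx(expit(0.85 - 1.68), abs=1e-10)
    assert p[0] == pytest.approx(0.3036, abs=2e-4)


def test_lt_zero_temperature_is_chance():
    data = get_model("lt").prepare(_lt_df(0.5, (3.85, 0.10), (2.00, 1.60)))
    assert get_model("lt").trial_probs((0.9, 1e-12), data)[0] == pytest.approx(0.5)


def test_lt_rho_to_zero_is_chance():
    data = get_model("lt").prepare(_lt_df(0.5, (3.85, 0.10), (2.00, 1.60)))
    p = get_model("lt").trial_probs((1e-8, 1.0), data)
    assert p[0] == pytest.approx(0.5, abs=1e-6)


# ---------------------------------------------------------------------------
# itc


def _itc_df(a0, aD, D):
    return pd.DataFrame(
        [
            dict(
                participant_id="p", week=1, block=1, trial=1, response=1,
                rt_ms=500.0, outcome=np.nan, amount_now=a0, amount_later=aD,
                delay_days=D,
            )
        ]
    )


def test_itc_hyperbolic_value_and_softmax():
    # V(10, 30 d) at k=0.1 is 10/4 = 2.5
    data = get_model("itc").prepare(_itc_df(2.5, 10.0, 30.0))
    assert get_model("itc").trial_probs((0.1, 5.0), data)[0] == pytest.approx(0.5)
    # k=0: $5 now vs $10 delayed at beta=1 -> logistic(5)
    data = get_model("itc").prepare(_itc_df(5.0, 10.0, 30.0))
    assert get_model("itc").trial_probs((1e-14, 1.0), data)[0] == pytest.approx(
        0.9933, abs=1e-4
    )
    assert get_model("itc").trial_probs((0.1, 0.0), data)[0] == 0.5


# ---------------------------------------------------------------------------
# tab


def _tab_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "week", "block", "trial", "response", "rt_ms",
            "outcome", "arm1_label", "arm2_label", "reward",
        ],
    )


def test_tab_single_kalman_step():
    # m=0, s2=100, tau_obs2=10, observe r=10: kappa=10/11, m'=s2'=100/11
    design = get_model("tab").Design(risky_sd=np.sqrt(10.0), s0sq=100.0, m0=0.0)
    df = _tab_df(
        [
            ("p", 1, 1, 1, 1, 500.0, 10.0, "R", "R", 10.0),
            ("p", 1, 1, 2, 1, 500.0, 0.0, "R", "R", 0.0),
        ]
    )
    data = get_model("tab").prepare(df, design)
    assert data["V"][1] == pytest.approx(100.0 / 11.0, abs=1e-10)
    s1sq = (1 - 10 / 11) * 100.0
    assert data["RU"][1] == pytest.approx(np.sqrt(s1sq) - 10.0, abs=1e-10)


def test_tab_zero_weights_are_chance():
    df = simulate_task("tab", THETA["tab"], seed=5)
    data = get_model("tab").prepare(df)
    assert np.allclose(get_model("tab").trial_probs((0.0, 0.0, 0.0), data), 0.5)


def test_tab_safe_arm_collapses_after_one_observation():
    df = _tab_df(
        [
            ("p", 1, 1, 1, 1, 500.0, 7.0, "S", "R", 7.0),
            ("p", 1, 1, 2, 1, 500.0, 7.0, "S", "R", 7.0),
        ]
    )
    data = get_model("tab").prepare(df)
    assert data["V"][1] == pytest.approx(7.0, rel=1e-5)  # m -> observed value
    assert data["RU"][1] == pytest.approx(-10.0, abs=1e-3)  # s1 ~ 0, s2 = 10


def test_tab_uncertainty_never_increases_within_block():
    df = simulate_task("tab", THETA["tab"], seed=6)
    from dynaphen.tasks.tab import _kalman_features, default_design

    d = df.sort_values(["block", "trial"])
    V, RU, sTU = _kalman_features(
        d["block"].to_numpy(int), d["arm1_label"].to_numpy(str),
        d["arm2_label"].to_numpy(str), d["response"].to_numpy(int),
        d["reward"].to_numpy(float), default_design(),
    )
    tu = np.abs(1.0 / np.where(sTU == 0, np.nan, sTU))
    for _, g in pd.DataFrame(dict(block=d["block"], tu=tu)).groupby("block"):
        vals = g["tu"].dropna().to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)


def test_tab_value_weight_uses_the_difference_only():
    # adding a constant to both arm means leaves the choice probability fixed
    base = _tab_df(
        [
            ("p", 1, 1, 1, 1, 500.0, 5.0, "R", "R", 5.0),
            ("p", 1, 1, 2, 0, 500.0, 3.0, "R", "R", 3.0),
            ("p", 1, 1, 3, 1, 500.0, 6.0, "R", "R", 6.0),
        ]
    )
    shifted = base.copy()
    shifted["reward"] += 50.0
    m = get_model("tab")
    design = m.Design(m0=0.0)
    design_shift = m.Design(m0=50.0)
    p0 = m.trial_probs(THETA["tab"], m.prepare(base, design))
    p1 = m.trial_probs(THETA["tab"], m.prepare(shifted, design_shift))
    assert np.allclose(p0, p1, atol=1e-10)


# ---------------------------------------------------------------------------
# nc


def _nc_df(a1, a2, resp=1):
    return pd.DataFrame(
        [
            dict(
                participant_id="p", week=1, block=1, trial=1, response=resp,
                rt_ms=500.0, outcome=1, a1=a1, a2=a2,
            )
        ]
    )


def test_nc_weber_formula():
    data = get_model("nc").prepare(_nc_df(20, 10))
    p = get_model("nc").trial_probs((0.2,), data)
    assert p[0] == pytest.approx(norm.cdf(10.0 / (0.2 * np.sqrt(500.0))), abs=1e-12)
    assert p[0] == pytest.approx(0.9873, abs=2e-4)


def test_nc_infinite_noise_is_chance_and_swap_symmetry():
    m = get_model("nc")
    assert m.trial_probs((1e9,), m.prepare(_nc_df(20, 10)))[0] == pytest.approx(0.5)
    p = m.trial_probs((0.25,), m.prepare(_nc_df(20, 10)))[0]
    q = m.trial_probs((0.25,), m.prepare(_nc_df(10, 20)))[0]
    assert p == pytest.approx(1 - q, abs=1e-12)


def test_nc_equal_counts_rejected():
    with pytest.raises(ValueError, match="equal"):
        get_model("nc").prepare(_nc_df(10, 10))


# ---------------------------------------------------------------------------
# shared properties


@pytest.mark.parametrize("task", list(TASK_MODELS))
def test_simulate_is_deterministic_under_seed(task):
    a = simulate_task(task, THETA[task], seed=42)
    b = simulate_task(task, THETA[task], seed=42)
    pdt.assert_frame_equal(a, b)


@pytest.mark.parametrize("task", list(TASK_MODELS))
def test_probabilities_are_proper(task):
    m = get_model(task)
    df = simulate_task(task, THETA[task], seed=8)
    p = m.trial_probs(THETA[task], m.prepare(df, m.default_design()))
    assert np.all((p >= 0) & (p <= 1))
    assert 0.0 < p.mean() < 1.0


@pytest.mark.parametrize("task", list(TASK_MODELS))
def test_likelihood_dominance_of_generating_parameters(task):
    """Average per-trial log-likelihood peaks at the generating parameters."""
    m = get_model(task)
    design = _big_design(task)
    df = simulate_task(task, THETA[task], design=design, seed=13)
    data = m.prepare(df, design)
    u = unconstrain_theta(task, np.asarray(THETA[task]))
    ll_true = m.loglik(constrain_theta(task, u), data)
    rng = np.random.default_rng(7)
    for _ in range(3):
        u_pert = u + rng.choice([-0.4, 0.4], size=len(u))
        ll_pert = m.loglik(constrain_theta(task, u_pert), data)
        assert ll_true >= ll_pert
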