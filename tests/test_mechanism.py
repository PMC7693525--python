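import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

import qpcrmiss as q

SIM_BETA = (-35.7, 1.0)


@pytest.fixture
def sim_mech():
    return q.MissingMechanism("logit", *SIM_BETA, detection_limit=40.0)


def test_sigmoid_midpoint_and_hard_limit(sim_mech):
    # the sigmoid crosses 1/2 where beta0 + beta1*x = 0
    assert sim_mech.detect_prob(35.7) == pytest.approx(0.5)
    assert sim_mech.detect_prob(40.0) == 0.0
    assert sim_mech.detect_prob(45.0) == 0.0
    # non-detect log-odds at Cq 30 is beta0 + 30*beta1 = -5.7
    assert sim_mech.nondetect_prob(30.0) == pytest.approx(1.0 / (1.0 + np.exp(5.7)), rel=1e-12)
    assert sim_mech.detect_prob(30.0) == pytest.approx(1.0 - expit(-5.7), rel=1e-12)


@given(st.floats(min_value=-50, max_value=100, allow_nan=False))
def test_detect_prob_is_a_probability_vanishing_above_limit(x):
    mech = q.MissingMechanism("logit", -35.7, 1.0, detection_limit=40.0)
    p = float(mech.detect_prob(x))
    assert 0.0 <= p <= 1.0
    if x >= 40.0:
        assert p == 0.0


@pytest.mark.parametrize("link", ["logit", "probit", "cloglog"])
def test_detect_prob_monotone_decreasing_for_positive_slope(link):
    mech = q.MissingMechanism(link, -35.7, 1.0, detection_limit=40.0)
    x = np.linspace(10, 39.9, 500)
    p = mech.detect_prob(x)
    assert np.all(np.diff(p) <= 1e-12)


def test_separation_raises_without_regularization():
    x = np.concatenate([np.linspace(20, 29.9, 50), np.linspace(30.1, 39, 50)])
    detected = x < 30  # perfectly separated
    with pytest.raises(q.SeparationError):
        q.fit_mechanism(x, detected, regularize=False)
    # one response class only
    with pytest.raises(q.SeparationError):
        q.fit_mechanism(x, np.ones_like(x, bool), regularize=False)


def test_regularized_fit_of_separated_data_is_steep_near_the_cut():
    x = np.concatenate([np.linspace(20, 29.9, 200), np.linspace(30.1, 39, 200)])
    detected = x < 30
    mech = q.fit_mechanism(x, detected, regularize=True)
    assert np.isfinite([mech.beta0, mech.beta1]).all()
    assert 29.0 < mech.crossing < 31.0
    assert mech.beta1 > 3.0  # steep rise
    assert np.all(np.linalg.eigvalsh(mech.beta_cov) >= -1e-10)


def test_parameter_recovery_on_simulated_mechanism():
    # Z drawn from the known logistic law on fully observed Cq values:
    # the pooled fit must recover (beta0, beta1) within Monte-Carlo error
    rng = np.random.default_rng(12)
    x = rng.normal(33, 3.0, 90 * 36)
    p_miss = expit(SIM_BETA[0] + SIM_BETA[1] * x)
    detected = rng.random(x.size) >= p_miss
    mech = q.fit_mechanism(x, detected, regularize=True)
    se = np.sqrt(np.diag(mech.beta_cov))
    assert abs(mech.beta0 - SIM_BETA[0]) < 3.5 * se[0]
    assert abs(mech.beta1 - SIM_BETA[1]) < 3.5 * se[1]


def test_mechanism_estimates_sharpen_with_more_genes():
    # shared-mechanism pooling: more genes -> tighter beta estimates
    def mean_abs_err(n_genes, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(33, 3.0, n_genes * 36)
        detected = rng.random(x.size) >= expit(SIM_BETA[0] + SIM_BETA[1] * x)
        m = q.fit_mechanism(x, detected)
        return abs(m.beta1 - SIM_BETA[1])

    small = np.mean([mean_abs_err(16, s) for s in range(8)])
    large = np.mean([mean_abs_err(90, s) for s in range(8)])
    assert large < small


def test_draw_mechanism_degenerate_and_moments(sim_mech):
    rng = np.random.default_rng(0)
    d = q.draw_mechanism(sim_mech, rng)  # zero covariance -> point estimate
    assert (d.beta0, d.beta1) == SIM_BETA
    cov = np.array([[4.0, -1.0], [-1.0, 0.5]])
    mech = q.MissingMechanism("logit", *SIM_BETA, beta_cov=cov)
    draws = np.array(
        [(m.beta0, m.beta1) for m in (q.draw_mechanism(mech, rng) for _ in range(10_000))]
    )
    # law of large numbers: sample mean and covariance match the target
    np.testing.assert_allclose(draws.mean(axis=0), SIM_BETA, atol=4 * 2.0 / 100)
    emp = np.cov(draws.T)
    np.testing.assert_allclose(emp, cov, rtol=0.12)
    r_emp = emp[0, 1] / np.sqrt(emp[0, 0] * emp[1, 1])
    assert r_emp == pytest.approx(-1.0 / np.sqrt(2.0), abs=0.05)
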