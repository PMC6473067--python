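"""Beta-uniform joint mixture: densities, EM updates, posteriors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointgsea import (
    MixtureParams,
    clamp_pvalues,
    e_step,
    fit_em,
    joint_density,
    m_step,
    marginal_density,
    posterior_de,
)
from jointgsea.mixture import ALPHA_MAX, read_params, write_params

from conftest import enumeration_posterior, sample_from_mixture, weighted_beta_mle


@pytest.mark.parametrize(
    "p, pi1, alpha, expected",
    [
        (0.5, 0.0, 0.5, 1.0),                      # zero mixing weight: uniform
        (1.0, 0.3, 0.5, 0.85),                     # p=1 makes p**(alpha-1) = 1
        (0.25, 0.2, 0.5, 0.2 * 0.5 * 0.25 ** -0.5 + 0.8),
    ],
)
def test_marginal_density_values(p, pi1, alpha, expected):
    assert marginal_density(p, pi1, alpha) == pytest.approx(expected, abs=1e-12)


def test_marginal_density_domain_errors():
    with pytest.raises(ValueError):
        marginal_density(0.0, 0.5, 0.5)
    with pytest.raises(ValueError):
        marginal_density(1.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        marginal_density(0.5, 0.5, 1.5)


def test_marginal_density_lower_bound(rng):
    p = rng.uniform(1e-6, 1.0, size=200)
    dens = marginal_density(p, 0.4, 0.3)
    assert np.all(dens >= 0.6 - 1e-12)


@pytest.mark.parametrize(
    "p_vec, config, alpha, expected",
    [
        ((0.5, 0.5), (0, 0), (0.3, 0.7), 1.0),     # all-null: unit density
        ((1.0, 1.0), (1, 1), (0.5, 0.5), 0.25),
        ((0.25, 0.81), (1, 0), (0.5, 0.5), 0.5 * 0.25 ** -0.5),
    ],
)
def test_joint_density_values(p_vec, config, alpha, expected):
    assert joint_density(p_vec, config, alpha) == pytest.approx(expected, abs=1e-12)


def test_e_step_uniform_prior_hand_case():
    """p=(1,1) with uniform prior weights configurations by prod(alpha)."""
    pv = clamp_pvalues(np.array([[1.0, 1.0]]))
    params = MixtureParams(np.full(4, 0.25), np.array([0.5, 0.5]))
    post = e_step(pv, params)
    np.testing.assert_allclose(post[0], [4 / 9, 2 / 9, 2 / 9, 1 / 9], atol=1e-12)


def test_e_step_point_mass_prior(rng):
    pv = clamp_pvalues(rng.uniform(size=(6, 2)))
    params = MixtureParams(np.array([1.0, 0.0, 0.0, 0.0]), np.array([0.5, 0.5]))
    post = e_step(pv, params)
    np.testing.assert_allclose(post, np.tile([1.0, 0, 0, 0], (6, 1)), atol=0)


def test_e_step_and_posterior_match_enumeration_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(1, 4))
        g = int(rng.integers(2, 21))
        pv = clamp_pvalues(rng.uniform(size=(g, n)))
        prior = rng.dirichlet(np.ones(2 ** n))
        alpha = rng.uniform(0.05, 0.95, size=n)
        params = MixtureParams(prior, alpha)
        post = e_step(pv, params)
        de = posterior_de(pv, params)
        oracle_post, oracle_de = enumeration_posterior(pv.values, prior, alpha)
        np.testing.assert_allclose(post, oracle_post, atol=1e-12)
        np.testing.assert_allclose(de.values, oracle_de, atol=1e-12)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


def test_m_step_hard_assignment_recovers_fractions():
    post = np.zeros((8, 4))
    post[np.arange(8), [0, 0, 0, 0, 1, 1, 2, 3]] = 1.0
    pv = clamp_pvalues(np.full((8, 2), 0.5))
    params = m_step(pv, post)
    np.testing.assert_allclose(params.config_prior, [0.5, 0.25, 0.125, 0.125])


def test_m_step_closed_form_alpha():
    """All weights one and every p = e**-2 gives alpha = 1/2 exactly."""
    g = 12
    post = np.zeros((g, 2))
    post[:, 1] = 1.0  # N=1, every feature fully differential
    pv = clamp_pvalues(np.full((g, 1), np.exp(-2.0)))
    params = m_step(pv, post)
    assert params.alpha[0] == pytest.approx(0.5, abs=1e-12)


def test_m_step_matches_weighted_mle_oracle(rng):
    # p-values small enough that the MLE stays inside (0,1): no clipping
    g, n = 15, 2
    pv = clamp_pvalues(rng.uniform(1e-4, 0.2, size=(g, n)))
    post = rng.dirichlet(np.ones(2 ** n), size=g)
    params = m_step(pv, post)
    prior, alpha = weighted_beta_mle(pv.values, post)
    np.testing.assert_allclose(params.config_prior, prior, atol=1e-12)
    np.testing.assert_allclose(params.alpha, alpha, atol=1e-12)


def test_clamp_pvalues_floor_and_identity():
    out = clamp_pvalues(np.array([[0.0, 0.5], [1e-12, 1.0]]))
    np.testing.assert_allclose(out.values, [[1e-10, 0.5], [1e-10, 1.0]])
    with pytest.raises(ValueError):
        clamp_pvalues(np.array([[-0.1]]))
    with pytest.raises(ValueError):
        clamp_pvalues(np.array([[1.1]]))


def test_fit_em_trace_monotone(rng):
    for _ in range(5):
        pv = sample_from_mixture(
            300, rng.dirichlet(np.ones(4)), rng.uniform(0.2, 0.8, 2), rng
        )
        params = fit_em(pv, max_iter=200)
        trace = np.asarray(params.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-8)


def test_fit_em_pure_null_gives_no_signal_component(rng):
    """On uniform p-values the fitted differential component collapses onto
    the uniform density (alpha at its ceiling): the model finds no signal."""
    pv = clamp_pvalues(rng.uniform(size=(5000, 2)))
    params = fit_em(pv)
    assert np.all(params.alpha >= 0.99)


def test_fit_em_recovers_known_parameters(rng):
    prior = np.array([0.7, 0.1, 0.08, 0.12])
    alpha = np.array([0.3, 0.4])
    pv = sample_from_mixture(10_000, prior, alpha, rng)
    params = fit_em(pv)
    np.testing.assert_allclose(params.alpha, alpha, atol=0.05)
    np.testing.assert_allclose(params.config_prior, prior, atol=0.03)


def test_posterior_monotone_in_p_when_alpha_below_one():
    """N=1 reduction: Pr(D=1|p) decreases in p for a beta-shaped alternative."""
    p = np.linspace(0.001, 1.0, 50)[:, None]
    params = MixtureParams(np.array([0.7, 0.3]), np.array([0.4]))
    post = posterior_de(clamp_pvalues(p), params)
    assert np.all(np.diff(post.values[:, 0]) < 0)


def test_posterior_all_de_point_mass(rng):
    pv = clamp_pvalues(rng.uniform(size=(5, 2)))
    params = MixtureParams(np.array([0.0, 0.0, 0.0, 1.0]), np.array([0.5, 0.5]))
    post = posterior_de(pv, params)
    np.testing.assert_allclose(post.values, 1.0)


def test_factorized_prior_posterior_depends_on_own_column(rng):
    """Independent datasets: column i of the posterior equals the
    single-dataset two-component posterior of column i."""
    pi = np.array([0.2, 0.35])
    alpha = np.array([0.3, 0.6])
    marg = [np.array([1 - pi[0], pi[0]]), np.array([1 - pi[1], pi[1]])]
    prior = np.array(
        [marg[0][k & 1] * marg[1][(k >> 1) & 1] for k in range(4)]
    )
    pv = clamp_pvalues(rng.uniform(size=(30, 2)))
    post = posterior_de(pv, MixtureParams(prior, alpha))
    for i in range(2):
        p = pv.values[:, i]
        beta = alpha[i] * p ** (alpha[i] - 1.0)
        single = pi[i] * beta / (pi[i] * beta + 1 - pi[i])
        np.testing.assert_allclose(post.values[:, i], single, atol=1e-10)


def test_dataset_cap_and_feature_warning(rng):
    with pytest.raises(ValueError, match="capped"):
        clamp_pvalues(rng.uniform(size=(5, 11)))
    with pytest.warns(UserWarning, match="unstable"):
        fit_em(clamp_pvalues(rng.uniform(size=(3, 2))), max_iter=3)


def test_params_roundtrip(tmp_path, rng):
    pv = sample_from_mixture(200, np.array([0.6, 0.15, 0.1, 0.15]),
                             np.array([0.3, 0.5]), rng)
    params = fit_em(pv, max_iter=50)
    path = tmp_path / "params.txt"
    write_params(params, path)
    loaded = read_params(path)
    np.testing.assert_allclose(loaded.config_prior, params.config_prior)
    np.testing.assert_allclose(loaded.alpha, params.alpha)
    assert loaded.n_iterations == params.n_iterations


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=8),
    st.floats(0.05, 0.95),
)
def test_e_step_rows_normalise(p_list, alpha):
    pv = clamp_pvalues(np.array(p_list)[:, None])
    params = MixtureParams(np.array([0.5, 0.5]), np.array([alpha]))
    post = e_step(pv, params)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(post >= 0)


def test_alpha_clipped_into_open_interval(rng):
    # p-values of exactly 1 drive the MLE above 1; the clip keeps it inside
    post = np.zeros((10, 2))
    post[:, 1] = 1.0
    pv = clamp_pvalues(np.ones((10, 1)))
    params = m_step(pv, post)
    assert params.alpha[0] == ALPHA_MAX
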