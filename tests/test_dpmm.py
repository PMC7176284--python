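"""Unit and property tests for the DP-GMM core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln, multigammaln
from sklearn.metrics import adjusted_rand_score

from mmsig.dpmm import (DPPrior, FitConfig, MixtureModel, compute_elbo,
                        effective_components, fit, minor_component_probability,
                        predict, stick_breaking_weights)

from conftest import model_with_weights


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def log_evidence_1d(x, m0=0.0, kappa0=1.0, dof0=3.0, invW0=2.0):
    """Closed-form normal-Wishart (d=1) marginal likelihood."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    S = ((x - xbar) ** 2).sum()
    kn, dn = kappa0 + n, dof0 + n
    invWn = invW0 + S + kappa0 * n / kn * (xbar - m0) ** 2
    return (gammaln(dn / 2) - gammaln(dof0 / 2)
            + 0.5 * dof0 * np.log(invW0) - 0.5 * dn * np.log(invWn)
            + 0.5 * np.log(kappa0 / kn) - 0.5 * n * np.log(np.pi))


def log_evidence_full(X, m0, kappa0, dof0, invW0):
    """Closed-form normal-Wishart marginal likelihood, dense covariance."""
    n, d = X.shape
    xbar = X.mean(axis=0)
    Xc = X - xbar
    S = Xc.T @ Xc
    kn, dn = kappa0 + n, dof0 + n
    invWn = invW0 + S + kappa0 * n / kn * np.outer(xbar - m0, xbar - m0)
    return (multigammaln(dn / 2, d) - multigammaln(dof0 / 2, d)
            + 0.5 * dof0 * np.linalg.slogdet(invW0)[1]
            - 0.5 * dn * np.linalg.slogdet(invWn)[1]
            + 0.5 * d * np.log(kappa0 / kn) - 0.5 * n * d * np.log(np.pi))


# ---------------------------------------------------------------------------
# stick breaking
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("nu, expected", [
    ([1.0], [1.0]),
    ([0.5, 0.5, 1.0], [0.5, 0.25, 0.25]),
    ([0.2, 0.2, 0.2, 1.0], [0.2, 0.16, 0.128, 0.512]),
])
def test_stick_breaking_examples(nu, expected):
    np.testing.assert_allclose(stick_breaking_weights(nu), expected,
                               atol=1e-12)


@pytest.mark.parametrize("nu", [[1.2, 1.0], [-0.1, 1.0], [0.5, 0.9]])
def test_stick_breaking_domain_errors(nu):
    with pytest.raises(ValueError):
        stick_breaking_weights(nu)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=0, max_size=15))
def test_stick_breaking_normalization(prefix):
    nu = prefix + [1.0]
    w = stick_breaking_weights(nu)
    assert np.all(w >= 0)
    assert abs(w.sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# evidence bound / ELBO
# ---------------------------------------------------------------------------

def test_one_component_elbo_matches_conjugate_evidence():
    rng = np.random.default_rng(0)
    x = rng.normal(1.3, 0.8, size=25)
    model = fit(x, DPPrior(k_trunc=1, m0=0.0, dof0=3.0, scale0=2.0),
                FitConfig(seed=1))
    oracle = log_evidence_1d(x)
    assert model.elbo <= oracle + 1e-9
    assert oracle - model.elbo < 1e-6     # exact in the conjugate case


def test_full_covariance_elbo_matches_conjugate_evidence():
    rng = np.random.default_rng(3)
    d = 3
    X = rng.standard_normal((40, d)) @ rng.standard_normal((d, d))
    model = fit(X, DPPrior(k_trunc=1, m0=0.0, covariance_type="full"),
                FitConfig(seed=1))
    oracle = log_evidence_full(X, np.zeros(d), 1.0, d + 2, 2.0 * np.eye(d))
    assert abs(oracle - model.elbo) < 1e-6


def test_diagonal_elbo_is_product_of_univariate_evidences():
    rng = np.random.default_rng(5)
    d = 4
    X = rng.normal(2.0, 1.5, size=(35, d))
    model = fit(X, DPPrior(k_trunc=1, m0=0.0, covariance_type="diag"),
                FitConfig(seed=2))
    oracle = sum(log_evidence_1d(X[:, j]) for j in range(d))
    assert abs(oracle - model.elbo) < 1e-6


def test_elbo_trace_monotone_and_final_at_least_initial():
    rng = np.random.default_rng(11)
    x = np.concatenate([rng.normal(-2, 1, 80), rng.normal(2, 1, 80)])
    model = fit(x, DPPrior(k_trunc=6), FitConfig(seed=4))
    trace = np.asarray(model.elbo_trace)
    assert np.all(np.diff(trace) >= -1e-9 * (1 + np.abs(trace[1:])))
    assert trace[-1] >= trace[0]


def test_compute_elbo_dimension_mismatch():
    model = fit(np.random.default_rng(0).normal(size=30),
                DPPrior(k_trunc=2), FitConfig(seed=0))
    with pytest.raises(ValueError):
        compute_elbo(model, np.zeros((10, 3)))


# ---------------------------------------------------------------------------
# fitting behavior
# ---------------------------------------------------------------------------

def test_fit_standard_normal_gives_one_effective_component():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(200)
    model = fit(x, DPPrior(k_trunc=5), FitConfig(seed=3))
    w = model.weights
    assert (w >= 0.95).sum() == 1
    assert model.effective_components(0.05) == 1


def test_fit_two_well_separated_components():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(-4, 1, 100), rng.normal(4, 1, 100)])
    truth = np.repeat([0, 1], 100)
    model = fit(x, DPPrior(k_trunc=10), FitConfig(seed=5))
    assert model.effective_components(0.01) == 2
    w = model.weights
    eff = np.flatnonzero(w >= 0.01)
    means = np.sort(model.means[eff, 0])
    np.testing.assert_allclose(means, [-4.0, 4.0], atol=0.3)
    assert adjusted_rand_score(truth, model.labels) >= 0.99


def test_fit_identical_points_single_component():
    x = np.array([3.7, 3.7])
    model = fit(x, DPPrior(k_trunc=10), FitConfig(seed=0))
    assert model.effective_components(0.05) == 1
    k = int(np.argmax(model.weights))
    assert abs(model.means[k, 0] - 3.7) < 1e-6


def test_fit_rejects_nonfinite():
    with pytest.raises(ValueError):
        fit(np.array([1.0, np.nan, 2.0]))


def test_fit_deterministic_given_seed():
    rng = np.random.default_rng(6)
    x = np.concatenate([rng.normal(-3, 1, 60), rng.normal(3, 1, 60)])
    m1 = fit(x, DPPrior(k_trunc=6), FitConfig(seed=9))
    m2 = fit(x, DPPrior(k_trunc=6), FitConfig(seed=9))
    np.testing.assert_array_equal(m1.weights, m2.weights)
    np.testing.assert_array_equal(m1.labels, m2.labels)
    assert m1.elbo == m2.elbo


def test_cross_check_against_sklearn_dpgmm():
    """Independent implementation agreement on a clean 2-mode problem."""
    from sklearn.mixture import BayesianGaussianMixture

    rng = np.random.default_rng(8)
    x = np.concatenate([rng.normal(-3, 0.7, 150), rng.normal(3, 0.7, 150)])
    ours = fit(x, DPPrior(k_trunc=8), FitConfig(seed=1))
    ref = BayesianGaussianMixture(
        n_components=8, weight_concentration_prior_type="dirichlet_process",
        random_state=0, max_iter=500).fit(x[:, None])
    ours_means = np.sort(ours.means[ours.weights >= 0.05, 0])
    ref_means = np.sort(ref.means_[ref.weights_ >= 0.05, 0])
    assert len(ours_means) == len(ref_means) == 2
    np.testing.assert_allclose(ours_means, ref_means, atol=0.2)


# ---------------------------------------------------------------------------
# component summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("weights, min_weight, expected", [
    ([0.7, 0.3], 0.1, 2),
    ([0.96, 0.04], 0.05, 1),
    ([1 / 3, 1 / 3, 1 / 3], 0.2, 3),
])
def test_effective_components(weights, min_weight, expected):
    model = model_with_weights(weights)
    assert effective_components(model, min_weight) == expected


@pytest.mark.parametrize("weights, min_weight, expected", [
    ([0.8, 0.2], 0.01, 0.2),
    ([0.42, 0.34, 0.17, 0.07], 0.1, 0.17),
    ([1.0], 0.01, 1.0),
])
def test_minor_component_probability(weights, min_weight, expected):
    model = model_with_weights(weights)
    assert abs(minor_component_probability(model, min_weight) - expected) < 1e-9


def test_minor_component_probability_no_effective_component():
    model = model_with_weights([0.4, 0.3, 0.3])
    with pytest.raises(ValueError):
        minor_component_probability(model, 0.45)
    assert minor_component_probability(model, 0.25) == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_at_component_mean_is_confident():
    rng = np.random.default_rng(10)
    x = np.concatenate([rng.normal(-6, 1, 100), rng.normal(6, 1, 100)])
    model = fit(x, DPPrior(k_trunc=6), FitConfig(seed=2))
    labels, proba = model.predict(np.array([[-6.0], [6.0]]))
    assert proba.to_numpy().max(axis=1).min() > 0.99
    assert labels[0] != labels[1]


def test_predict_symmetric_midpoint_equal_probabilities():
    model = model_with_weights([0.5, 0.5], means=[-2.0, 2.0], n_train=100)
    _, proba = model.predict(np.array([[0.0]]))
    cols = [c for c in proba.columns if c != "new"]
    assert abs(proba.iloc[0][cols[0]] - proba.iloc[0][cols[1]]) < 1e-6


def test_predict_rows_sum_to_one_and_empty_input():
    model = model_with_weights([0.6, 0.4], means=[0.0, 5.0])
    labels, proba = model.predict(np.array([[0.0], [5.0], [2.5]]))
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    labels_e, proba_e = model.predict(np.empty((0, 1)))
    assert labels_e.size == 0 and len(proba_e) == 0


def test_predict_far_sample_prefers_new_cluster():
    model = model_with_weights([0.5, 0.5], means=[0.0, 4.0])
    labels, proba = model.predict(np.array([[60.0]]))
    assert labels[0] == -1
    assert proba.iloc[0]["new"] == proba.iloc[0].max()


def test_predict_missing_features_listed():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 2))
    model = fit(X, DPPrior(k_trunc=3), FitConfig(seed=0),
                gene_ids=["TP53", "MYC"])
    bad = pd.DataFrame({"TP53": [1.0]})
    with pytest.raises(KeyError, match="MYC"):
        model.predict(bad)


def test_predict_dataframe_reorders_by_identifier():
    rng = np.random.default_rng(12)
    X = np.column_stack([rng.normal(0, 1, 80), rng.normal(10, 1, 80)])
    model = fit(X, DPPrior(k_trunc=3), FitConfig(seed=0),
                gene_ids=["a", "b"])
    df = pd.DataFrame({"b": [10.0], "a": [0.0]})
    _, proba = model.predict(df)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    assert proba.to_numpy().max() > 0.5


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_model_round_trip_reproduces_predictions_bitwise(tmp_path):
    rng = np.random.default_rng(13)
    x = np.concatenate([rng.normal(-3, 1, 70), rng.normal(3, 1, 70)])
    model = fit(x, DPPrior(k_trunc=6), FitConfig(seed=7))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = type(model).load(path)
    Xnew = rng.normal(0, 3, size=(25, 1))
    l1, p1 = model.predict(Xnew)
    l2, p2 = loaded.predict(Xnew)
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())
    np.testing.assert_array_equal(model.weights, loaded.weights)
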