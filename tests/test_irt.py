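"""Unit tests for the IRT core: response function, calibration, scoring,
information curves, fit statistics, and the scree dimensionality check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

import triadkit as tk
from oracles import grid_search_rasch_mml, rasch_marginal_loglik


# ---------------------------------------------------------------------------
# response function
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "theta,beta,expected_2dp",
    [(0.0, -2.72, 0.94), (0.0, 0.86, 0.30)],
)
def test_probability_matches_worked_examples(theta, beta, expected_2dp):
    assert round(tk.probability_correct(theta, beta), 2) == expected_2dp


@pytest.mark.parametrize("beta", [-2.72, 0.0, 0.86, 3.5])
def test_probability_half_when_ability_equals_difficulty(beta):
    assert tk.probability_correct(beta, beta) == pytest.approx(0.5, abs=1e-12)


def test_probability_lower_asymptote_is_guessing_level():
    assert tk.probability_correct(-30.0, 0.0, c=1 / 3) == pytest.approx(1 / 3, abs=1e-9)
    assert tk.probability_correct(30.0, 0.0, c=1 / 3) == pytest.approx(1.0, abs=1e-9)


@given(
    theta=st.floats(-5, 5),
    delta=st.floats(0.01, 3),
    beta=st.floats(-4, 4),
    c=st.floats(0, 0.5),
)
def test_probability_monotone_in_theta_and_beta(theta, delta, beta, c):
    lo = tk.probability_correct(theta, beta, c=c)
    hi = tk.probability_correct(theta + delta, beta, c=c)
    assert hi > lo
    harder = tk.probability_correct(theta, beta + delta, c=c)
    assert harder < lo


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), float("-inf")])
def test_probability_rejects_nonfinite_theta(bad):
    with pytest.raises(ValueError, match="finite"):
        tk.probability_correct(bad, 0.0)


def test_probability_accepts_item_parameters_record():
    item = tk.ItemParameters(item_id="x", beta=1.0, alpha=2.0, c=0.2)
    manual = 0.2 + 0.8 * expit(2.0 * (0.5 - 1.0))
    assert tk.probability_correct(0.5, item) == pytest.approx(manual, abs=1e-12)


def test_item_parameters_validation():
    with pytest.raises(ValueError, match="alpha"):
        tk.ItemParameters("x", beta=0.0, alpha=0.0)
    with pytest.raises(ValueError, match="c must"):
        tk.ItemParameters("x", beta=0.0, c=1.0)
    with pytest.raises(ValueError, match="beta"):
        tk.ItemParameters("x", beta=float("inf"))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _flat_bank(n, beta=0.0):
    return tk.ItemBank([tk.ItemParameters(f"i{j:03d}", beta=beta) for j in range(n)])


def test_em_loglik_nondecreasing():
    sim = tk.simulate_responses(tk.SimulationDesign(n_respondents=200, n_items=15, seed=4))
    bank, _, _ = tk.fit_rasch(sim.responses)
    trace = np.asarray(bank.calibration_meta["log_likelihood_trace"])
    assert np.all(np.diff(trace) >= -1e-7)


def test_fit_recovers_symmetric_null():
    """With every true difficulty 0 and 2000 respondents, estimates sit
    within sampling error of 0 (per-item SE is ~0.045 at p=0.5, plus a
    common shift from the sample ability mean; 0.15 is ~3.3 SDs)."""
    design = tk.SimulationDesign(
        n_respondents=2000, n_items=20, item_bank=_flat_bank(20), seed=9
    )
    sim = tk.simulate_responses(design)
    bank, abilities, stats = tk.fit_rasch(sim.responses)
    assert np.all(np.abs(bank.betas) < 0.15)
    assert abs(bank.betas.mean()) < 0.08
    # scale identification: average posterior-mean ability pinned near 0
    assert abs(abilities.theta.mean()) < 0.05
    assert stats.converged


def test_fit_matches_grid_search_oracle():
    sim = tk.simulate_responses(
        tk.SimulationDesign(n_respondents=50, n_items=3,
                            difficulty_low=-1.5, difficulty_high=1.5, seed=17)
    )
    X = sim.responses.values
    bank, _, stats = tk.fit_rasch(sim.responses, tk.CalibrationConfig(tol=1e-6))
    oracle_betas, oracle_ll = grid_search_rasch_mml(X)
    assert np.max(np.abs(bank.betas - oracle_betas)) < 1e-3
    assert stats.log_likelihood == pytest.approx(oracle_ll, abs=1e-4)
    # the oracle's own likelihood at the EM solution agrees too
    assert rasch_marginal_loglik(X, bank.betas) == pytest.approx(
        stats.log_likelihood, abs=1e-6
    )


def test_degenerate_item_clamped_with_warning():
    rng = np.random.default_rng(0)
    X = (rng.random((40, 5)) < 0.6).astype(float)
    X[:, 2] = 1.0  # answered correctly by everyone
    rm = tk.ResponseMatrix.from_arrays(X)
    with pytest.warns(RuntimeWarning, match="no observed variation"):
        bank, _, _ = tk.fit_rasch(rm)
    assert bank.betas[2] == -6.0
    assert bank.calibration_meta["degenerate_items"] == [rm.item_ids[2]]


def test_fit_input_validation():
    with pytest.raises(ValueError, match=">= 2 items"):
        tk.fit_rasch(tk.ResponseMatrix.from_arrays(np.ones((5, 1))))
    X = np.ones((4, 3))
    X[:, 1] = np.nan
    with pytest.raises(ValueError, match="no observed response"):
        tk.fit_rasch(tk.ResponseMatrix.from_arrays(X))


def test_response_matrix_validation():
    with pytest.raises(ValueError, match="must be 0, 1 or missing"):
        tk.ResponseMatrix.from_arrays(np.array([[1.0, 2.0], [0.0, 1.0]]))
    frame = pd.DataFrame([[1.0, 0.0]], index=["r1"], columns=["a", "a"])
    with pytest.raises(ValueError, match="duplicate item ids"):
        tk.ResponseMatrix(frame)


# ---------------------------------------------------------------------------
# scoring with a fixed bank
# ---------------------------------------------------------------------------


def test_scoring_self_consistency():
    sim = tk.simulate_responses(tk.SimulationDesign(n_respondents=80, n_items=12, seed=5))
    bank, fit_abilities, _ = tk.fit_rasch(sim.responses)
    rescored = tk.score_with_fixed_items(sim.responses, bank)
    np.testing.assert_allclose(rescored.theta, fit_abilities.theta, atol=1e-6)
    np.testing.assert_allclose(rescored.se, fit_abilities.se, atol=1e-6)


def test_all_correct_pattern_finite_with_larger_se():
    bank = _flat_bank(10)
    X = np.vstack([np.ones(10), np.tile([1.0, 0.0], 5)])
    rm = tk.ResponseMatrix.from_arrays(
        X, respondent_ids=["perfect", "mixed"], item_ids=bank.item_ids
    )
    est = tk.score_with_fixed_items(rm, bank)
    assert np.all(np.isfinite(est.theta))
    frame = est.frame
    assert frame.loc["perfect", "se"] > frame.loc["mixed", "se"]
    assert frame.loc["perfect", "theta"] > frame.loc["mixed", "theta"]


def test_scoring_errors_name_the_culprit():
    bank = _flat_bank(3)
    rm = tk.ResponseMatrix.from_arrays(np.ones((2, 2)), item_ids=["i000", "mystery"])
    with pytest.raises(KeyError, match="mystery"):
        tk.score_with_fixed_items(rm, bank)
    X = np.array([[1.0, 0.0], [np.nan, np.nan]])
    rm2 = tk.ResponseMatrix.from_arrays(
        X, respondent_ids=["ok", "ghost"], item_ids=["i000", "i001"]
    )
    with pytest.raises(ValueError, match="ghost"):
        tk.score_with_fixed_items(rm2, bank)


# ---------------------------------------------------------------------------
# information / SE curves
# ---------------------------------------------------------------------------


def test_single_item_information_peak():
    bank = tk.ItemBank([tk.ItemParameters("i", beta=0.7)])
    curve = tk.test_information(bank, np.array([-1.0, 0.7, 2.0]))
    assert curve.information[1] == pytest.approx(0.25, abs=1e-12)
    assert curve.se[1] == pytest.approx(2.0, abs=1e-9)
    assert curve.peak_theta == 0.7


def test_information_is_additive_over_items(rng):
    grid = np.linspace(-4, 4, 41)
    i1 = tk.ItemParameters("a", beta=-0.5)
    i2 = tk.ItemParameters("b", beta=1.2, alpha=1.7, c=0.2)
    both = tk.test_information(tk.ItemBank([i1, i2]), grid)
    single = [tk.test_information(tk.ItemBank([i]), grid) for i in (i1, i2)]
    np.testing.assert_allclose(
        both.information, single[0].information + single[1].information, rtol=1e-12
    )


def test_information_argmax_matches_dense_oracle(study_calibration):
    _, bank, _, _ = study_calibration
    coarse = np.linspace(-4, 4, 81)
    curve = tk.test_information(bank, coarse)
    fine = np.linspace(-4, 4, 801)
    # direct evaluation from the model definition
    P = expit(fine[:, None] - bank.betas[None, :])
    fine_info = (P * (1 - P)).sum(axis=1)
    assert abs(curve.peak_theta - fine[np.argmax(fine_info)]) <= (coarse[1] - coarse[0])


def test_se_is_reciprocal_root_information(rng):
    betas = rng.uniform(-3, 3, size=30)
    bank = tk.ItemBank([tk.ItemParameters(f"i{j}", beta=b) for j, b in enumerate(betas)])
    curve = tk.test_information(bank, np.linspace(-5, 5, 101))
    mask = curve.information > 0
    np.testing.assert_allclose(curve.se[mask], 1.0 / np.sqrt(curve.information[mask]),
                               rtol=1e-12)


def test_information_input_validation():
    bank = _flat_bank(2)
    with pytest.raises(ValueError, match="empty"):
        tk.test_information(tk.ItemBank([]), np.array([0.0]))
    with pytest.raises(ValueError, match="strictly increasing"):
        tk.test_information(bank, np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def test_information_criteria_definitions():
    sim = tk.simulate_responses(tk.SimulationDesign(n_respondents=150, n_items=8, seed=2))
    bank, _, _ = tk.fit_rasch(sim.responses)
    stats = tk.fit_statistics(sim.responses, bank)
    m, n = 8, 150
    assert stats.aic == pytest.approx(-2 * stats.log_likelihood + 2 * m, abs=1e-9)
    assert stats.bic == pytest.approx(
        -2 * stats.log_likelihood + m * np.log(n), abs=1e-9
    )
    assert stats.aic - stats.bic == pytest.approx(m * (2 - np.log(n)), abs=1e-9)


def test_rmsea_small_for_well_specified_model():
    sim = tk.simulate_responses(
        tk.SimulationDesign(n_respondents=1000, n_items=15, seed=13)
    )
    bank, _, _ = tk.fit_rasch(sim.responses)
    stats = tk.fit_statistics(sim.responses, bank)
    assert stats.rmsea is not None
    assert stats.rmsea <= 0.06
    assert stats.rmsea_df == 15 + 15 * 14 // 2 - 15


def test_rmsea_skipped_for_missing_data_or_large_banks():
    sim = tk.simulate_responses(tk.SimulationDesign(n_respondents=60, n_items=10, seed=1))
    X = sim.responses.values.copy()
    X[0, 0] = np.nan
    holey = tk.ResponseMatrix.from_arrays(
        X, sim.responses.respondent_ids, sim.responses.item_ids
    )
    bank, _, _ = tk.fit_rasch(sim.responses)
    stats = tk.fit_statistics(holey, bank)
    assert stats.rmsea is None and "missing" in stats.rmsea_note
    stats2 = tk.fit_statistics(sim.responses, bank, rmsea_max_items=5)
    assert stats2.rmsea is None and "rmsea_max_items" in stats2.rmsea_note


# ---------------------------------------------------------------------------
# dimensionality
# ---------------------------------------------------------------------------


def test_scree_unidimensional_for_single_trait_data():
    sim = tk.simulate_responses(tk.SimulationDesign(n_respondents=600, n_items=60, seed=33))
    result = tk.dimensionality_scree(sim.responses)
    assert result.unidimensional
    assert result.first_second_ratio > 3


def test_scree_rejects_two_independent_blocks(rng):
    n, half = 600, 20
    betas = rng.uniform(-1.5, 1.5, size=2 * half)
    th = rng.normal(size=(n, 2))
    X = np.empty((n, 2 * half))
    X[:, :half] = rng.random((n, half)) < expit(th[:, :1] - betas[None, :half])
    X[:, half:] = rng.random((n, half)) < expit(th[:, 1:] - betas[None, half:])
    result = tk.dimensionality_scree(tk.ResponseMatrix.from_arrays(X))
    assert not result.unidimensional


def test_scree_independent_items_have_flat_spectrum(rng):
    X = (rng.random((4000, 3)) < 0.5).astype(float)
    result = tk.dimensionality_scree(tk.ResponseMatrix.from_arrays(X))
    np.testing.assert_allclose(result.eigenvalues, 1.0, atol=0.1)


def test_scree_excludes_zero_variance_items(rng):
    X = (rng.random((200, 4)) < 0.5).astype(float)
    X[:, 3] = 1.0
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        result = tk.dimensionality_scree(tk.ResponseMatrix.from_arrays(X))
    assert len(result.eigenvalues) == 3
    assert len(result.excluded_items) == 1
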