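"""Conditional-ML Rasch estimation against closed-form and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from starmh import RaschModel, SimulationConfig, simulate_cohort
from starmh.exceptions import InestimableItemError
from starmh.rasch import conditional_pattern_logprob, log_esf, log_esf_without

TABLE_DIFFICULTIES = [0.06, 0.06, 0.40, -0.27, -0.13, -0.22, 0.11]


def brute_force_log_esf(eps):
    """gamma_r by explicit enumeration of all subsets."""
    m = len(eps)
    gamma = np.zeros(m + 1)
    for pattern in itertools.product([0, 1], repeat=m):
        r = sum(pattern)
        gamma[r] += np.prod([e for e, x in zip(eps, pattern) if x] or [1.0])
    return np.log(gamma)


@pytest.mark.parametrize("m", [2, 3, 5, 8, 10])
def test_esf_recursion_matches_pattern_enumeration(m, rng):
    beta = rng.normal(0, 1.2, size=m)
    expected = brute_force_log_esf(np.exp(-beta))
    np.testing.assert_allclose(log_esf(-beta), expected, rtol=1e-10)
    # partial ESFs agree with enumeration on the reduced item set
    skip = int(rng.integers(m))
    reduced = np.delete(np.exp(-beta), skip)
    np.testing.assert_allclose(
        log_esf_without(-beta, skip), brute_force_log_esf(reduced), rtol=1e-10)


def test_conditional_likelihood_matches_enumeration(rng):
    """Model log-likelihood equals the brute-force conditional probability of
    the data given the raw-score margins."""
    m, n = 4, 40
    beta = rng.normal(0, 1, size=m)
    X = (rng.random((n, m)) < 0.5).astype(int)
    X = X[(X.sum(1) > 0) & (X.sum(1) < m)]
    model = RaschModel(X)
    ll_brute = sum(conditional_pattern_logprob(row, beta) for row in model.X)
    assert np.isclose(model.loglike(beta), ll_brute, rtol=1e-10)


def _two_item_data(n10, n01, n_pad=4):
    """Persons with discordant patterns (1,0) x n10 and (0,1) x n01, plus
    concordant padding (which carries no conditional information)."""
    rows = [[1, 0]] * n10 + [[0, 1]] * n01 + [[1, 1], [0, 0]] * n_pad
    return np.array(rows)


def test_two_item_closed_form():
    # discordant counts 9:3 -> difficulty difference ln 3, sum-zero split
    fit = RaschModel(_two_item_data(9, 3)).fit()
    np.testing.assert_allclose(
        fit.params.to_numpy(), [-np.log(3) / 2, np.log(3) / 2], atol=1e-8)
    # balanced discordance -> both difficulties zero
    fit0 = RaschModel(_two_item_data(6, 6)).fit()
    np.testing.assert_allclose(fit0.params.to_numpy(), [0.0, 0.0], atol=1e-10)


def test_sum_zero_and_margin_reproduction(default_cohort):
    cohort, truth = default_cohort
    items = list(truth["difficulties"])
    model = RaschModel(cohort.responses[items])
    fit = model.fit()
    assert abs(fit.params.sum()) < 1e-8
    # conditional probabilities reproduce the observed item margins at the
    # CML solution (zero-gradient condition) ...
    pi = model._pi_matrix(fit.params.to_numpy())
    nr = model.score_counts[1:model.m]
    np.testing.assert_allclose(nr @ pi, model.item_margins, atol=1e-6)
    # ... and the ability-based expected matrix reproduces each person's raw
    # score (the ML-ability defining equation)
    E = fit.expected()
    raw = model.raw_scores[model._nonextreme]
    np.testing.assert_allclose(E.sum(axis=1), raw, atol=1e-8)


def test_inestimable_item_named():
    X = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 1, 0]])
    with pytest.raises(InestimableItemError, match="item_3"):
        RaschModel(X).fit()


def test_difficulty_recovery_large_n(large_cohort):
    cohort, truth = large_cohort
    items = list(truth["difficulties"])
    fit = RaschModel(cohort.responses[items]).fit()
    true = np.array([truth["difficulties"][i] for i in items])
    rmse = float(np.sqrt(np.mean((fit.params.to_numpy() - (true - true.mean())) ** 2)))
    assert rmse < 0.15
    assert np.corrcoef(fit.params.to_numpy(), true)[0, 1] > 0.9


def test_location_invariance_of_difficulties():
    """Shifting every ability by a constant leaves CML difficulties alone."""
    base = SimulationConfig(n_persons=3000, seed=3)
    shifted = SimulationConfig(
        n_persons=3000, seed=3,
        trait_mean_noncase=base.trait_mean_noncase + 0.7,
        trait_mean_case=base.trait_mean_case + 0.7,
    )
    items = list(base.difficulties)
    fits = []
    for cfg in (base, shifted):
        cohort, _ = simulate_cohort(cfg)
        fits.append(RaschModel(cohort.responses[items]).fit().params.to_numpy())
    np.testing.assert_allclose(fits[0], fits[1], atol=0.15)


def test_abilities_symmetry_and_monotonicity():
    X = _symmetric_dataset()
    fit = RaschModel(X).fit()
    tbl = fit.theta_by_score
    m = X.shape[1]
    # symmetric difficulties: ability at raw m/2 is zero
    assert abs(tbl.loc[m // 2, "theta"]) < 1e-8
    assert np.all(np.diff(tbl["theta"]) > 0)


def _symmetric_dataset(seed=5, n=300):
    rng = np.random.default_rng(seed)
    beta = np.array([-1.0, -0.3, 0.3, 1.0])
    theta = rng.normal(0, 1, n)
    X = (rng.random((n, 4)) < 1 / (1 + np.exp(-(theta[:, None] - beta)))).astype(int)
    # symmetrise by stacking the complement (flips item margins)
    return np.vstack([X, 1 - X[:, ::-1]])


def test_ability_closed_form_equal_difficulties():
    # all difficulties 0: raw score 5 of 7 -> theta = ln(5/2)
    rng = np.random.default_rng(0)
    X = (rng.random((400, 7)) < 0.5).astype(int)
    fit = RaschModel(X).fit()
    beta = fit.params.to_numpy()
    # force the exactly-zero difficulty vector through the ability solver
    from starmh.rasch import _solve_theta
    assert np.isclose(_solve_theta(np.zeros(7), 5), np.log(5 / 2), atol=1e-8)
    assert np.allclose(beta, np.zeros(7), atol=0.35)  # sanity: near-zero estimates


def test_item_fit_flags_miscoded_item(large_cohort):
    cohort, truth = large_cohort
    items = list(truth["difficulties"])
    M = cohort.responses[items].copy()
    M[items[2]] = 1.0 - M[items[2]]  # invert one item
    fit = RaschModel(M).fit()
    report = fit.item_fit()
    assert report.loc[items[2], "outfit_msq"] > 1.40
    assert bool(report.loc[items[2], "misfit"])


def test_item_fit_calibration_under_model():
    """Data generated from the fitted model keep nearly all items inside the
    conventional (0.60, 1.40) mean-square band."""
    rng = np.random.default_rng(42)
    beta = np.array(TABLE_DIFFICULTIES)
    beta = beta - beta.mean()
    inside = total = 0
    for _ in range(30):
        theta = rng.normal(-1.4, 1.55, 400)
        X = (rng.random((400, 7)) < 1 / (1 + np.exp(-(theta[:, None] - beta)))).astype(int)
        rep = RaschModel(X).fit().item_fit()
        inside += int(((rep["infit_msq"] > 0.60) & (rep["infit_msq"] < 1.40)
                       & (rep["outfit_msq"] > 0.60) & (rep["outfit_msq"] < 1.40)).sum())
        total += 7
    assert inside / total >= 0.95


def test_reliability_components(default_cohort):
    cohort, truth = default_cohort
    items = list(truth["difficulties"])
    fit = RaschModel(cohort.responses[items]).fit()
    rel = fit.reliability(cohort.responses[items])
    assert 0.0 <= rel.psi <= 1.0
    assert -1.0 <= rel.mean_interitem_r <= 1.0
    # duplicated columns correlate perfectly
    dup = cohort.responses[items].copy()
    dup["copy"] = dup[items[0]]
    corr = dup.corr()
    assert np.isclose(corr.loc[items[0], "copy"], 1.0)


def test_independent_items_have_near_zero_mean_r(rng):
    coins = pd.DataFrame(rng.integers(0, 2, size=(1000, 5)).astype(float))
    corr = coins.corr().to_numpy()
    mean_r = corr[np.triu_indices(5, 1)].mean()
    assert abs(mean_r) < 0.05


def test_summary_prints_table(default_cohort):
    cohort, truth = default_cohort
    fit = RaschModel(cohort.responses[list(truth["difficulties"])]).fit()
    text = fit.summary()
    assert "difficulty" in text and "restless" in text
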