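"""Fixed-margin sampling, T1 local dependence and parallel analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from starmh import (
    MarginFixedSampler,
    RaschModel,
    SimulationConfig,
    modified_parallel_analysis,
    ponocny_t1,
    sample_fixed_margins,
    simulate_cohort,
)
from starmh.structure import bvn_cdf, tetrachoric_from_counts


@pytest.mark.parametrize("rho", [-0.8, -0.3, 0.0, 0.4, 0.9])
def test_bvn_cdf_matches_scipy(rho):
    grid = [-1.7, -0.5, 0.0, 0.8, 2.1]
    cov = [[1.0, rho], [rho, 1.0]]
    for h, k in itertools.product(grid, repeat=2):
        ref = multivariate_normal(mean=[0, 0], cov=cov).cdf([h, k])
        assert abs(bvn_cdf(h, k, rho) - ref) < 5e-7


def test_tetrachoric_recovers_latent_correlation(rng):
    n = 60000
    for rho, tau1, tau2 in [(0.5, 0.4, -0.3), (-0.4, 0.0, 0.5), (0.0, 0.6, 0.6)]:
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        x = (z[:, 0] > tau1).astype(int)
        y = (z[:, 1] > tau2).astype(int)
        n11 = int(np.sum((x == 1) & (y == 1)))
        n10 = int(np.sum((x == 1) & (y == 0)))
        n01 = int(np.sum((x == 0) & (y == 1)))
        n00 = int(np.sum((x == 0) & (y == 0)))
        est = tetrachoric_from_counts(n11, n10, n01, n00)
        assert abs(est - rho) < 0.03


def test_tetrachoric_zero_cell_continuity():
    # a zero cell must not crash nor return exactly +/-1 spuriously
    est = tetrachoric_from_counts(20, 0, 10, 30)
    assert -1.0 < est <= 1.0


def test_sampler_preserves_margins(default_cohort):
    cohort, truth = default_cohort
    X = cohort.responses[list(truth["difficulties"])].dropna().to_numpy(dtype=int)
    sampler = MarginFixedSampler(seed=1, burn_in=50, thin=2, n_samples=20)
    for sim in sample_fixed_margins(X, sampler):
        np.testing.assert_array_equal(sim.sum(axis=0), X.sum(axis=0))
        np.testing.assert_array_equal(sim.sum(axis=1), X.sum(axis=1))


def test_sampler_two_by_two_reference_set():
    X = np.array([[1, 0], [0, 1]])
    seen = set()
    for sim in sample_fixed_margins(X, MarginFixedSampler(seed=0, burn_in=5, thin=1,
                                                          n_samples=200)):
        seen.add(tuple(sim.ravel()))
    assert seen == {(1, 0, 0, 1), (0, 1, 1, 0)}


def _enumerate_reference_set(X):
    """All 0/1 matrices with the margins of X (small instances only)."""
    n, m = X.shape
    col_sums = X.sum(axis=0)
    row_sums = X.sum(axis=1)
    out = []

    def rec(i, cols_left, rows):
        if i == n:
            if all(c == 0 for c in cols_left):
                out.append(tuple(itertools.chain.from_iterable(rows)))
            return
        for ones in itertools.combinations(range(m), int(row_sums[i])):
            if all(cols_left[j] > 0 for j in ones):
                nxt = list(cols_left)
                for j in ones:
                    nxt[j] -= 1
                rec(i + 1, nxt, rows + [[1 if j in ones else 0 for j in range(m)]])

    rec(0, list(col_sums), [])
    return out


def test_sampler_uniform_over_enumerable_reference_set(rng):
    X = (rng.random((6, 4)) < 0.45).astype(int)
    ref = _enumerate_reference_set(X)
    assert len(ref) > 1
    counts = {r: 0 for r in ref}
    sampler = MarginFixedSampler(seed=9, burn_in=200, thin=4, n_samples=4000)
    for sim in sample_fixed_margins(X, sampler):
        counts[tuple(sim.ravel())] += 1
    observed = np.array(list(counts.values()))
    expected = observed.sum() / len(ref)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = stats.chi2.sf(chi2, len(ref) - 1)
    assert p > 0.01


def test_t1_pair_count_and_duplicate_detection(default_cohort):
    cohort, truth = default_cohort
    items = list(truth["difficulties"])
    M = cohort.responses[items].dropna()
    sampler = MarginFixedSampler(seed=2, burn_in=100, thin=2, n_samples=100)
    out = ponocny_t1(M, sampler)
    assert len(out) == 21  # C(7, 2)
    # duplicating an item makes that pair maximally concordant
    dup = M[items[:3]].copy()
    dup["dup"] = dup[items[0]]
    out2 = ponocny_t1(dup, MarginFixedSampler(seed=3, burn_in=100, thin=2,
                                              n_samples=150))
    row = out2[(out2["item_i"] == items[0]) & (out2["item_j"] == "dup")].iloc[0]
    assert row["statistic"] == len(dup)
    assert row["p_value"] == min(out2["p_value"])
    assert bool(row["locally_dependent"])


def test_t1_invariant_to_person_reordering(default_cohort):
    cohort, truth = default_cohort
    items = list(truth["difficulties"])[:4]
    M = cohort.responses[items].dropna()
    sampler = MarginFixedSampler(seed=4, burn_in=100, thin=2, n_samples=100)
    a = ponocny_t1(M, sampler)
    b = ponocny_t1(M.sample(frac=1.0, random_state=0), sampler)
    pd.testing.assert_frame_equal(a, b)


def test_parallel_analysis_deterministic_and_bounded(default_cohort):
    cohort, truth = default_cohort
    items = list(truth["difficulties"])
    M = cohort.responses[items]
    fit = RaschModel(M).fit()
    a = modified_parallel_analysis(M, fit, n_mc=100, seed=5)
    b = modified_parallel_analysis(M, fit, n_mc=100, seed=5)
    assert a.p_value == b.p_value
    assert 0.0 < a.p_value <= 1.0
    assert a.observed_second_eigenvalue > 0


def test_parallel_analysis_detects_two_factors():
    """Items split over two weakly correlated traits push the second
    eigenvalue above its unidimensional null."""
    rejections = 0
    reps = 12
    for s in range(reps):
        cfg = SimulationConfig(
            n_persons=800, seed=100 + s,
            second_factor=__import__("starmh").SecondFactor(
                items=("restless", "interest", "crazy"), loading=1.0,
                correlation=0.2),
        )
        cohort, truth = simulate_cohort(cfg)
        M = cohort.responses[list(truth["difficulties"])]
        fit = RaschModel(M).fit()
        pa = modified_parallel_analysis(M, fit, n_mc=100, seed=s)
        rejections += pa.p_value < 0.05
    assert rejections >= 0.8 * reps
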