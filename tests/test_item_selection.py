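"""Item-selection cascade: diagnostic filters, CART, endorsement specificity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starmh import (
    SimulationConfig,
    cart_select,
    endorsement_specificity_flag,
    item_diagnostic_filter,
    simulate_cohort,
    spearman_accuracy_filter,
)
from starmh.exceptions import DegenerateInputError
from starmh.item_selection import cohen_kappa


def test_perfect_item_retained():
    y = pd.Series([1, 1, 1, 0, 0, 0, 1, 0, 1, 0] * 4)
    M = pd.DataFrame({"perfect": y.astype(float)})
    rec = item_diagnostic_filter(M, y)[0]
    assert rec.sensitivity == 1.0 and rec.specificity == 1.0
    assert rec.kappa == pytest.approx(1.0)
    assert rec.spearman_rho == pytest.approx(1.0)
    assert rec.retained


def test_two_by_two_arithmetic():
    # TP=8 FN=2 FP=3 TN=7
    item = pd.Series([1] * 8 + [0] * 2 + [1] * 3 + [0] * 7, dtype=float)
    y = pd.Series([1] * 10 + [0] * 10)
    rec = item_diagnostic_filter(item.to_frame("i"), y, sn_min=0, sp_min=0)[0]
    assert rec.sensitivity == pytest.approx(0.80)
    assert rec.specificity == pytest.approx(0.70)
    assert rec.predictive_accuracy == pytest.approx(0.75)


def test_single_class_caseness_rejected():
    M = pd.DataFrame({"i": [0.0, 1.0, 0.0]})
    with pytest.raises(DegenerateInputError):
        item_diagnostic_filter(M, pd.Series([1, 1, 1]))


def test_independent_item_type_one_rate(rng):
    """An item independent of caseness passes the kappa gate at about the
    nominal rate."""
    n, reps, alpha = 500, 400, 0.05
    kept = 0
    for _ in range(reps):
        y = pd.Series(rng.integers(0, 2, n))
        M = pd.DataFrame({"i": rng.integers(0, 2, n).astype(float)})
        rec = item_diagnostic_filter(M, y, sn_min=0.0, sp_min=0.0, alpha=alpha)[0]
        kept += rec.retained
    assert kept / reps <= alpha * 1.8  # one-sided gate, generous MC slack


def test_spearman_equals_phi_for_binary_pairs(rng):
    """For two binary vectors the Spearman correlation equals Pearson's phi;
    the rank computation is the independent oracle."""
    for _ in range(100):
        x = rng.integers(0, 2, 60)
        y = rng.integers(0, 2, 60)
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            continue
        rho = stats.spearmanr(x, y).statistic
        phi = np.corrcoef(x, y)[0, 1]
        assert rho == pytest.approx(phi, abs=1e-12)


def test_spearman_accuracy_filter_thresholds():
    # TP=8 FN=2 FP=3 TN=7: significant kappa, accuracy 0.75
    base = item_diagnostic_filter(
        pd.DataFrame({"i": [1.0] * 8 + [0.0] * 2 + [1.0] * 3 + [0.0] * 7}),
        pd.Series([1] * 10 + [0] * 10), sn_min=0, sp_min=0)
    assert base[0].retained  # passes the diagnostic stage
    # accuracy 0.75 -> dropped at acc_min 0.85
    out = spearman_accuracy_filter(base, rho_min=0.0, acc_min=0.85)
    assert not out[0].retained and out[0].stage_dropped == "spearman_accuracy_filter"
    keep = spearman_accuracy_filter(base, rho_min=-1.0, acc_min=0.0)
    assert keep[0].retained == base[0].retained


def test_cart_root_split_is_predictive_item(rng):
    n = 300
    y = pd.Series(rng.integers(0, 2, n))
    M = pd.DataFrame({
        "noise1": rng.integers(0, 2, n).astype(float),
        "signal": y.astype(float),
        "noise2": rng.integers(0, 2, n).astype(float),
    })
    sel = cart_select(M, y)
    assert sel.retained_items == ["signal"]
    assert "signal" in sel.tree_text.splitlines()[0]


def test_cart_xor_interaction_found(rng):
    """Two items jointly (not marginally) predictive both become splits."""
    n = 400
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    y = pd.Series(a ^ b)
    M = pd.DataFrame({"a": a.astype(float), "b": b.astype(float)})
    sel = cart_select(M, y, max_depth=3)
    assert set(sel.retained_items) == {"a", "b"}


def test_cart_depth_zero_and_constant_outcome(rng):
    M = pd.DataFrame({"a": [0.0, 1.0] * 5, "b": [1.0, 0.0] * 5})
    assert cart_select(M, pd.Series([0, 1] * 5), max_depth=0).retained_items == []
    with pytest.raises(DegenerateInputError):
        cart_select(M, pd.Series([1] * 10))


def test_cart_invariant_to_person_shuffling(default_cohort):
    cohort, truth = default_cohort
    items = list(truth["difficulties"])
    M = cohort.responses[items].dropna()
    y = cohort.caseness.loc[M.index].astype(int)
    sel = cart_select(M, y)
    perm = M.sample(frac=1.0, random_state=3)
    sel2 = cart_select(perm, y.loc[perm.index])
    assert sel.retained_items == sel2.retained_items


def test_endorsement_specificity_flagging():
    rng = np.random.default_rng(8)
    n = 400
    rest = rng.integers(0, 2, size=(n, 3)).astype(float)
    # "leaky" item endorsed by ~35% even when everything else is 0
    leaky = (rng.random(n) < 0.35).astype(float)
    never = np.zeros(n)
    never[rest.sum(axis=1) > 0] = rng.integers(0, 2, int((rest.sum(axis=1) > 0).sum()))
    M = pd.DataFrame(np.column_stack([rest, leaky, never]),
                     columns=["r1", "r2", "r3", "leaky", "quiet"])
    flagged, curves = endorsement_specificity_flag(M, threshold=0.30)
    assert "leaky" in flagged and "quiet" not in flagged
    assert ((curves["p_rest"].dropna() >= 0) & (curves["p_rest"].dropna() <= 1)).all()
    # curves cover rest-scores 0..m-1 for every item
    assert set(curves["score"]) == {0, 1, 2, 3, 4}


def test_easy_item_flagged_hard_item_not():
    """Under the Rasch generator only a very easy item is endorsed at
    rest-score zero with non-trivial probability."""
    cfg = SimulationConfig(
        n_persons=5000, seed=21,
        difficulties={"easy": -2.0, "hard": 2.0, "m1": 0.0, "m2": 0.0, "m3": 0.0},
    )
    cohort, _ = simulate_cohort(cfg)
    M = cohort.responses[["easy", "hard", "m1", "m2", "m3"]]
    flagged, curves = endorsement_specificity_flag(M, threshold=0.30)
    assert "hard" not in flagged
    p0 = curves.set_index(["item", "score"])["p_rest"]
    assert p0.loc[("easy", 0)] > p0.loc[("hard", 0)]


def test_joint_filter_order_stability(default_cohort):
    """Applying the two filter stages sequentially equals evaluating the
    conjunction of their predicates."""
    cohort, truth = default_cohort
    items = list(truth["difficulties"])
    M = cohort.responses[items].dropna()
    y = cohort.caseness.loc[M.index].astype(int)
    recs = item_diagnostic_filter(M, y, sn_min=0.3, sp_min=0.3, alpha=0.05)
    seq = spearman_accuracy_filter(recs, rho_min=0.2, acc_min=0.5)
    for r0, r1 in zip(recs, seq):
        joint = (r0.retained and r0.spearman_rho >= 0.2
                 and r0.predictive_accuracy >= 0.5)
        assert r1.retained == joint


def test_kappa_zero_under_independence():
    # kappa of a table with independent margins is ~0
    kappa, z = cohen_kappa(25, 25, 25, 25)
    assert kappa == pytest.approx(0.0, abs=1e-12)
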