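"""Derivation cascade reducing a pooled item bank to a short screening scale.

Stages, applied to dichotomised items against interview caseness:

1. per-item 2x2 diagnostics — sensitivity/specificity thresholds plus a
   significant Cohen's kappa (asymptotic z-test of kappa > 0);
2. Spearman-correlation and predictive-accuracy thresholds;
3. a classification tree (CART, Gini impurity) whose split variables form the
   retained set;
4. an endorsement-specificity check flagging items still endorsed by persons
   who endorse nothing else (low-specificity items such as sleep trouble).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier, export_text

from .exceptions import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass
class ItemDiagnosticRecord:
    item_id: str
    sensitivity: float
    specificity: float
    kappa: float
    kappa_z: float
    chi2_p: float
    spearman_rho: float
    predictive_accuracy: float
    retained: bool
    stage_dropped: str | None


def _two_by_two(item: np.ndarray, caseness: np.ndarray):
    tp = int(np.sum((item == 1) & (caseness == 1)))
    fn = int(np.sum((item == 0) & (caseness == 1)))
    fp = int(np.sum((item == 1) & (caseness == 0)))
    tn = int(np.sum((item == 0) & (caseness == 0)))
    return tp, fn, fp, tn


def cohen_kappa(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """Kappa and its z statistic under H0 of chance agreement (Fleiss's
    asymptotic SE, no continuity correction)."""
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    p_yes_item = (tp + fp) / n
    p_yes_case = (tp + fn) / n
    pe = p_yes_item * p_yes_case + (1 - p_yes_item) * (1 - p_yes_case)
    if pe == 1.0:
        return 0.0, 0.0
    kappa = (po - pe) / (1 - pe)
    # H0 variance (Fleiss, Cohen): sum over categories of p_i+ p_+i terms
    pr = [p_yes_item, 1 - p_yes_item]
    pc = [p_yes_case, 1 - p_yes_case]
    term = sum(r * c * (r + c) ** 2 for r, c in zip(pr, pc))
    var0 = (pe + pe**2 - term) / (n * (1 - pe) ** 2)
    z = kappa / np.sqrt(var0) if var0 > 0 else 0.0
    return float(kappa), float(z)


def item_diagnostic_filter(
    matrix: pd.DataFrame,
    caseness: pd.Series,
    sn_min: float = 0.85,
    sp_min: float = 0.75,
    alpha: float = 0.05,
) -> list[ItemDiagnosticRecord]:
    """Per-item SN/SP/kappa filter against caseness (complete pairs only).

    Retained iff SN >= sn_min, SP >= sp_min and the kappa z-test rejects
    chance agreement (one-sided, kappa > 0) at ``alpha``.  The chi-square
    test of the 2x2 table (no Yates correction) is reported alongside.
    """
    y_full = np.asarray(caseness.reindex(matrix.index), dtype=float)
    if len(np.unique(y_full[~np.isnan(y_full)])) < 2:
        raise DegenerateInputError("caseness must contain both classes")
    records = []
    for item_id in matrix.columns:
        x = np.asarray(matrix[item_id], dtype=float)
        mask = ~(np.isnan(x) | np.isnan(y_full))
        xi, yi = x[mask].astype(int), y_full[mask].astype(int)
        tp, fn, fp, tn = _two_by_two(xi, yi)
        sn = tp / (tp + fn) if tp + fn else np.nan
        sp = tn / (tn + fp) if tn + fp else np.nan
        kappa, z = cohen_kappa(tp, fn, fp, tn)
        table = np.array([[tp, fn], [fp, tn]])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2_p = float(stats.chi2_contingency(table, correction=False)[1])
        else:
            chi2_p = 1.0
        if len(np.unique(xi)) < 2:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(xi, yi).statistic)
        acc = (tp + tn) / len(xi)
        kappa_sig = stats.norm.sf(z) < alpha  # one-sided, kappa > 0
        retained = bool(sn >= sn_min and sp >= sp_min and kappa_sig)
        records.append(ItemDiagnosticRecord(
            item_id=item_id, sensitivity=float(sn), specificity=float(sp),
            kappa=kappa, kappa_z=z, chi2_p=chi2_p, spearman_rho=rho,
            predictive_accuracy=float(acc), retained=retained,
            stage_dropped=None if retained else "diagnostic_filter",
        ))
    return records


def spearman_accuracy_filter(
    records: list[ItemDiagnosticRecord],
    rho_min: float = 0.7,
    acc_min: float = 0.85,
) -> list[ItemDiagnosticRecord]:
    """Keep items with Spearman rho >= rho_min and accuracy >= acc_min.

    Operates on records already carrying rho and accuracy; items previously
    dropped stay dropped.  (For two binary vectors the Spearman correlation
    equals the Pearson phi coefficient.)
    """
    out = []
    for r in records:
        keep = r.retained and r.spearman_rho >= rho_min and r.predictive_accuracy >= acc_min
        stage = r.stage_dropped
        if r.retained and not keep:
            stage = "spearman_accuracy_filter"
        out.append(ItemDiagnosticRecord(**{**r.__dict__, "retained": keep,
                                           "stage_dropped": None if keep else stage}))
    return out


@dataclass
class CartSelection:
    retained_items: list[str]
    tree_text: str
    params: dict


def cart_select(
    matrix: pd.DataFrame,
    caseness: pd.Series,
    max_depth: int = 5,
    min_leaf: int = 5,
) -> CartSelection:
    """Greedy Gini classification tree; retained items = split variables.

    No pruning; defaults max_depth 5, min_leaf 5.  The tree is deterministic
    for given data (seeded splitter), so split ties are broken reproducibly.
    ``max_depth 0`` returns an empty selection.
    """
    if matrix.shape[1] < 2:
        raise DegenerateInputError("need at least 2 candidate items")
    y = np.asarray(caseness.reindex(matrix.index), dtype=float)
    mask = ~(np.isnan(y) | matrix.isna().any(axis=1).to_numpy())
    X = matrix.loc[mask].to_numpy(dtype=float)
    yy = y[mask].astype(int)
    if len(np.unique(yy)) < 2:
        raise DegenerateInputError("caseness is constant")
    params = {"max_depth": max_depth, "min_leaf": min_leaf, "criterion": "gini"}
    if max_depth == 0:
        return CartSelection([], "(empty tree: max_depth = 0)", params)
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, min_samples_leaf=min_leaf,
        random_state=0,
    ).fit(X, yy)
    used = sorted({f for f in tree.tree_.feature if f >= 0})
    retained = [matrix.columns[i] for i in used]
    text = export_text(tree, feature_names=list(matrix.columns))
    return CartSelection(retained, text, params)


def endorsement_specificity_flag(
    matrix: pd.DataFrame,
    threshold: float = 0.30,
) -> tuple[list[str], pd.DataFrame]:
    """Endorsement curves P(endorse item | rest-score = k) and low-specificity
    flags.

    The rest-score excludes the item itself (the cleaner conditional for
    "endorsed even when nothing else is"); an item is flagged when
    P(endorse | rest-score = 0) >= threshold.  The inclusive-total variant is
    emitted alongside for fidelity with total-score endorsement plots.
    """
    if matrix.shape[1] < 2:
        raise DegenerateInputError("need at least 2 items")
    X = matrix.dropna().to_numpy(dtype=int)
    if X.shape[0] == 0:
        raise DegenerateInputError("no complete cases")
    items = list(matrix.columns)
    m = len(items)
    total = X.sum(axis=1)
    rows = []
    flagged = []
    for j, item_id in enumerate(items):
        rest = total - X[:, j]
        for k in range(m):  # rest-score ranges 0..m-1
            sel = rest == k
            p_rest = float(X[sel, j].mean()) if sel.any() else np.nan
            sel_tot = total == k
            p_tot = float(X[sel_tot, j].mean()) if sel_tot.any() else np.nan
            rows.append({"item": item_id, "score": k, "p_rest": p_rest,
                         "n_rest": int(sel.sum()), "p_total": p_tot})
        p0 = next(r["p_rest"] for r in rows if r["item"] == item_id and r["score"] == 0)
        if not np.isnan(p0) and p0 >= threshold:
            flagged.append(item_id)
    return flagged, pd.DataFrame(rows)
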