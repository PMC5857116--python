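"""Differential item functioning by the logistic-regression method.

For each item and grouping variable two nested logistic models of the item
response are compared, matching on the total scale score:

    M0:  item ~ score
    M2:  item ~ score + group + score x group

The likelihood-ratio chi-square (df = 2 by default: joint uniform +
non-uniform DIF; df = 1 for the pure-uniform variant) tests DIF; the effect
size is the Nagelkerke R-squared difference between M2 and M0, classified as
negligible (< 0.035), moderate (0.035–0.07) or large (> 0.07).  p-values are
controlled per grouping variable across items with the Benjamini–Hochberg
step-up false-discovery-rate adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import DataValidationError, DegenerateInputError

logger = logging.getLogger(__name__)

EFFECT_THRESHOLDS = (0.035, 0.07)


@dataclass
class DifResult:
    item_id: str
    grouping: str
    lr_chi2: float
    df: int
    p_raw: float
    p_bh: float | None
    delta_r2: float
    effect_class: str
    penalized: bool = False


def classify_effect(delta_r2: float) -> str:
    if delta_r2 < EFFECT_THRESHOLDS[0]:
        return "negligible"
    if delta_r2 <= EFFECT_THRESHOLDS[1]:
        return "moderate"
    return "large"


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[float, bool]:
    """Log-likelihood of a logistic fit; falls back to an L1-penalized fit
    when the MLE does not exist (complete separation)."""
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
        if np.isnan(res.llf) or not res.mle_retvals.get("converged", True):
            raise PerfectSeparationError
        return float(res.llf), False
    except (PerfectSeparationError, np.linalg.LinAlgError):
        with np.errstate(all="ignore"):
            res = model.fit_regularized(method="l1", alpha=1e-4, disp=0)
        return float(model.loglike(res.params)), True


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke's R^2 = [1 - (L0/L)^(2/n)] / [1 - L0^(2/n)]."""
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_r2 = 1.0 - np.exp(2.0 * llnull / n)
    return float(cox_snell / max_r2)


def dif_logistic_item(
    item: np.ndarray | pd.Series,
    score: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
    item_id: str = "item",
    grouping: str = "group",
    joint: bool = True,
) -> DifResult:
    """Test one item for DIF against one binary grouping variable.

    ``score`` is the matching total scale score (including the studied item);
    ``group`` any two-category labelling.  ``joint=True`` tests uniform and
    non-uniform DIF together (df = 2); ``joint=False`` the uniform term only.
    """
    item = np.asarray(item, dtype=float)
    score = np.asarray(score, dtype=float)
    group = np.asarray(group)
    mask = ~(np.isnan(item) | np.isnan(score) | pd.isna(group))
    item, score, group = item[mask], score[mask], group[mask]
    levels = pd.unique(group)
    if len(levels) != 2:
        raise DegenerateInputError(
            f"grouping {grouping!r} must have exactly 2 observed levels, got {len(levels)}"
        )
    if len(np.unique(item)) < 2:
        raise DegenerateInputError(f"item {item_id!r} is constant")
    g = (group == levels[1]).astype(float)
    n = len(item)

    X0 = np.column_stack([np.ones(n), score])
    if joint:
        X2 = np.column_stack([np.ones(n), score, g, score * g])
        df = 2
    else:
        X2 = np.column_stack([np.ones(n), score, g])
        df = 1
    ll0, pen0 = _fit_logit(item, X0)
    ll2, pen2 = _fit_logit(item, X2)
    p1 = item.mean()
    llnull = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
    lr = max(0.0, 2.0 * (ll2 - ll0))
    p = float(stats.chi2.sf(lr, df))
    delta = max(0.0, nagelkerke_r2(ll2, llnull, n) - nagelkerke_r2(ll0, llnull, n))
    return DifResult(
        item_id=item_id, grouping=grouping, lr_chi2=lr, df=df, p_raw=p,
        p_bh=None, delta_r2=delta, effect_class=classify_effect(delta),
        penalized=pen0 or pen2,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dif_analysis(
    matrix: pd.DataFrame,
    scores: pd.Series,
    groupings: pd.DataFrame,
    joint: bool = True,
) -> pd.DataFrame:
    """Run the logistic DIF test for every item x grouping combination.

    BH adjustment is applied per grouping variable across the items (one
    family per grouping).  Returns a long-format frame.
    """
    rows = []
    for gname in groupings.columns:
        fam = []
        for item_id in matrix.columns:
            res = dif_logistic_item(
                matrix[item_id], scores.reindex(matrix.index),
                groupings[gname], item_id=item_id, grouping=gname, joint=joint,
            )
            fam.append(res)
        adj = bh_adjust([r.p_raw for r in fam])
        for r, pa in zip(fam, adj):
            r.p_bh = float(pa)
            rows.append(r.__dict__)
    return pd.DataFrame(rows)
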