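"""Diagnostic accuracy of the scale score against interview caseness.

ROC curve over every observed threshold ("score >= c"), AUC with DeLong
variance, Harrell's bootstrap optimism correction of the AUC, and a
per-cutoff table of sensitivity, specificity, likelihood ratios, predictive
values and efficiency with confidence intervals, from which the operating
cut-score is chosen by Youden's criterion (reported, as published, as the sum
SN + SP) or by privileging sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DataValidationError, DegenerateInputError

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


def _check_two_class(caseness: np.ndarray) -> None:
    u = np.unique(caseness)
    if not np.array_equal(u, [0, 1]):
        raise DegenerateInputError("caseness must contain both classes (0 and 1)")


# ---------------------------------------------------------------------------
# ROC curve and AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    thresholds: np.ndarray          # "positive" means score >= threshold
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None = None
    auc_se: float | None = None


def roc_points(scores, caseness) -> RocCurve:
    """Empirical ROC: one point per observed threshold plus the endpoints;
    AUC by the trapezoid rule (equals the Mann–Whitney concordance)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(caseness, dtype=int)
    _check_two_class(y)
    thr = np.sort(np.unique(s))[::-1]
    sens = [0.0]
    fpr = [0.0]
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    for c in thr:
        pos = s >= c
        sens.append(float(np.sum(pos & (y == 1))) / n1)
        fpr.append(float(np.sum(pos & (y == 0))) / n0)
    sens, fpr = np.array(sens), np.array(fpr)
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(thresholds=thr, sensitivity=sens[1:],
                    one_minus_specificity=fpr[1:], auc=auc)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_with_ci(scores, caseness, method: str = "delong") -> RocCurve:
    """AUC as the Mann–Whitney concordance with a DeLong 95% Wald CI."""
    if method != "delong":
        raise DataValidationError(f"unknown CI method {method!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(caseness, dtype=int)
    _check_two_class(y)
    x1 = s[y == 1]
    x0 = s[y == 0]
    m, n = len(x1), len(x0)
    if min(m, n) < 10:
        logger.warning("fewer than 10 observations in a class; DeLong CI unreliable")
    tz = _midranks(np.concatenate([x1, x0]))
    t1 = _midranks(x1)
    t0 = _midranks(x0)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - t1) / n
    v10 = 1.0 - (tz[m:] - t0) / m
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    lo, hi = np.clip([auc - Z95 * se, auc + Z95 * se], 0.0, 1.0)
    curve = roc_points(s, y)
    curve.auc = float(auc)
    curve.auc_se = se
    curve.auc_ci = (float(lo), float(hi))
    return curve


# ---------------------------------------------------------------------------
# Optimism-corrected AUC (Harrell's bootstrap)
# ---------------------------------------------------------------------------

@dataclass
class OptimismResult:
    apparent_auc: float
    mean_optimism: float
    corrected_auc: float
    n_boot: int
    n_redrawn: int


def _model_auc(train_s, train_y, eval_s, eval_y) -> float:
    """AUC on (eval) of a univariable logistic model fitted on (train).

    With a single predictor the fitted probabilities are monotone in the
    score, so only the coefficient's sign matters for the ranking; if the
    MLE fails (separation) the sign of the score/outcome correlation is used.
    """
    X = sm.add_constant(np.asarray(train_s, dtype=float))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(np.asarray(train_y), X).fit(disp=0, maxiter=100)
        slope = res.params[1]
    except Exception:
        slope = np.corrcoef(train_s, train_y)[0, 1]
    pred = np.asarray(eval_s, dtype=float) * (1.0 if slope >= 0 else -1.0)
    return auc_with_ci(pred, eval_y).auc


def optimism_corrected_auc(
    scores, caseness, n_boot: int = 200, seed: int = 0
) -> OptimismResult:
    """Harrell's algorithm: corrected = apparent - mean bootstrap optimism.

    Each bootstrap resample refits the univariable logistic model
    caseness ~ score; optimism = AUC(boot model on boot sample) - AUC(boot
    model on original sample).  Single-class resamples are redrawn (counted).
    """
    if n_boot < 50:
        raise DataValidationError("n_boot must be at least 50")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(caseness, dtype=int)
    _check_two_class(y)
    n = len(s)
    apparent = _model_auc(s, y, s, y)
    rng = np.random.default_rng(seed)
    optimism = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            n_redrawn += 1
        sb = s[idx]
        optimism[b] = _model_auc(sb, yb, sb, yb) - _model_auc(sb, yb, s, y)
    if n_redrawn:
        logger.info("optimism bootstrap: %d single-class resamples redrawn", n_redrawn)
    mean_opt = float(optimism.mean())
    return OptimismResult(apparent, mean_opt, apparent - mean_opt, n_boot, n_redrawn)


# ---------------------------------------------------------------------------
# Cutoff table and Youden selection
# ---------------------------------------------------------------------------

def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def cutoff_table(scores, caseness, cutoffs=None) -> pd.DataFrame:
    """Per-cutoff diagnostic metrics for the rule "score >= cutoff".

    SN, SP, PPV, NPV and efficiency get Clopper–Pearson 95% CIs; the
    likelihood ratios get log-method Wald CIs.  Youden's statistic is
    reported both as the published sum SN + SP (``youden_sum``) and in the
    conventional SN + SP - 1 form (``youden_j``).  A cutoff with SP = 1 has
    an infinite PLR (flagged); SN = 1 gives NLR = 0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(caseness, dtype=int)
    _check_two_class(y)
    if cutoffs is None:
        cutoffs = np.arange(int(s.min()) + 1, int(s.max()) + 1)
    cutoffs = list(cutoffs)
    if any(c < s.min() - 1e-9 or c > s.max() + 1e-9 for c in cutoffs):
        raise DataValidationError("cutoffs must lie within the score range")
    rows = []
    for c in cutoffs:
        pos = s >= c
        tp = int(np.sum(pos & (y == 1)))
        fp = int(np.sum(pos & (y == 0)))
        fn = int(np.sum(~pos & (y == 1)))
        tn = int(np.sum(~pos & (y == 0)))
        n1, n0 = tp + fn, fp + tn
        sn, sp = tp / n1, tn / n0
        row = {
            "cutoff": c, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sn": sn, "sp": sp,
            "sn_ci": _clopper_pearson(tp, n1),
            "sp_ci": _clopper_pearson(tn, n0),
        }
        # likelihood ratios (log-method CIs)
        if sp < 1.0:
            plr = sn / (1.0 - sp)
            if tp > 0 and fp > 0:
                se_log = np.sqrt(1 / tp - 1 / n1 + 1 / fp - 1 / n0)
                row["plr_ci"] = (plr * np.exp(-Z95 * se_log), plr * np.exp(Z95 * se_log))
            else:
                row["plr_ci"] = (np.nan, np.nan)
        else:
            plr = np.inf
            row["plr_ci"] = (np.nan, np.nan)
        row["plr"] = plr
        row["plr_infinite"] = not np.isfinite(plr)
        if sn < 1.0 and sp > 0.0:
            nlr = (1.0 - sn) / sp
            if fn > 0 and tn > 0:
                se_log = np.sqrt(1 / fn - 1 / n1 + 1 / tn - 1 / n0)
                row["nlr_ci"] = (nlr * np.exp(-Z95 * se_log), nlr * np.exp(Z95 * se_log))
            else:
                row["nlr_ci"] = (np.nan, np.nan)
        else:
            nlr = 0.0 if sn == 1.0 else np.nan
            row["nlr_ci"] = (np.nan, np.nan)
        row["nlr"] = nlr
        row["ppv"] = tp / (tp + fp) if tp + fp else np.nan
        row["ppv_ci"] = _clopper_pearson(tp, tp + fp) if tp + fp else (np.nan, np.nan)
        row["npv"] = tn / (tn + fn) if tn + fn else np.nan
        row["npv_ci"] = _clopper_pearson(tn, tn + fn) if tn + fn else (np.nan, np.nan)
        row["efficiency"] = (tp + tn) / (n1 + n0)
        row["efficiency_ci"] = _clopper_pearson(tp + tn, n1 + n0)
        row["youden_sum"] = sn + sp
        row["youden_j"] = sn + sp - 1.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CutoffChoice:
    optimal_cutoff: float
    sensitivity_privileged_cutoff: float | None
    sn_floor: float


def youden_select(table: pd.DataFrame, sn_floor: float = 0.90) -> CutoffChoice:
    """Operating-point selection from a cutoff table.

    ``optimal_cutoff`` maximises the Youden sum SN + SP (ties -> lower
    cutoff); ``sensitivity_privileged_cutoff`` is the lowest cutoff keeping
    SN >= ``sn_floor`` — the rationale for preferring a lower cut-score in a
    screening (rule-out) setting.
    """
    if len(table) == 0:
        raise DegenerateInputError("empty cutoff table")
    t = table.sort_values("cutoff", kind="stable")
    best = t.loc[t["youden_sum"].idxmax()]  # idxmax returns first max -> lower cutoff
    eligible = t.loc[t["sn"] >= sn_floor, "cutoff"]
    priv = float(eligible.iloc[-1]) if len(eligible) else None
    # SN is non-increasing in cutoff, so the *highest* eligible cutoff gives
    # the best specificity while keeping the floor; the published choice is
    # the highest cutoff with SN >= floor.
    return CutoffChoice(float(best["cutoff"]), priv, sn_floor)
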