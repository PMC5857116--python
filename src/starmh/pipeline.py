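"""End-to-end validation run mirroring the published analysis sequence.

Stage order: complete-case filtering -> endorsement table -> endorsement-
specificity flags -> Rasch CML fit (item fit, reliability) -> modified
parallel analysis -> Ponocny T1 -> DIF across all groupings -> ROC / AUC /
optimism bootstrap -> cutoff table -> Youden selection.  Every stage writes a
plain-text table into the report directory; a stage failure is recorded and
the run continues where dependencies allow.  With a fixed seed the report is
byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import Cohort, drop_incomplete, endorsement_table
from .dif import dif_analysis
from .diagnostics import auc_with_ci, cutoff_table, optimism_corrected_auc, youden_select
from .item_selection import endorsement_specificity_flag
from .rasch import RaschModel
from .scoring import ScaleDefinition, classify_cohort, scale_scores
from .structure import MarginFixedSampler, modified_parallel_analysis, ponocny_t1

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "cutoffs": None,               # default: every score 1..max
    "n_parallel_mc": 2000,
    "n_boot": 200,
    "sampler": {"burn_in": 1000, "thin": 16, "n_samples": 500},
    "dif_joint": True,
    "sn_floor": 0.90,
    "specificity_threshold": 0.30,
    "drop_items": [],              # analyst-directed drops (flags never auto-drop)
    "groupings": ["sex", "age_group", "interpreter", "agency", "origin",
                  "marital", "travel_mode", "detention"],
}

_CSV_KW = dict(float_format="%.6g", lineterminator="\n")


def load_config(path=None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else (list(v) if isinstance(v, list) else v))
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if k == "sampler" and isinstance(v, dict):
                cfg["sampler"].update(v)
            else:
                cfg[k] = v
    return cfg


def run_validation_report(
    cohort: Cohort,
    scale: ScaleDefinition,
    outdir,
    seed: int = 0,
    config: dict | None = None,
) -> dict:
    """Execute the full validation sequence and write its tables to ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    cfg = {**load_config(None), **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scale_items = [i for i in scale.scale_items if i not in cfg["drop_items"]]
    all_items = list(scale.screen_in_items) + scale_items
    summary: dict = {
        "seed": seed,
        "package_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "stages": {},
    }

    def stage(name, fn):
        try:
            fn()
            summary["stages"][name] = "ok"
        except Exception as exc:  # keep going where dependencies allow
            logger.error("stage %s failed: %s", name, exc)
            summary["stages"][name] = f"failed: {exc}"

    state: dict = {}

    def s_filter():
        analyzed, acc = drop_incomplete(cohort, all_items)
        state["analyzed"] = analyzed
        summary["n_input"] = cohort.n_persons
        summary["n_analyzed"] = acc.n_analyzed
        summary["n_missing_omitted"] = acc.n_missing_omitted
    stage("complete_case_filter", s_filter)
    analyzed = state.get("analyzed", cohort)
    matrix = analyzed.responses[scale_items]

    stage("endorsement", lambda: endorsement_table(matrix).to_csv(
        outdir / "endorsement.csv", **_CSV_KW))

    def s_flags():
        flagged, curves = endorsement_specificity_flag(
            matrix, threshold=cfg["specificity_threshold"])
        curves.to_csv(outdir / "endorsement_curves.csv", index=False, **_CSV_KW)
        summary["low_specificity_flags"] = flagged
    stage("endorsement_specificity", s_flags)

    def s_scoring():
        outcomes, rates = classify_cohort(analyzed, scale)
        outcomes.to_csv(outdir / "screen_outcomes.csv", **_CSV_KW)
        summary["screening"] = rates
    stage("scoring", s_scoring)

    def s_rasch():
        fit = RaschModel(matrix).fit()
        state["fit"] = fit
        tbl = fit.item_fit()
        tbl.insert(0, "difficulty", fit.params)
        tbl.insert(1, "se", fit.bse)
        tbl.to_csv(outdir / "rasch_items.csv", **_CSV_KW)
        rel = fit.reliability(matrix)
        summary["psi"] = rel.psi
        summary["mean_interitem_r"] = rel.mean_interitem_r
    stage("rasch", s_rasch)

    def s_parallel():
        pa = modified_parallel_analysis(
            matrix, state["fit"], n_mc=cfg["n_parallel_mc"], seed=seed)
        summary["parallel_analysis"] = {
            "p_value": pa.p_value,
            "observed_second_eigenvalue": pa.observed_second_eigenvalue,
            "n_mc": pa.n_mc,
        }
    if "fit" in state:
        stage("parallel_analysis", s_parallel)
    else:
        summary["stages"]["parallel_analysis"] = "skipped: no Rasch fit"

    def s_t1():
        sampler = MarginFixedSampler(seed=seed, **cfg["sampler"])
        t1 = ponocny_t1(matrix, sampler)
        t1.to_csv(outdir / "t1_pairs.csv", index=False, **_CSV_KW)
        summary["t1_n_pairs"] = len(t1)
        summary["t1_n_dependent"] = int(t1["locally_dependent"].sum())
    stage("ponocny_t1", s_t1)

    def s_dif():
        scores = scale_scores(analyzed, ScaleDefinition(
            scale.screen_in_items, tuple(scale_items), scale.cutoff))
        grp = analyzed.covariates[[g for g in cfg["groupings"]
                                   if g in analyzed.covariates.columns]]
        res = dif_analysis(matrix, scores, grp, joint=cfg["dif_joint"])
        res.to_csv(outdir / "dif.csv", index=False, **_CSV_KW)
        summary["dif_n_flagged"] = int(((res["p_bh"] < 0.05)
                                        & (res["effect_class"] != "negligible")).sum())
    if analyzed.covariates is not None:
        stage("dif", s_dif)
    else:
        summary["stages"]["dif"] = "skipped: no covariates"

    def s_roc():
        scores = scale_scores(analyzed, ScaleDefinition(
            scale.screen_in_items, tuple(scale_items), scale.cutoff))
        y = analyzed.caseness.loc[scores.index]
        keep = y.notna()
        sc, yy = scores[keep].to_numpy(), y[keep].to_numpy().astype(int)
        curve = auc_with_ci(sc, yy)
        pd.DataFrame({
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "one_minus_specificity": curve.one_minus_specificity,
        }).to_csv(outdir / "roc_points.csv", index=False, **_CSV_KW)
        opt = optimism_corrected_auc(sc, yy, n_boot=cfg["n_boot"], seed=seed)
        tab = cutoff_table(sc, yy, cfg["cutoffs"])
        tab.to_csv(outdir / "cutoff_table.csv", index=False, **_CSV_KW)
        choice = youden_select(tab, sn_floor=cfg["sn_floor"])
        summary["roc"] = {
            "auc": curve.auc,
            "auc_ci": list(curve.auc_ci),
            "apparent_auc": opt.apparent_auc,
            "optimism_corrected_auc": opt.corrected_auc,
            "n_boot": opt.n_boot,
            "optimal_cutoff": choice.optimal_cutoff,
            "sensitivity_privileged_cutoff": choice.sensitivity_privileged_cutoff,
        }
    if analyzed.caseness is not None:
        stage("roc", s_roc)
    else:
        summary["stages"]["roc"] = "skipped: no caseness"

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return summary


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
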