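"""Scale scoring as fielded: immediate screen-in items, summed scale, cut-score.

The screening tool has two *immediate screen-in* items (help seeking,
suicidality) whose positive answer classifies the person screen-positive
without administering the rest, and a 7-item summed scale with a configurable
positivity cut-score (``total ≥ cutoff``; the fielded recommendation is ≥2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import reference
from .data_model import Cohort
from .exceptions import DataValidationError, DegenerateInputError, IncompleteScreenError


@dataclass(frozen=True)
class ScaleDefinition:
    """Item lists and cut-score defining the screening rule."""

    screen_in_items: tuple[str, ...] = tuple(reference.SCREEN_IN_ITEMS)
    scale_items: tuple[str, ...] = tuple(reference.SCALE_ITEMS)
    cutoff: int = 2

    def __post_init__(self):
        object.__setattr__(self, "screen_in_items", tuple(self.screen_in_items))
        object.__setattr__(self, "scale_items", tuple(self.scale_items))
        if set(self.screen_in_items) & set(self.scale_items):
            raise DataValidationError("screen-in and scale item sets must be disjoint")
        if not (0 <= self.cutoff <= len(self.scale_items)):
            raise DataValidationError("cutoff must lie in [0, n scale items]")

    @classmethod
    def from_yaml(cls, path) -> "ScaleDefinition":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            screen_in_items=tuple(cfg.get("screen_in_items", reference.SCREEN_IN_ITEMS)),
            scale_items=tuple(cfg.get("scale_items", reference.SCALE_ITEMS)),
            cutoff=int(cfg.get("cutoff", 2)),
        )

    def to_dict(self) -> dict:
        return {
            "screen_in_items": list(self.screen_in_items),
            "scale_items": list(self.scale_items),
            "cutoff": self.cutoff,
        }


@dataclass
class ScreenOutcome:
    person_id: object
    screened_in_immediately: bool
    total_score: int | None
    positive: bool


def score_star_mh(
    answers: Mapping[str, float],
    scale: ScaleDefinition,
    early_exit: bool = True,
    missing_policy: str = "zero",
    person_id: object = None,
) -> ScreenOutcome:
    """Score one person.

    With ``early_exit``, a positive answer to either immediate screen-in item
    classifies the person positive and the scale total is left undefined (the
    remaining items need not be administered).  Otherwise the total is the
    unweighted sum of the scale items and positivity is ``total ≥ cutoff``.

    Missing scale answers: ``missing_policy="zero"`` counts them as 0 with a
    recorded flag (a field tool must degrade gracefully); ``"strict"`` raises
    :class:`IncompleteScreenError`.
    """
    if missing_policy not in ("zero", "strict"):
        raise DataValidationError(f"unknown missing_policy {missing_policy!r}")
    if early_exit:
        for it in scale.screen_in_items:
            v = answers.get(it, np.nan)
            if not _is_missing(v) and float(v) == 1.0:
                return ScreenOutcome(person_id, True, None, True)
    vals = []
    for it in scale.scale_items:
        v = answers.get(it, np.nan)
        if _is_missing(v):
            if missing_policy == "strict":
                raise IncompleteScreenError(f"missing answer for scale item {it!r}")
            v = 0.0
        vals.append(float(v))
    total = int(sum(vals))
    return ScreenOutcome(person_id, False, total, total >= scale.cutoff)


def _is_missing(v) -> bool:
    try:
        return v is None or np.isnan(float(v))
    except (TypeError, ValueError):
        return True


def classify_cohort(
    cohort: Cohort,
    scale: ScaleDefinition,
    early_exit: bool = True,
    missing_policy: str = "zero",
) -> tuple[pd.DataFrame, dict]:
    """Vectorized scoring of every person; returns outcomes and summary rates."""
    if cohort.n_persons == 0:
        raise DegenerateInputError("empty cohort")
    rows = []
    for pid, row in cohort.responses.iterrows():
        out = score_star_mh(row, scale, early_exit=early_exit,
                            missing_policy=missing_policy, person_id=pid)
        rows.append({
            "person_id": pid,
            "screened_in_immediately": out.screened_in_immediately,
            "total_score": np.nan if out.total_score is None else out.total_score,
            "positive": out.positive,
        })
    frame = pd.DataFrame(rows).set_index("person_id")
    summary = {
        "fraction_positive": float(frame["positive"].mean()),
        "fraction_early_exit": float(frame["screened_in_immediately"].mean()),
        "n": len(frame),
    }
    return frame, summary


def scale_scores(
    cohort: Cohort,
    scale: ScaleDefinition,
    complete_only: bool = True,
) -> pd.Series:
    """7-item total score used in the diagnostic-accuracy analyses.

    Screen-in items are excluded; by default only complete cases are scored
    (the published ROC analysis used the complete-case scale sum for all
    retained persons, regardless of screen-in answers).
    """
    sub = cohort.responses[list(scale.scale_items)]
    if complete_only:
        sub = sub.loc[sub.notna().all(axis=1)]
    return sub.sum(axis=1).astype(int)
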