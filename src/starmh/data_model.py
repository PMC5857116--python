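"""Cohort ingestion, dichotomization and sample accounting.

The substrate of every analysis in this package is a persons × items matrix of
dichotomous (0/1) responses with explicit missingness, joined with a per-person
caseness indicator (structured-interview diagnosis of MDD and/or PTSD) and
categorical grouping covariates.  Responses live in a float ``DataFrame`` whose
cells are 0.0, 1.0 or NaN; person order is preserved across every filter so row
indices remain joinable without keys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    DegenerateInputError,
    IntegrityError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Input spellings accepted as missing (case-insensitive), per CSV dialect.
MISSING_SPELLINGS = {"", "na", "nan"}

COVARIATE_COLUMNS = [
    "sex", "age", "age_group", "interpreter", "agency", "origin",
    "marital", "travel_mode", "detention",
]


@dataclass
class SampleAccounting:
    """Recruitment / retention arithmetic for a screening cohort."""

    recruited_per_site: dict[str, int] = field(default_factory=dict)
    declined_per_site: dict[str, int] = field(default_factory=dict)
    n_missing_omitted: int = 0
    n_analyzed: int = 0

    def __post_init__(self) -> None:
        for d in (self.recruited_per_site, self.declined_per_site):
            if any(v < 0 for v in d.values()):
                raise DataValidationError("site counts must be non-negative")
        if self.n_missing_omitted < 0 or self.n_analyzed < 0:
            raise DataValidationError("counts must be non-negative")


class Cohort:
    """Binary response matrix joined with caseness and covariates.

    Parameters
    ----------
    responses
        persons × items frame; cells must be 0, 1 or NaN.  The index carries
        person identifiers and must be unique.
    caseness
        Per-person 0/1 (or NaN when the reference diagnosis is missing),
        aligned with ``responses.index``.
    covariates
        Per-person categorical frame aligned with ``responses.index``.
    """

    def __init__(
        self,
        responses: pd.DataFrame,
        caseness: pd.Series | None = None,
        covariates: pd.DataFrame | None = None,
    ):
        responses = responses.astype(float)
        vals = responses.to_numpy()
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            raise DataValidationError(
                f"{int(bad.sum())} response cells are neither 0, 1 nor missing"
            )
        if responses.index.has_duplicates:
            raise IntegrityError("duplicate person_id in response matrix")
        self.responses = responses
        if caseness is not None:
            caseness = caseness.reindex(responses.index).astype(float)
        self.caseness = caseness
        if covariates is not None:
            covariates = covariates.reindex(responses.index)
        self.covariates = covariates

    # -- convenience ------------------------------------------------------
    @property
    def persons(self) -> pd.Index:
        return self.responses.index

    @property
    def items(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def n_persons(self) -> int:
        return len(self.responses)

    def complete_mask(self, items: Sequence[str] | None = None) -> pd.Series:
        """True for persons with no missing cell among ``items``."""
        sub = self.responses if items is None else self.responses[list(items)]
        return sub.notna().all(axis=1)

    def subset(self, mask: pd.Series) -> "Cohort":
        return Cohort(
            self.responses.loc[mask],
            None if self.caseness is None else self.caseness.loc[mask],
            None if self.covariates is None else self.covariates.loc[mask],
        )


def _parse_cell(raw: object) -> tuple[float, bool]:
    """Return (value, malformed) with NaN for any accepted missing spelling."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, False
    s = str(raw).strip()
    if s.lower() in MISSING_SPELLINGS:
        return np.nan, False
    try:
        return float(s), False
    except ValueError:
        return np.nan, True


def load_cohort(
    path,
    schema: Mapping[str, object] | None = None,
) -> Cohort:
    """Read a wide one-row-per-person CSV into a :class:`Cohort`.

    ``schema`` maps roles to column names: ``person_id`` (str), ``items``
    (list of columns), ``mdd`` / ``ptsd`` (diagnosis columns, optional),
    ``covariates`` (list, optional).  Unmapped columns are ignored.  Malformed
    cells become missing; their count is logged and stored on the returned
    cohort as ``n_malformed``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    person_col = schema.get("person_id", "person_id")
    item_cols = list(schema.get("items")) if schema.get("items") else [
        c for c in frame.columns if c.startswith("item_")
    ]
    missing_cols = [c for c in [person_col, *item_cols] if c not in frame.columns]
    if missing_cols or not item_cols:
        raise SchemaError(f"mandatory columns absent: {missing_cols or 'item columns'}")
    if frame[person_col].duplicated().any():
        dup = frame[person_col][frame[person_col].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate person_id {dup!r}")

    n_malformed = 0
    parsed = {}
    for c in item_cols:
        col = []
        for raw in frame[c]:
            v, bad = _parse_cell(raw)
            n_malformed += bad
            col.append(v)
        parsed[c] = col
    responses = pd.DataFrame(parsed, index=pd.Index(frame[person_col], name="person_id"))
    if n_malformed:
        logger.warning("load_cohort: %d malformed cells set to missing", n_malformed)

    caseness = None
    mdd_col = schema.get("mdd", "mini_mdd" if "mini_mdd" in frame.columns else None)
    ptsd_col = schema.get("ptsd", "mini_ptsd" if "mini_ptsd" in frame.columns else None)
    diag = []
    for c in (mdd_col, ptsd_col):
        if c is not None:
            if c not in frame.columns:
                raise SchemaError(f"diagnosis column {c!r} absent")
            diag.append([_parse_cell(v)[0] for v in frame[c]])
    if diag:
        arr = np.vstack(diag)
        with np.errstate(invalid="ignore"):
            case = np.where(
                np.all(np.isnan(arr), axis=0), np.nan, np.nanmax(arr, axis=0)
            )
        caseness = pd.Series(case, index=responses.index, name="caseness")

    cov_cols = schema.get("covariates") or [c for c in COVARIATE_COLUMNS if c in frame.columns]
    covariates = None
    if cov_cols:
        covariates = frame[list(cov_cols)].copy()
        covariates.index = responses.index

    cohort = Cohort(responses, caseness, covariates)
    cohort.n_malformed = n_malformed
    return cohort


def dichotomize_likert(responses: pd.DataFrame, threshold: int = 3) -> pd.DataFrame:
    """Dichotomize 1–4 Likert responses: value ≥ threshold → 1, else 0.

    The threshold marks clinical relevance; missing stays missing.  A
    threshold of 1 would map every observed value to 1 and is rejected.
    """
    if threshold not in (2, 3, 4):
        raise DataValidationError(f"threshold must be in {{2,3,4}}, got {threshold}")
    vals = responses.astype(float).to_numpy()
    bad = ~(np.isnan(vals) | np.isin(vals, (1.0, 2.0, 3.0, 4.0)))
    if bad.any():
        raise DataValidationError(
            f"{int(bad.sum())} cells outside the 1–4 Likert range"
        )
    out = np.where(np.isnan(vals), np.nan, (vals >= threshold).astype(float))
    return pd.DataFrame(out, index=responses.index, columns=responses.columns)


def drop_incomplete(
    cohort: Cohort,
    item_subset: Sequence[str],
    accounting: SampleAccounting | None = None,
) -> tuple[Cohort, SampleAccounting]:
    """Remove persons with any missing cell among ``item_subset``.

    Person order is preserved.  Returns the filtered cohort and updated
    accounting (site counts carried over from ``accounting`` if given).
    """
    item_subset = list(item_subset)
    if not item_subset:
        raise DataValidationError("item_subset must be non-empty")
    mask = cohort.complete_mask(item_subset)
    n_omitted = int((~mask).sum())
    if mask.sum() == 0:
        raise DegenerateInputError("no complete cases remain")
    acc = SampleAccounting(
        recruited_per_site=dict(accounting.recruited_per_site) if accounting else {},
        declined_per_site=dict(accounting.declined_per_site) if accounting else {},
        n_missing_omitted=n_omitted,
        n_analyzed=int(mask.sum()),
    )
    logger.info(
        "drop_incomplete: omitted %d of %d persons (%.1f%%)",
        n_omitted, cohort.n_persons, 100.0 * n_omitted / cohort.n_persons,
    )
    return cohort.subset(mask), acc


def endorsement_table(matrix: pd.DataFrame, denominator: int | None = None) -> pd.DataFrame:
    """Per-item yes/no counts and percentage endorsed.

    Percentages use the stated ``denominator`` (default: number of rows) even
    for items with missing cells, following the convention of reporting on the
    full analysed N.
    """
    if denominator is None:
        denominator = len(matrix)
    n_yes = matrix.sum(axis=0, skipna=True).astype(int)
    n_no = (matrix == 0).sum(axis=0).astype(int)
    if denominator < int((n_yes + n_no).max()):
        raise DataValidationError("denominator smaller than observed item totals")
    out = pd.DataFrame({
        "n_yes": n_yes,
        "n_no": n_no,
        "pct_yes": 100.0 * n_yes / denominator,
        "pct_no": 100.0 * n_no / denominator,
    })
    out.index.name = "item"
    return out


def participation_summary(accounting: SampleAccounting) -> dict:
    """Overall and per-site participation rates (percent)."""
    sites = sorted(set(accounting.recruited_per_site) | set(accounting.declined_per_site))
    rec = {s: accounting.recruited_per_site.get(s, 0) for s in sites}
    dec = {s: accounting.declined_per_site.get(s, 0) for s in sites}
    total = sum(rec.values()) + sum(dec.values())
    if total == 0:
        raise DegenerateInputError("no recruitment counts")
    per_site = {}
    for s in sites:
        denom = rec[s] + dec[s]
        per_site[s] = 100.0 * rec[s] / denom if denom else float("nan")
    return {
        "participation_rate_pct": 100.0 * sum(rec.values()) / total,
        "per_site_pct": per_site,
        "n_recruited": sum(rec.values()),
        "n_approached": total,
    }
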