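"""Synthetic cohorts with the statistical structure the analyses assume.

The raw validation data were never deposited, so every stage of the pipeline
is exercised on generated cohorts.  The generator implements the same Rasch
measurement model the analyses fit: a latent psychological-distress trait
theta per person, item endorsement Bernoulli(sigma(theta - beta_i)), with

* caseness ~ Bernoulli(prevalence) and a two-component normal trait mixture
  (case / non-case means) linking distress to diagnosis;
* difficulties defaulting to the published sum-zero estimates of the 7-item
  scale;
* immediate screen-in items drawn from caseness-conditional endorsement
  rates;
* optional injected uniform DIF (a difficulty shift for one covariate
  level), an optional second latent factor for a subset of items, and MCAR
  missingness applied last.

Default trait means (-2.6 non-case, +0.9 case, SD 1.55) were solved from the
published cohort geometry before any fitting: ~33% prevalence, ~30% item
endorsement, the case/non-case score separation implied by the printed
sensitivity/specificity column (case mean score ~4.3, non-case ~1.0), a
scale-score AUC near 0.91, person-separation reliability near 0.75 and mean
inter-item correlation near 0.46.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import reference
from .data_model import Cohort
from .exceptions import DataValidationError


@dataclass(frozen=True)
class DifShift:
    """Uniform DIF: persons with ``covariate == level`` see the item's
    difficulty shifted by ``delta`` logits (positive = harder to endorse)."""
    item: str
    covariate: str
    level: str
    delta: float


@dataclass(frozen=True)
class SecondFactor:
    """Items in ``items`` load on a second trait correlated ``correlation``
    with the main trait; ``loading`` in [0,1] mixes the two (1 = pure
    second factor)."""
    items: tuple[str, ...]
    loading: float = 1.0
    correlation: float = 0.2


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic screening cohort."""

    n_persons: int = 185
    difficulties: dict = field(
        default_factory=lambda: dict(reference.ITEM_DIFFICULTIES))
    trait_mean_noncase: float = -2.6
    trait_mean_case: float = 0.9
    trait_sd: float = 1.55
    prevalence: float = 0.33
    #: P(yes | case), P(yes | non-case) for each immediate screen-in item.
    screen_in_rate_case: float = 0.35
    screen_in_rate_noncase: float = 0.05
    screen_in_items: tuple = tuple(reference.SCREEN_IN_ITEMS)
    dif_shifts: tuple = ()
    #: per-cell MCAR probability (0.004 ~ 3.6% of 9-item records incomplete)
    missing_rate: float = 0.0
    second_factor: SecondFactor | None = None
    covariate_frequencies: dict = field(
        default_factory=lambda: dict(reference.COVARIATE_FREQUENCIES))
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if not (0 < self.prevalence < 1):
            bad.append("prevalence must be in (0,1)")
        if self.trait_sd <= 0:
            bad.append("trait_sd must be positive")
        if not (0 <= self.missing_rate < 1):
            bad.append("missing_rate must be in [0,1)")
        if self.n_persons < 2:
            bad.append("n_persons must be at least 2")
        for r in (self.screen_in_rate_case, self.screen_in_rate_noncase):
            if not (0 <= r <= 1):
                bad.append("screen-in rates must be probabilities")
        for shift in self.dif_shifts:
            if shift.item not in self.difficulties:
                bad.append(f"dif shift names unknown item {shift.item!r}")
            if shift.covariate not in self.covariate_frequencies:
                bad.append(f"dif shift names unknown covariate {shift.covariate!r}")
        if self.second_factor is not None:
            unknown = set(self.second_factor.items) - set(self.difficulties)
            if unknown:
                bad.append(f"second factor names unknown items {sorted(unknown)}")
            if not (0 <= self.second_factor.loading <= 1):
                bad.append("second-factor loading must be in [0,1]")
            if not (-1 <= self.second_factor.correlation <= 1):
                bad.append("second-factor correlation must be in [-1,1]")
        if bad:
            raise DataValidationError("; ".join(bad))


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, dict]:
    """Draw one cohort; returns (cohort, truth record of all latent values)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    items = list(config.difficulties)
    beta = np.array([config.difficulties[i] for i in items])

    caseness = (rng.random(n) < config.prevalence).astype(int)
    mean = np.where(caseness == 1, config.trait_mean_case, config.trait_mean_noncase)
    theta = rng.normal(mean, config.trait_sd)

    # covariates from marginal frequencies
    cov = {}
    for name, (level1, p1) in config.covariate_frequencies.items():
        is1 = rng.random(n) < p1
        other = {"sex": "female", "age_group": "18-33", "interpreter": "no",
                 "agency": "MHC", "origin": "other", "marital": "other",
                 "travel_mode": "other", "detention": "no"}.get(name, f"not_{level1}")
        cov[name] = np.where(is1, level1, other)
    covariates = pd.DataFrame(cov, index=pd.RangeIndex(n, name="person_id"))

    # second factor: per-person effective trait per item group
    theta_eff = np.tile(theta[:, None], (1, len(items)))
    if config.second_factor is not None:
        sf = config.second_factor
        rho = sf.correlation
        theta_b = (mean + rho * (theta - mean)
                   + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, config.trait_sd, n))
        lam = sf.loading
        mixed = lam * theta_b + (1 - lam) * theta
        for j, it in enumerate(items):
            if it in sf.items:
                theta_eff[:, j] = mixed

    # difficulty shifts (uniform DIF)
    beta_eff = np.tile(beta[None, :], (n, 1))
    for shift in config.dif_shifts:
        j = items.index(shift.item)
        in_group = covariates[shift.covariate].to_numpy() == shift.level
        beta_eff[in_group, j] += shift.delta

    p = 1.0 / (1.0 + np.exp(-(theta_eff - beta_eff)))
    responses = (rng.random((n, len(items))) < p).astype(float)

    # immediate screen-in items
    screen = {}
    for it in config.screen_in_items:
        rate = np.where(caseness == 1, config.screen_in_rate_case,
                        config.screen_in_rate_noncase)
        screen[it] = (rng.random(n) < rate).astype(float)

    frame = pd.DataFrame(
        np.column_stack([screen[it] for it in config.screen_in_items] + [responses]),
        columns=list(config.screen_in_items) + items,
        index=covariates.index,
    )
    if config.missing_rate > 0:
        drop = rng.random(frame.shape) < config.missing_rate
        frame = frame.mask(drop)

    cohort = Cohort(frame, pd.Series(caseness, index=frame.index, dtype=float),
                    covariates)
    truth = {
        "theta": theta,
        "caseness": caseness,
        "difficulties": dict(zip(items, beta)),
        "config": asdict(config),
    }
    return cohort, truth
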