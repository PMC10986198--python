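"""Configuration models for the synthetic cohort generator and the pipeline.

Everything is a pydantic model so that invalid configurations are rejected,
with the offending field named, before any data are generated.
"""
from __future__ import annotations

import math

from pydantic import BaseModel, Field, field_validator, model_validator

from .constants import LABEL_MISSING, LABEL_MULTIPLE, ORGANS, RACE_LEVELS

_PROB_TOL = 1e-9


def _check_simplex(name: str, values: dict[str, float]) -> None:
    total = sum(values.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} must sum to 1 (got {total!r})")
    if any(v < 0 for v in values.values()):
        raise ValueError(f"{name} entries must be non-negative")


class TruthConfig(BaseModel):
    """Ground-truth generative configuration for the synthetic study cohort.

    Defaults emulate the study population: ~20 000 transplant-related
    campaigns created 2015 through March 2019, race mix 52/17/15/16 percent,
    negative-binomial donation counts with multiplicative race effects on the
    expected amount raised (Black 0.85, Hispanic 0.80 vs the White baseline).
    """

    seed: int = 0
    n_campaigns: int = Field(default=20_000, ge=1)

    race_mix: dict[str, float] = Field(
        default_factory=lambda: {"White": 0.52, "Black": 0.17, "Hispanic": 0.15, "Other": 0.16}
    )
    #: multiplicative effect on the expected amount raised, White baseline 1.
    true_irr_amount: dict[str, float] = Field(
        default_factory=lambda: {"White": 1.0, "Black": 0.85, "Hispanic": 0.80, "Other": 0.95}
    )
    #: multiplicative effect on the expected success rate, White baseline 1.
    true_irr_success: dict[str, float] = Field(
        default_factory=lambda: {"White": 1.0, "Black": 0.88, "Hispanic": 0.82, "Other": 0.95}
    )
    organ_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "kidney": 0.30, "liver": 0.14, "heart": 0.12, "lung": 0.06,
            "pancreas": 0.03, "intestine": 0.02, "bone_marrow": 0.18,
            LABEL_MULTIPLE: 0.05, LABEL_MISSING: 0.10,
        }
    )

    #: NB2 overdispersion of the donation count (Var = mu + alpha * mu^2).
    dispersion_alpha: float = Field(default=0.8, gt=0)

    # Geography of the synthetic gazetteer (planar coordinates by default).
    n_states: int = Field(default=51, ge=1, le=51)
    cities_per_state: int = Field(default=8, ge=1)
    max_zips_per_city: int = Field(default=3, ge=1)
    #: fraction of cities with exactly one zip; calibrates the share of
    #: campaigns with multiple candidate race/ethnicity outcomes (~7%).
    single_zip_fraction: float = Field(default=0.7, ge=0, le=1)
    hospital_fraction: float = Field(default=0.3, ge=0, le=1)
    geometry: str = Field(default="planar", pattern="^(planar|spherical)$")

    panel_years: tuple[int, int] = (2015, 2019)
    #: fraction of state-race panel cells marked population-insufficient.
    insufficient_fraction: float = Field(default=0.05, ge=0, le=1)

    # Monetary goal: lognormal, median ~$10 000 with an IQR spanning ~5k-25k.
    mean_goal_log: float = math.log(10_000)
    sd_goal_log: float = Field(default=1.0, gt=0)

    # Per-donation amount: lognormal with mean ~$75.
    mean_donation_log: float = math.log(75.0) - 0.125
    sd_donation_log: float = Field(default=0.5, gt=0)

    # Baseline donation-count mean and nuisance covariate effects (log scale).
    base_log_donations: float = math.log(40.0)
    year_effect: float = 0.05          # per year since 2015
    shares_coef: float = 0.004
    shares_sq_coef: float = 0.0
    organizer_effect: float = -0.05    # organizer != beneficiary
    fraud_effect: float = -0.10        # high fraud score
    solid_effect: float = 0.05
    q4_wla_effect: float = 0.05
    q4_unins_effect: float = 0.05
    medicaid_effect: float = -0.05

    # Noise for engagement and fraud fields.
    shares_mean: float = Field(default=20.0, gt=0)
    shares_alpha: float = Field(default=1.0, gt=0)
    organizer_not_beneficiary_rate: float = Field(default=0.2, ge=0, le=1)

    #: name-table fidelity: probability that a zip's argmax equals the truth.
    name_fidelity: float = Field(default=0.9, ge=0, le=1)

    #: fraction of stories carrying a non-clinical organ-mention distractor.
    distractor_fraction: float = Field(default=0.3, ge=0, le=1)

    # Exclusion-rule violation fractions (labeled in the truth table).
    frac_non_us: float = Field(default=0.0, ge=0, le=1)
    frac_invalid: float = Field(default=0.0, ge=0, le=1)
    frac_no_transplant: float = Field(default=0.0, ge=0, le=1)
    frac_outlier: float = Field(default=0.0, ge=0, le=1)

    @field_validator("race_mix", "true_irr_amount", "true_irr_success")
    @classmethod
    def _race_keys(cls, v: dict[str, float], info) -> dict[str, float]:
        if set(v) != set(RACE_LEVELS):
            raise ValueError(f"{info.field_name} must have exactly the keys {RACE_LEVELS}")
        return v

    @field_validator("true_irr_amount", "true_irr_success")
    @classmethod
    def _positive_irrs(cls, v: dict[str, float], info) -> dict[str, float]:
        if any(x <= 0 for x in v.values()):
            raise ValueError(f"{info.field_name} multipliers must be > 0")
        return v

    @field_validator("organ_mix")
    @classmethod
    def _organ_keys(cls, v: dict[str, float]) -> dict[str, float]:
        expected = set(ORGANS) | {LABEL_MULTIPLE, LABEL_MISSING}
        if set(v) != expected:
            raise ValueError(f"organ_mix must have exactly the keys {sorted(expected)}")
        return v

    @model_validator(mode="after")
    def _simplexes(self) -> "TruthConfig":
        _check_simplex("race_mix", self.race_mix)
        _check_simplex("organ_mix", self.organ_mix)
        lo, hi = self.panel_years
        if lo > hi:
            raise ValueError("panel_years must be an increasing range")
        return self


class ExclusionConfig(BaseModel):
    """Parameters of the four-rule exclusion filter."""

    required_word: str = "transplant"
    outlier_quantile: float = Field(default=0.999, gt=0, lt=1)


class RunConfig(BaseModel):
    """Single-file configuration of a full pipeline run."""

    truth: TruthConfig = Field(default_factory=TruthConfig)
    exclusions: ExclusionConfig = Field(default_factory=ExclusionConfig)

    #: fraud scores above this sample quantile flag "high probability of fraud".
    fraud_quantile: float = Field(default=0.9, gt=0, lt=1)
    #: race/ethnicity certainty threshold (strict inequality).
    certainty_threshold: float = Field(default=0.6, gt=0, lt=1)
    #: minimum race-specific state population for the KFF-style restriction.
    min_population: int = Field(default=10_000, ge=0)

    # Query-planner parameters.
    dbscan_eps: float = Field(default=50.0, gt=0)
    dbscan_min_pts: int = Field(default=1, ge=1)
    top_k_cities: int = Field(default=25, ge=1)
    coverage_radius: float = Field(default=100.0, gt=0)

    family: str = Field(default="auto", pattern="^(auto|poisson|negbin)$")
    run_sensitivities: bool = False
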