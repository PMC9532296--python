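"""Model parameters for the FLS cost-effectiveness microsimulation.

The complete input set of the model — demographics, age/gender-stratified
fracture incidence and osteoporosis prevalence, relative risks, the life
table, costs, utilities, alendronate efficacy and persistence, FLS effect
parameters, and economic settings — lives in a single validated
:class:`ModelParameters` tree.  :func:`default_parameters` returns the
published Chinese base case.  Parameter sets round-trip losslessly through
YAML (:func:`save_parameters` / :func:`load_parameters`); partial documents
are merged over the defaults so a config file only needs to state overrides.

All currency values are unit-less 2020 US dollars; rates are annual per
person (incidence and mortality tables are stored per 1000 as printed and
divided down at the point of use).
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

Gender = Literal["F", "M"]
Site = Literal["hip", "vertebral", "wrist"]
SITES: tuple[Site, ...] = ("hip", "vertebral", "wrist")


class AgeRangeError(ValueError):
    """Raised when an age falls outside the bands covered by a table."""


class _Model(BaseModel):
    model_config = ConfigDict(validate_assignment=True)


class AgeBandTable(_Model):
    """Piecewise-constant values over inclusive age bands.

    Bands are ``(lower, upper)`` in whole years, interpreted as the
    closed-open interval ``[lower, upper + 1)`` so that e.g. age 69.5 still
    falls in a "65-69" band; ``upper=None`` marks the open-ended terminal
    band ("90+").  ``values_male=None`` declares a gender-invariant table.
    """

    name: str = ""
    bands: list[tuple[int, Optional[int]]]
    values_female: list[float]
    values_male: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "AgeBandTable":
        if not self.bands:
            raise ValueError("age band table needs at least one band")
        for i, (lo, hi) in enumerate(self.bands):
            last = i == len(self.bands) - 1
            if hi is None and not last:
                raise ValueError("only the terminal band may be open-ended")
            if hi is not None and hi < lo:
                raise ValueError(f"band ({lo}, {hi}) has upper < lower")
            if i > 0:
                prev_hi = self.bands[i - 1][1]
                if prev_hi is None or lo != prev_hi + 1:
                    raise ValueError(
                        f"bands must be contiguous; band {i} starts at {lo}"
                    )
        for label, vals in (("female", self.values_female), ("male", self.values_male)):
            if vals is None:
                continue
            if len(vals) != len(self.bands):
                raise ValueError(f"values_{label} length must match bands")
            if any(v < 0 for v in vals):
                raise ValueError(f"values_{label} must be nonnegative")
        return self

    def lookup(self, age: float, gender: Gender = "F") -> float:
        values = self.values_female
        if gender == "M" and self.values_male is not None:
            values = self.values_male
        for (lo, hi), value in zip(self.bands, values):
            if age >= lo and (hi is None or age < hi + 1):
                return value
        label = self.name or "age band table"
        raise AgeRangeError(f"age {age} outside range of {label!r}")

    @property
    def min_age(self) -> int:
        return self.bands[0][0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (lo, hi) in enumerate(self.bands):
            row = {"age_lower": lo, "age_upper": hi, "female": self.values_female[i]}
            if self.values_male is not None:
                row["male"] = self.values_male[i]
            rows.append(row)
        return pd.DataFrame(rows)


def lookup(table: AgeBandTable, age: float, gender: Gender = "F") -> float:
    """Value of the band containing ``age`` for ``gender`` (band edges inclusive)."""
    return table.lookup(age, gender)


class DemographicParams(_Model):
    start_age: float = 65.0
    proportion_female: float = Field(0.577, ge=0.0, le=1.0)
    max_age: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "DemographicParams":
        if not self.start_age < self.max_age:
            raise ValueError("start_age must be below max_age")
        return self


class FractureRiskParams(_Model):
    incidence: dict[Site, AgeBandTable]
    rr_subsequent_female: float = Field(1.95, ge=1.0)
    rr_subsequent_male: float = Field(3.47, ge=1.0)
    rr_osteoporosis: dict[Site, AgeBandTable]
    attribution: dict[Site, AgeBandTable]
    wrist_asian_adjustment: float = Field(1.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "FractureRiskParams":
        for field_name, tables in (
            ("incidence", self.incidence),
            ("rr_osteoporosis", self.rr_osteoporosis),
            ("attribution", self.attribution),
        ):
            missing = set(SITES) - set(tables)
            if missing:
                raise ValueError(f"{field_name} missing sites: {sorted(missing)}")
        for site, table in self.rr_osteoporosis.items():
            if any(v < 1.0 for v in table.values_female):
                raise ValueError(f"rr_osteoporosis[{site}] must be >= 1")
        for site, table in self.attribution.items():
            vals = table.values_female + (table.values_male or [])
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"attribution[{site}] must lie in [0, 1]")
        return self

    def rr_subsequent(self, gender: Gender) -> float:
        return self.rr_subsequent_female if gender == "F" else self.rr_subsequent_male


class MortalityParams(_Model):
    life_table: AgeBandTable
    excess_rr_female: float = Field(1.91, ge=1.0)
    excess_rr_male: float = Field(2.99, ge=1.0)
    excess_attribution: float = Field(0.25, ge=0.0, le=1.0)
    fls_mortality_or: Optional[float] = Field(None, gt=0.0, le=1.0)

    def excess_rr(self, gender: Gender) -> float:
        return self.excess_rr_female if gender == "F" else self.excess_rr_male


class CostParams(_Model):
    fracture_first_year: dict[Site, float]
    hip_longterm_annual: float = Field(4799.0, ge=0.0)
    nursing_home_probability: float = Field(0.05, ge=0.0, le=1.0)
    drug_per_cycle: float = Field(392.31, ge=0.0)
    dxa_cost: float = Field(87.57, ge=0.0)
    gp_visit_cost: float = Field(10.3, ge=0.0)
    side_effect_gp_visits_first_cycle: float = Field(0.041, ge=0.0)
    side_effect_gp_visits_later_cycle: float = Field(0.021, ge=0.0)
    fls_fee: float = Field(200.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CostParams":
        missing = set(SITES) - set(self.fracture_first_year)
        if missing:
            raise ValueError(f"fracture_first_year missing sites: {sorted(missing)}")
        if any(v < 0 for v in self.fracture_first_year.values()):
            raise ValueError("fracture costs must be nonnegative")
        return self


class SiteMultipliers(_Model):
    first_year: float = Field(..., gt=0.0, le=1.0)
    subsequent_years: float = Field(..., gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "SiteMultipliers":
        if self.first_year > self.subsequent_years:
            raise ValueError("first_year multiplier must not exceed subsequent_years")
        return self


class UtilityParams(_Model):
    baseline: float = Field(0.70, gt=0.0, le=1.0)
    multipliers: dict[Site, SiteMultipliers]

    @model_validator(mode="after")
    def _check(self) -> "UtilityParams":
        missing = set(SITES) - set(self.multipliers)
        if missing:
            raise ValueError(f"multipliers missing sites: {sorted(missing)}")
        return self


class TreatmentParams(_Model):
    efficacy_rr: dict[Site, float]
    max_duration: float = Field(5.0, gt=0.0)
    persistence_schedule: list[tuple[float, float]]

    @model_validator(mode="after")
    def _check(self) -> "TreatmentParams":
        missing = set(SITES) - set(self.efficacy_rr)
        if missing:
            raise ValueError(f"efficacy_rr missing sites: {sorted(missing)}")
        if any(not 0.0 < v <= 1.0 for v in self.efficacy_rr.values()):
            raise ValueError("efficacy_rr values must lie in (0, 1]")
        sched = self.persistence_schedule
        if not sched:
            raise ValueError("persistence_schedule must not be empty")
        times = [t for t, _ in sched]
        fracs = [s for _, s in sched]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("persistence times must be strictly increasing")
        if any(s2 >= s1 for s1, s2 in zip(fracs, fracs[1:])):
            raise ValueError("persistence fractions must be strictly decreasing")
        if any(not 0.0 < s <= 1.0 for s in fracs):
            raise ValueError("persistence fractions must lie in (0, 1]")
        return self


class FLSParams(_Model):
    attendance: float = Field(0.66, ge=0.0, le=1.0)
    initiation_fls: float = Field(0.38, ge=0.0, le=1.0)
    initiation_no_fls: float = Field(0.172, ge=0.0, le=1.0)
    adherence_fls: float = Field(0.57, ge=0.0, le=1.0)
    adherence_no_fls: float = Field(0.341, ge=0.0, le=1.0)


class EconParams(_Model):
    discount_rate_costs: float = Field(0.05, ge=0.0)
    discount_rate_qalys: float = Field(0.05, ge=0.0)
    wtp: float = Field(10500.0, ge=0.0)
    cycle_length: float = Field(0.5, gt=0.0)
    n_patients: int = Field(1_000_000, ge=1)
    seed: int = 0


class ConventionParams(_Model):
    """Structural conventions the source model leaves open; see docs/methods.md."""

    # payoff accrued by a patient dying within a cycle: the full half-year
    # cycle payoff or half of it (mid-cycle death approximation)
    death_cycle_payoff: Literal["full", "half"] = "full"
    # long-term utility for a multi-site fracture history: worst multiplier
    # or product over fractured sites
    longterm_utility_rule: Literal["worst", "multiplicative"] = "worst"
    # cycles the post-fracture excess mortality persists; None = lifetime
    excess_mortality_duration_cycles: Optional[int] = Field(None, ge=1)


class ModelParameters(_Model):
    demographics: DemographicParams
    osteoporosis_prevalence: AgeBandTable
    risk: FractureRiskParams
    mortality: MortalityParams
    costs: CostParams
    utilities: UtilityParams
    treatment: TreatmentParams
    fls: FLSParams
    econ: EconParams
    conventions: ConventionParams = Field(default_factory=ConventionParams)


def _table(name, bands, female, male=None):
    return AgeBandTable(name=name, bands=bands, values_female=female, values_male=male)


# Bands below 65 are not published for the incidence, mortality and RR
# tables; the first band is extended down to age 60 (the same convention the
# source analysis used for the osteoporosis RR at 60-64) so that the
# sensitivity-analysis starting age of 60 is covered.
_HIP_BANDS = [(60, 69), (70, 74), (75, 79), (80, 84), (85, 89), (90, None)]
_VERT_BANDS = [(60, 69), (70, 74), (75, 79), (80, 84), (85, None)]


def default_parameters() -> ModelParameters:
    """The published Chinese base case.

    Osteoporosis attribution defaults to 1.0 everywhere (no adjustment; the
    cited site/age/gender attribution probabilities are not published) and
    the FLS mortality odds ratio is absent (base case excludes a mortality
    effect of FLS).  Wrist incidence is taken as printed, i.e. already
    adjusted to the Asian population (``wrist_asian_adjustment = 1.0``).
    """
    incidence = {
        "hip": _table(
            "hip incidence (per 1000 person-years)",
            _HIP_BANDS,
            [0.96, 2.34, 4.08, 6.44, 6.59, 8.67],
            [0.65, 1.26, 2.37, 5.19, 5.71, 8.35],
        ),
        "vertebral": _table(
            "clinical vertebral incidence (per 1000 person-years)",
            _VERT_BANDS,
            [5.64, 8.74, 12.05, 21.19, 26.89],
            [0.95, 2.26, 4.50, 5.94, 9.54],
        ),
        "wrist": _table(
            "wrist incidence (per 1000 person-years)",
            _HIP_BANDS,
            [12.95, 13.17, 13.87, 15.01, 15.10, 13.97],
            [3.27, 2.79, 3.13, 4.75, 4.78, 3.23],
        ),
    }
    rr_osteoporosis = {
        "hip": _table(
            "osteoporosis RR, hip",
            [(60, 69), (70, 74), (75, 79), (80, 84), (85, None)],
            [3.91, 3.31, 2.6, 2.04, 1.92],
        ),
        "vertebral": _table(
            "osteoporosis RR, vertebral",
            [(60, 69), (70, 79), (80, None)],
            [2.59, 2.15, 1.82],
        ),
        "wrist": _table(
            "osteoporosis RR, wrist",
            [(60, 69), (70, 79), (80, None)],
            [1.78, 1.60, 1.45],
        ),
    }
    attribution = {
        site: _table(f"osteoporosis attribution, {site}", [(60, None)], [1.0])
        for site in SITES
    }
    return ModelParameters(
        demographics=DemographicParams(),
        osteoporosis_prevalence=_table(
            "osteoporosis prevalence (%)",
            [(60, 69), (70, 79), (80, None)],
            [37.1, 51.3, 67.5],
            [5.4, 12.3, 21.9],
        ),
        risk=FractureRiskParams(
            incidence=incidence,
            rr_osteoporosis=rr_osteoporosis,
            attribution=attribution,
        ),
        mortality=MortalityParams(
            life_table=_table(
                "all-cause mortality (per 1000)",
                [(60, 69), (70, 74), (75, 79), (80, 84), (85, 89), (90, 94), (95, 99), (100, None)],
                [13.06, 24.36, 40.89, 73.98, 115.29, 180.24, 219.46, 436.34],
                [21.26, 37.02, 59.13, 98.56, 146.53, 211.66, 212.07, 507.28],
            ),
        ),
        costs=CostParams(
            fracture_first_year={"hip": 11166.0, "vertebral": 6328.0, "wrist": 2162.0},
        ),
        utilities=UtilityParams(
            multipliers={
                "hip": SiteMultipliers(first_year=0.55, subsequent_years=0.86),
                "vertebral": SiteMultipliers(first_year=0.68, subsequent_years=0.85),
                "wrist": SiteMultipliers(first_year=0.83, subsequent_years=0.99),
            },
        ),
        treatment=TreatmentParams(
            efficacy_rr={"hip": 0.67, "vertebral": 0.45, "wrist": 0.81},
            persistence_schedule=[
                (0.5, 0.56),
                (1.0, 0.50),
                (2.0, 0.33),
                (3.0, 0.21),
                (4.0, 0.12),
                (5.0, 0.06),
            ],
        ),
        fls=FLSParams(),
        econ=EconParams(),
    )


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def save_parameters(params: ModelParameters, path: str | Path | None = None) -> str:
    """Serialize a parameter set to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(params.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_parameters(source: str | Path | dict) -> ModelParameters:
    """Load a parameter set from YAML text, a file path, or a mapping.

    Partial documents are merged over :func:`default_parameters`, so a
    configuration file only needs to state the fields it overrides.
    Validation failures raise a ``pydantic.ValidationError`` enumerating
    every violated invariant with its path.
    """
    if isinstance(source, dict):
        data = source
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise TypeError("parameter document must be a mapping")
    merged = _deep_merge(default_parameters().model_dump(mode="json"), data)
    return ModelParameters.model_validate(merged)
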