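"""One-way deterministic sensitivity analysis and perturbed parameter sets.

Each scenario is a named override of the base case touching exactly one
conceptual parameter: the FLS fee doubled and tripled, an FLS mortality
odds ratio of 0.73 or 0.876, FLS attendance and adherence shifted by +-20
absolute percentage points, alternative starting ages and gender mixes,
scaled costs, utilities, efficacy, osteoporosis prevalence, and 3%/0%
discount rates.  Every scenario is re-run with the same seed (common
random numbers across scenarios) so rows differ only through parameters.

:func:`perturbed_parameters` draws randomized but schema-valid parameter
sets around the base case for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .parameters import (
    AgeBandTable,
    ModelParameters,
    SITES,
    SiteMultipliers,
    default_parameters,
)

OverrideOp = Literal["set", "scale", "add", "scale_reduction"]


@dataclass(frozen=True)
class Override:
    """One change to a parameter path.

    ``set`` replaces the value; ``scale`` multiplies (AgeBandTable targets
    have every band value scaled); ``add`` shifts additively (absolute
    percentage points for rates); ``scale_reduction`` rescales a relative
    risk's risk *reduction*, rr -> 1 - value x (1 - rr).  ``cap`` clips the
    result from above.
    """

    path: str
    op: OverrideOp
    value: float
    cap: Optional[float] = None


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    category: str  # "base" | "fls" | "other"
    overrides: tuple[Override, ...] = ()


def _resolve(params: ModelParameters, path: str):
    tokens = path.split(".")
    obj = params
    for token in tokens[:-1]:
        obj = obj[token] if isinstance(obj, dict) else getattr(obj, token)
    return obj, tokens[-1]


def _apply_override(params: ModelParameters, ov: Override) -> None:
    parent, leaf = _resolve(params, ov.path)
    current = parent[leaf] if isinstance(parent, dict) else getattr(parent, leaf)

    def _clip(x: float) -> float:
        return min(x, ov.cap) if ov.cap is not None else x

    if isinstance(current, AgeBandTable):
        if ov.op != "scale":
            raise ValueError(f"only 'scale' applies to table path {ov.path!r}")
        current.values_female = [_clip(v * ov.value) for v in current.values_female]
        if current.values_male is not None:
            current.values_male = [_clip(v * ov.value) for v in current.values_male]
        return
    if ov.op == "set":
        new = ov.value
    elif ov.op == "scale":
        new = current * ov.value
    elif ov.op == "add":
        new = current + ov.value
    elif ov.op == "scale_reduction":
        new = 1.0 - ov.value * (1.0 - current)
    else:  # pragma: no cover
        raise ValueError(f"unknown override op {ov.op!r}")
    new = _clip(new)
    if isinstance(parent, dict):
        parent[leaf] = new
    else:
        setattr(parent, leaf, new)


def apply_scenario(params: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """A deep copy of ``params`` with the scenario's overrides applied.

    The input is never mutated, so reverting a scenario is simply keeping
    the base object.  Any invariant violated by an override surfaces as a
    validation error naming the scenario.
    """
    out = params.model_copy(deep=True)
    try:
        for ov in spec.overrides:
            _apply_override(out, ov)
        return ModelParameters.model_validate(out.model_dump())
    except Exception as exc:
        raise ValueError(f"scenario {spec.name!r} failed validation: {exc}") from exc


BASE_SCENARIO = ScenarioSpec(name="Base case", category="base")


def table2_scenarios(include_initiation: bool = False) -> list[ScenarioSpec]:
    """The printed one-way sensitivity grid: 8 FLS-related + 23 other rows.

    ``include_initiation`` adds the two treatment-initiation scenarios
    (halved / doubled in the FLS pathway) that were run but not tabulated.
    FLS attendance and adherence shifts are absolute percentage points.
    """
    f = lambda name, *ovs: ScenarioSpec(name, "fls", tuple(ovs))
    o = lambda name, *ovs: ScenarioSpec(name, "other", tuple(ovs))
    efficacy = lambda factor: tuple(
        Override(f"treatment.efficacy_rr.{site}", "scale_reduction", factor)
        for site in SITES
    )
    fracture_costs = lambda factor: tuple(
        Override(f"costs.fracture_first_year.{site}", "scale", factor)
        for site in SITES
    )
    discount = lambda rate: (
        Override("econ.discount_rate_costs", "set", rate),
        Override("econ.discount_rate_qalys", "set", rate),
    )
    fls_rows = [
        f("FLS cost +100%", Override("costs.fls_fee", "scale", 2.0)),
        f("FLS cost +200%", Override("costs.fls_fee", "scale", 3.0)),
        f(
            "Lower mortality rate for FLS pathway (OR = 0.73)",
            Override("mortality.fls_mortality_or", "set", 0.73),
        ),
        f(
            "Odds ratio of mortality +20%",
            Override("mortality.fls_mortality_or", "set", 0.876),
        ),
        f("FLS attendance rate -20%", Override("fls.attendance", "add", -0.20)),
        f("FLS attendance rate +20%", Override("fls.attendance", "add", 0.20, cap=1.0)),
        f(
            "Medication adherence in FLS -20%",
            Override("fls.adherence_fls", "add", -0.20),
        ),
        f(
            "Medication adherence in FLS +20%",
            Override("fls.adherence_fls", "add", 0.20, cap=1.0),
        ),
    ]
    if include_initiation:
        fls_rows += [
            f(
                "Treatment initiation in FLS halved",
                Override("fls.initiation_fls", "scale", 0.5),
            ),
            f(
                "Treatment initiation in FLS doubled",
                Override("fls.initiation_fls", "scale", 2.0, cap=1.0),
            ),
        ]
    other_rows = [
        o("Starting age: 60", Override("demographics.start_age", "set", 60.0)),
        o("Starting age: 70", Override("demographics.start_age", "set", 70.0)),
        o("Starting age: 75", Override("demographics.start_age", "set", 75.0)),
        o("Starting age: 80", Override("demographics.start_age", "set", 80.0)),
        o(
            "Proportion of women: 80%",
            Override("demographics.proportion_female", "set", 0.80),
        ),
        o(
            "Proportion of women: 100%",
            Override("demographics.proportion_female", "set", 1.0),
        ),
        o(
            "Proportion of women: 0%",
            Override("demographics.proportion_female", "set", 0.0),
        ),
        o(
            "Proportion of patients entering nursing home +100%",
            Override("costs.nursing_home_probability", "scale", 2.0, cap=1.0),
        ),
        o(
            "Proportion of patients entering nursing home -50%",
            Override("costs.nursing_home_probability", "scale", 0.5),
        ),
        o(
            "Osteoporosis prevalence +20%",
            Override("osteoporosis_prevalence", "scale", 1.2, cap=100.0),
        ),
        o(
            "Osteoporosis prevalence +40%",
            Override("osteoporosis_prevalence", "scale", 1.4, cap=100.0),
        ),
        o(
            "Nursing home cost -50%",
            Override("costs.hip_longterm_annual", "scale", 0.5),
        ),
        o(
            "Nursing home cost +50%",
            Override("costs.hip_longterm_annual", "scale", 1.5),
        ),
        o("Fracture cost -50%", *fracture_costs(0.5)),
        o("Fracture cost +50%", *fracture_costs(1.5)),
        o("Drug cost -50%", Override("costs.drug_per_cycle", "scale", 0.5)),
        o("Drug cost +50%", Override("costs.drug_per_cycle", "scale", 1.5)),
        o(
            "Baseline utility -20%",
            Override("utilities.baseline", "scale", 0.8),
        ),
        o(
            "Baseline utility +20%",
            Override("utilities.baseline", "scale", 1.2, cap=1.0),
        ),
        o("Treatment efficacy -20%", *efficacy(0.8)),
        o("Treatment efficacy +20%", *efficacy(1.2)),
        o("Discount rate: 3%", *discount(0.03)),
        o("Discount rate: 0%", *discount(0.0)),
    ]
    return fls_rows + other_rows


def run_dsa(
    params: ModelParameters,
    scenarios: list[ScenarioSpec],
    n: int,
    seed: int,
    include_base: bool = True,
) -> pd.DataFrame:
    """One common-random-numbers comparison per scenario.

    Returns a table shaped like the published sensitivity analysis: one row
    per scenario with incremental cost, incremental QALY, and the ICER or
    dominance label.
    """
    from .simulate import run_comparison

    rows = []
    todo = ([BASE_SCENARIO] if include_base else []) + list(scenarios)
    for spec in todo:
        scenario_params = apply_scenario(params, spec)
        result = run_comparison(scenario_params, n, seed)
        rows.append(
            {
                "scenario": spec.name,
                "category": spec.category,
                "delta_cost": result.delta_cost,
                "delta_qaly": result.delta_qaly,
                "icer": result.icer,
                "attendance_realized": result.attendance_realized,
                "mean_fee_burden": result.mean_fee_burden,
            }
        )
    return pd.DataFrame(rows)


def perturbed_parameters(
    rng: np.random.Generator,
    spread: float,
    base: Optional[ModelParameters] = None,
    max_retries: int = 20,
) -> ModelParameters:
    """A randomized, schema-valid parameter set around the base case.

    Every strictly positive scalar is multiplied by an independent draw
    from [1 - spread, 1 + spread]; probabilities are clipped to [0, 1],
    relative risks to >= 1, utilities to (0, 1].  Coupled quantities that
    must stay ordered (the persistence curve, per-site utility multiplier
    pairs) share a common factor.  Structural integers (ages, counts) are
    left alone.  Reproducible given the generator state.
    """
    if not 0.0 < spread < 0.5:
        raise ValueError("spread must lie in (0, 0.5)")
    base = base if base is not None else default_parameters()

    def factor() -> float:
        return 1.0 + spread * (2.0 * rng.random() - 1.0)

    def prob(x: float) -> float:
        return float(np.clip(x * factor(), 0.0, 1.0))

    def ratio(x: float) -> float:
        return max(1.0, x * factor())

    def unit(x: float) -> float:
        return float(np.clip(x * factor(), 1e-9, 1.0))

    for _ in range(max_retries):
        p = base.model_copy(deep=True)
        p.demographics.proportion_female = prob(p.demographics.proportion_female)
        for table in p.risk.incidence.values():
            table.values_female = [v * factor() for v in table.values_female]
            table.values_male = [v * factor() for v in table.values_male]
        p.risk.rr_subsequent_female = ratio(p.risk.rr_subsequent_female)
        p.risk.rr_subsequent_male = ratio(p.risk.rr_subsequent_male)
        for table in p.risk.rr_osteoporosis.values():
            table.values_female = [ratio(v) for v in table.values_female]
        prev = p.osteoporosis_prevalence
        prev.values_female = [min(v * factor(), 100.0) for v in prev.values_female]
        prev.values_male = [min(v * factor(), 100.0) for v in prev.values_male]
        life = p.mortality.life_table
        life.values_female = [v * factor() for v in life.values_female]
        life.values_male = [v * factor() for v in life.values_male]
        p.mortality.excess_rr_female = ratio(p.mortality.excess_rr_female)
        p.mortality.excess_rr_male = ratio(p.mortality.excess_rr_male)
        p.mortality.excess_attribution = prob(p.mortality.excess_attribution)
        c = p.costs
        c.fracture_first_year = {
            site: v * factor() for site, v in c.fracture_first_year.items()
        }
        c.hip_longterm_annual *= factor()
        c.nursing_home_probability = prob(c.nursing_home_probability)
        c.drug_per_cycle *= factor()
        c.dxa_cost *= factor()
        c.gp_visit_cost *= factor()
        c.fls_fee *= factor()
        p.utilities.baseline = unit(p.utilities.baseline)
        new_mults = {}
        for site, mult in p.utilities.multipliers.items():
            common = factor()
            subs = min(1.0, mult.subsequent_years * common)
            first = min(subs, mult.first_year * common)
            new_mults[site] = SiteMultipliers(
                first_year=max(first, 1e-9), subsequent_years=max(subs, 1e-9)
            )
        p.utilities.multipliers = new_mults
        p.treatment.efficacy_rr = {
            site: unit(v) for site, v in p.treatment.efficacy_rr.items()
        }
        common = factor()
        p.treatment.persistence_schedule = [
            (t, min(0.999, s * common)) for t, s in p.treatment.persistence_schedule
        ]
        fls = p.fls
        fls.attendance = prob(fls.attendance)
        fls.initiation_fls = prob(fls.initiation_fls)
        fls.initiation_no_fls = prob(fls.initiation_no_fls)
        fls.adherence_fls = prob(fls.adherence_fls)
        fls.adherence_no_fls = prob(fls.adherence_no_fls)
        try:
            return ModelParameters.model_validate(p.model_dump())
        except Exception:
            continue
    raise RuntimeError("could not draw a valid perturbed parameter set")
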