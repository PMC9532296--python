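"""Conversion of published population rates into per-cycle event probabilities.

The model's inputs are annual, population-level rates.  Each 6-month cycle
they are turned into per-individual probabilities in a fixed order, always
composing multiplicative adjustments on the *rate* scale and converting to
a probability exactly once (so any stack of relative risks keeps the
probability in [0, 1]):

fracture:  general-population incidence -> calibration into
osteoporotic / non-osteoporotic rates consistent with prevalence (with the
osteoporosis RR shrunk by the attribution probability) -> x subsequent-
fracture RR (all simulated patients have a recent fracture) -> x current
treatment efficacy RR -> 1 - exp(-rate x cycle length).

death:  life-table rate -> x excess-mortality multiplier
1 + attribution x (RR - 1) after an in-simulation hip or clinical
vertebral fracture -> 1 - exp(-rate x cycle length) -> FLS mortality odds
ratio applied on the odds scale when configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .parameters import Gender, ModelParameters, SITES, Site
from . import treatment as _treatment

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PatientState


def rate_to_cycle_prob(rate, cycle_length: float):
    """1 - exp(-rate x cycle_length); accepts scalars or arrays."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rates must be nonnegative")
    out = -np.expm1(-rate * cycle_length)
    return float(out) if out.ndim == 0 else out


def split_incidence_by_op_status(
    i_general: float, prevalence: float, rr_op: float, attribution: float = 1.0
):
    """Split a general-population incidence rate by osteoporosis status.

    With the effective ratio R = 1 + attribution x (rr_op - 1), returns
    (i_non_op, i_op) such that i_op = R x i_non_op and
    prevalence x i_op + (1 - prevalence) x i_non_op = i_general.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if rr_op < 1.0:
        raise ValueError("osteoporosis RR must be >= 1")
    if not 0.0 <= attribution <= 1.0:
        raise ValueError("attribution must lie in [0, 1]")
    ratio = 1.0 + attribution * (rr_op - 1.0)
    i_non_op = i_general / (1.0 + prevalence * (ratio - 1.0))
    return i_non_op, ratio * i_non_op


def excess_mortality_multiplier(params: ModelParameters, gender: Gender) -> float:
    """1 + excess_attribution x (excess RR - 1), e.g. 1.2275 for females."""
    return 1.0 + params.mortality.excess_attribution * (
        params.mortality.excess_rr(gender) - 1.0
    )


def apply_odds_ratio(p, odds_ratio: float):
    """Transform a probability by an odds ratio: OR p / (1 - p + OR p)."""
    p = np.asarray(p, dtype=float)
    out = odds_ratio * p / (1.0 - p + odds_ratio * p)
    return float(out) if out.ndim == 0 else out


def _site_annual_rate(
    params: ModelParameters, site: Site, age: float, gender: Gender, osteoporotic: bool
) -> float:
    """Annual per-person fracture rate at a site before treatment efficacy."""
    incidence = params.risk.incidence[site].lookup(age, gender) / 1000.0
    if site == "wrist":
        incidence *= params.risk.wrist_asian_adjustment
    prevalence = params.osteoporosis_prevalence.lookup(age, gender) / 100.0
    rr_op = params.risk.rr_osteoporosis[site].lookup(age, gender)
    attribution = params.risk.attribution[site].lookup(age, gender)
    i_non_op, i_op = split_incidence_by_op_status(incidence, prevalence, rr_op, attribution)
    rate = i_op if osteoporotic else i_non_op
    return rate * params.risk.rr_subsequent(gender)


def fracture_cycle_prob(patient: "PatientState", site: Site, params: ModelParameters) -> float:
    """Per-cycle probability that ``patient`` fractures at ``site``."""
    rate = _site_annual_rate(
        params, site, patient.age, patient.gender, patient.pathway.osteoporosis
    )
    rate *= _treatment.efficacy_rr(site, patient.treatment, params)
    return rate_to_cycle_prob(rate, params.econ.cycle_length)


def death_cycle_prob(patient: "PatientState", params: ModelParameters, arm: str) -> float:
    """Per-cycle death probability, with post-fracture excess mortality and,
    in the FLS arm, the optional mortality odds ratio."""
    rate = params.mortality.life_table.lookup(patient.age, patient.gender) / 1000.0
    if patient.has_excess_mortality(params):
        rate *= excess_mortality_multiplier(params, patient.gender)
    p = rate_to_cycle_prob(rate, params.econ.cycle_length)
    orr = params.mortality.fls_mortality_or
    if arm == "FLS" and orr is not None:
        p = apply_odds_ratio(p, orr)
    return p


@dataclass
class CyclePlan:
    """Per-cycle, per-gender scalars precomputed for the simulation horizon.

    ``site_rate[s][t, g, op]`` is the annual fracture rate at site index
    ``s`` during cycle ``t`` for gender ``g`` (0=F, 1=M) and osteoporosis
    status ``op`` (0/1), inclusive of the subsequent-fracture RR but
    exclusive of treatment efficacy.  ``death_rate[t, g]`` is the annual
    life-table rate.  Both the microsimulation engine and the exact cohort
    oracle consume the same plan.
    """

    ages: np.ndarray
    site_rate: np.ndarray  # (3, C, 2, 2)
    death_rate: np.ndarray  # (C, 2)
    excess_mult: np.ndarray  # (2,)

    @classmethod
    def build(cls, params: ModelParameters, n_cycles: int) -> "CyclePlan":
        cl = params.econ.cycle_length
        start = params.demographics.start_age
        ages = start + cl * np.arange(n_cycles)
        genders: tuple[Gender, ...] = ("F", "M")
        site_rate = np.zeros((len(SITES), n_cycles, 2, 2))
        death_rate = np.zeros((n_cycles, 2))
        for t, age in enumerate(ages):
            for g, gender in enumerate(genders):
                death_rate[t, g] = (
                    params.mortality.life_table.lookup(age, gender) / 1000.0
                )
                for s, site in enumerate(SITES):
                    site_rate[s, t, g, 0] = _site_annual_rate(
                        params, site, age, gender, osteoporotic=False
                    )
                    site_rate[s, t, g, 1] = _site_annual_rate(
                        params, site, age, gender, osteoporotic=True
                    )
        excess_mult = np.array(
            [excess_mortality_multiplier(params, g) for g in genders]
        )
        return cls(
            ages=ages,
            site_rate=site_rate,
            death_rate=death_rate,
            excess_mult=excess_mult,
        )
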