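"""Alendronate therapy: persistence, adherence, efficacy, and per-cycle cost.

Initiators start weekly oral alendronate at model entry, for at most five
years.  Adherent initiators discontinue according to the published
time-dependent persistence curve (56% still on therapy at 6 months, 50% at
1 year, ... 6% at 5 years, linearly interpolated at 6-month boundaries);
non-adherent initiators take the drug for exactly one cycle.  After
discontinuation the fracture risk reduction wanes linearly back to none
over a period equal to the time spent on therapy ("offset time").

While on treatment, per-cycle costs comprise the 6-month drug cost plus
amortized monitoring (one GP visit per year, one DXA per two years) and
the expected side-effect GP consultations.  Costs stop at discontinuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters, Site

if False:  # pragma: no cover - import cycle guard, typing only
    from .pathways import Pathway


@dataclass
class TreatmentState:
    initiated: bool = False
    adherent: bool = False
    on_treatment: bool = False
    cycles_on_treatment: int = 0
    cycles_since_stop: int = 0

    def __post_init__(self) -> None:
        if self.on_treatment and not self.initiated:
            raise ValueError("on_treatment requires initiated")
        if self.on_treatment and self.cycles_since_stop != 0:
            raise ValueError("cycles_since_stop must be 0 while on treatment")


def persistence_surviving_fraction(t: float, params: ModelParameters) -> float:
    """S(t): fraction of adherent initiators still on therapy at ``t`` years.

    S(0) = 1, the published knots are honoured exactly, and values between
    knots are linearly interpolated.
    """
    if t < 0:
        raise ValueError("time on treatment must be nonnegative")
    if t > params.treatment.max_duration:
        raise ValueError(
            f"time on treatment {t} exceeds maximum {params.treatment.max_duration}"
        )
    knots_t = [0.0] + [t_ for t_, _ in params.treatment.persistence_schedule]
    knots_s = [1.0] + [s for _, s in params.treatment.persistence_schedule]
    return float(np.interp(t, knots_t, knots_s))


def continuation_probability(cycles_completed: int, params: ModelParameters) -> float:
    """P(on therapy during the next cycle | on therapy through ``cycles_completed``).

    Equals S(t) / S(t - cycle_length) with t = cycles_completed x cycle_length;
    zero once the five-year maximum is reached.
    """
    if cycles_completed < 1:
        raise ValueError("continuation is defined after at least one cycle on therapy")
    cl = params.econ.cycle_length
    max_cycles = int(round(params.treatment.max_duration / cl))
    if cycles_completed >= max_cycles:
        return 0.0
    t = cycles_completed * cl
    return persistence_surviving_fraction(t, params) / persistence_surviving_fraction(
        t - cl, params
    )


def sample_adherence(
    rng: np.random.Generator, pathway: "Pathway", params: ModelParameters
) -> bool:
    """Adherence class of an initiator: Bernoulli(adherence_fls) for FLS
    attenders, Bernoulli(adherence_no_fls) for non-attenders and no-FLS."""
    if not pathway.initiates_treatment:
        raise ValueError("adherence is only defined for treatment initiators")
    p = (
        params.fls.adherence_fls
        if (pathway.arm == "FLS" and pathway.attender)
        else params.fls.adherence_no_fls
    )
    return bool(rng.random() < p)


def efficacy_rr(site: Site, state: TreatmentState, params: ModelParameters) -> float:
    """Current fracture relative risk at ``site`` under the treatment state.

    1 if never initiated or fully offset; the site efficacy RR while on
    treatment; linearly between the two during the offset period, whose
    duration equals the time spent on therapy.
    """
    if not state.initiated:
        return 1.0
    rr = params.treatment.efficacy_rr[site]
    if state.on_treatment:
        return rr
    cl = params.econ.cycle_length
    duration = state.cycles_on_treatment * cl
    elapsed = state.cycles_since_stop * cl
    if duration <= 0 or elapsed >= duration:
        return 1.0
    return rr + (1.0 - rr) * elapsed / duration


def treatment_cycle_cost(
    state: TreatmentState, cycle_index_on_treatment: int, params: ModelParameters
) -> float:
    """Cost of one on-treatment cycle; 0 when off treatment.

    Drug cost per cycle plus amortized monitoring (GP visit / 2 cycles,
    DXA / 4 cycles) plus expected side-effect GP consultations, which are
    higher in the first on-treatment cycle.
    """
    if not state.on_treatment:
        return 0.0
    c = params.costs
    visits = (
        c.side_effect_gp_visits_first_cycle
        if cycle_index_on_treatment == 0
        else c.side_effect_gp_visits_later_cycle
    )
    return (
        c.drug_per_cycle
        + c.gp_visit_cost / 2.0
        + c.dxa_cost / 4.0
        + visits * c.gp_visit_cost
    )
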