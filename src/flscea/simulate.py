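"""The Markov microsimulation engine.

Every simulated patient starts in the "recent fracture" state and advances
in 6-month cycles until death or age 100, transiting between incident
fracture states (hip, clinical vertebral, wrist), their post-fracture
states, and death.  Lifetime fracture counts per site are carried as
tracker variables.  Costs and QALYs are accumulated per cycle, discounted
at annual compounding from model entry.

Within a cycle events happen in a fixed order: death draw first; survivors
draw at most one incident fracture with severity priority hip > vertebral >
wrist; the fracture updates the health state (acute "first-year" states
last two cycles, then the corresponding post-fracture state); payoffs for
the cycle are accrued from the updated state; finally the treatment state
advances (persistence draw, five-year cap, offset clock).

The engine is vectorized across patients.  Randomness is organised for
common random numbers: one block of per-patient uniforms (gender,
attendance, osteoporosis, initiation, adherence, nursing-home entry) and
five per-cycle streams (death, one per fracture site, persistence) are
derived from a single seed and consumed identically by both arms, so arm
differences are driven only by parameter differences, not by sampling
noise.

:func:`cohort_oracle` computes the exact cohort expectation of discounted
cost and QALYs over a short horizon by full enumeration of the state
space, using the same per-cycle probabilities and payoffs; it serves as an
independent check on the Monte-Carlo engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import outcomes as _outcomes
from .parameters import Gender, ModelParameters, SITES, Site
from .pathways import Arm, Pathway, enumerate_pathways
from .risk_engine import CyclePlan, apply_odds_ratio
from .treatment import TreatmentState, treatment_cycle_cost

SITE_INDEX: dict[Site, int] = {site: i for i, site in enumerate(SITES)}


# ---------------------------------------------------------------------------
# scalar per-patient state (spec-level API, oracle, and unit tests)
# ---------------------------------------------------------------------------


@dataclass
class PatientState:
    """Mutable per-individual state, the scalar view of the engine arrays."""

    age: float
    gender: Gender
    pathway: Pathway
    treatment: TreatmentState = field(default_factory=TreatmentState)
    health_state: str = "recent_fracture"
    fracture_counts: dict[Site, int] = field(
        default_factory=lambda: {s: 0 for s in SITES}
    )
    cycles_since_last_fracture: dict[Site, Optional[int]] = field(
        default_factory=lambda: {s: None for s in SITES}
    )
    in_nursing_home: bool = False
    disc_cost: float = 0.0
    disc_qaly: float = 0.0

    def has_excess_mortality(self, params: ModelParameters) -> bool:
        """True after an in-simulation hip or clinical vertebral fracture
        (within the configured persistence window, lifetime by default)."""
        window = params.conventions.excess_mortality_duration_cycles
        for site in ("hip", "vertebral"):
            if self.fracture_counts[site] > 0:
                since = self.cycles_since_last_fracture[site]
                if window is None or (since is not None and since < window):
                    return True
        return False


def cycle_utility(patient: PatientState, params: ModelParameters) -> float:
    """Health-state utility for the current cycle (multiplicative approach).

    Baseline fracture-population utility times: the first-year multiplier of
    the most recent fracture site if any in-simulation fracture occurred
    within the last two cycles; otherwise the long-term multiplier over all
    sites ever fractured (worst multiplier by default); 1 with no
    in-simulation fracture.  The QALY contribution of the cycle is this
    utility times the cycle length, discounted.
    """
    mult = _history_multiplier(
        acute_site=_acute_site(patient),
        ever_mask=sum(
            1 << SITE_INDEX[s] for s in SITES if patient.fracture_counts[s] > 0
        ),
        params=params,
    )
    return params.utilities.baseline * mult


def _acute_site(patient: PatientState) -> Optional[int]:
    best: Optional[tuple[int, int]] = None
    for site in SITES:
        since = patient.cycles_since_last_fracture[site]
        if since is not None and since < 2:
            if best is None or since < best[0]:
                best = (since, SITE_INDEX[site])
    return None if best is None else best[1]


def _history_multiplier(
    acute_site: Optional[int], ever_mask: int, params: ModelParameters
) -> float:
    mults = params.utilities.multipliers
    if acute_site is not None:
        return mults[SITES[acute_site]].first_year
    if ever_mask == 0:
        return 1.0
    subs = [
        mults[SITES[s]].subsequent_years for s in range(len(SITES)) if ever_mask >> s & 1
    ]
    if params.conventions.longterm_utility_rule == "worst":
        return min(subs)
    return math.prod(subs)


def cycle_cost(
    patient: PatientState, event: Optional[Site], params: ModelParameters
) -> float:
    """Undiscounted cost accrued in the current cycle.

    An incident fracture charges half of its first-year cost in each of the
    two acute cycles; nursing-home residents accrue half the annual
    long-term hip cost per cycle outside acute hip cycles; on-treatment
    cycles add the therapy cost.  The one-off FLS fee is charged at entry
    and is not part of this per-cycle amount.
    """
    c = params.costs
    total = 0.0
    acute: Optional[Site] = event
    if acute is None:
        for site in SITES:
            if patient.cycles_since_last_fracture[site] == 1:
                acute = site
    if acute is not None:
        total += c.fracture_first_year[acute] / 2.0
    if patient.in_nursing_home and acute != "hip":
        total += c.hip_longterm_annual / 2.0
    total += treatment_cycle_cost(
        patient.treatment, patient.treatment.cycles_on_treatment, params
    )
    return total


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class ArmRaw:
    """Per-patient outputs of one simulated arm (kept for paired statistics)."""

    arm: Arm
    cost: np.ndarray
    qaly: np.ndarray
    counts: np.ndarray  # (n, 3) lifetime fracture counts per site
    attender: np.ndarray
    fee: float


@dataclass
class ArmResult:
    arm: Arm
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    fractures_per_100: dict[Site, float]
    attendance_realized: float
    mean_fee_burden: float

    @classmethod
    def from_raw(cls, raw: ArmRaw) -> "ArmResult":
        n = raw.cost.size
        attendance = float(raw.attender.mean())
        return cls(
            arm=raw.arm,
            n=n,
            mean_cost=float(raw.cost.mean()),
            mean_qaly=float(raw.qaly.mean()),
            se_cost=float(raw.cost.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
            se_qaly=float(raw.qaly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
            fractures_per_100={
                site: float(raw.counts[:, i].mean() * 100.0)
                for site, i in SITE_INDEX.items()
            },
            attendance_realized=attendance,
            mean_fee_burden=attendance * raw.fee,
        )


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

_N_PATIENT_UNIFORMS = 6  # gender, attendance, osteoporosis, initiation, adherence, nursing
_CYCLE_STREAMS = ("death", "hip", "vertebral", "wrist", "persist")


def horizon_cycles(params: ModelParameters, max_cycles: Optional[int] = None) -> int:
    cl = params.econ.cycle_length
    full = int(
        math.ceil(
            (params.demographics.max_age - params.demographics.start_age) / cl - 1e-9
        )
    )
    return full if max_cycles is None else min(full, max_cycles)


def _pathway_flags(
    arm: Arm,
    params: ModelParameters,
    u: np.ndarray,
    pathway: Optional[Pathway] = None,
):
    n = u.shape[1]
    fls = params.fls
    if pathway is None:
        start_age = params.demographics.start_age
        female = u[0] < params.demographics.proportion_female
        prev_f = params.osteoporosis_prevalence.lookup(start_age, "F") / 100.0
        prev_m = params.osteoporosis_prevalence.lookup(start_age, "M") / 100.0
        prevalence = np.where(female, prev_f, prev_m)
        attender = (u[1] < fls.attendance) if arm == "FLS" else np.zeros(n, dtype=bool)
        op = u[2] < prevalence
        p_init = np.where(attender, fls.initiation_fls, fls.initiation_no_fls)
        initiated = op & (u[3] < p_init)
    else:
        if pathway.arm != arm:
            raise ValueError("pathway arm does not match the simulated arm")
        female = np.full(n, pathway.gender == "F")
        attender = np.full(n, pathway.attender)
        op = np.full(n, pathway.osteoporosis)
        initiated = np.full(n, pathway.initiates_treatment)
    p_adh = np.where(attender, fls.adherence_fls, fls.adherence_no_fls)
    adherent = initiated & (u[4] < p_adh)
    return female, attender, op, initiated, adherent


def _run_arm(
    arm: Arm,
    params: ModelParameters,
    n: int,
    patient_u: np.ndarray,
    cycle_seeds: list[np.random.SeedSequence],
    fee: Optional[float] = None,
    max_cycles: Optional[int] = None,
    pathway: Optional[Pathway] = None,
) -> ArmRaw:
    cl = params.econ.cycle_length
    n_cycles = horizon_cycles(params, max_cycles)
    plan = CyclePlan.build(params, n_cycles)
    rngs = {
        name: np.random.Generator(np.random.PCG64(seed_seq))
        for name, seed_seq in zip(_CYCLE_STREAMS, cycle_seeds)
    }

    female, attender, op, initiated, adherent = _pathway_flags(
        arm, params, patient_u, pathway
    )
    g_idx = (~female).astype(np.intp)  # 0 = female, 1 = male
    op_idx = op.astype(np.intp)

    tp = params.treatment
    rr_site = np.array([tp.efficacy_rr[s] for s in SITES])
    first_mult = np.array([params.utilities.multipliers[s].first_year for s in SITES])
    subs_mult = np.array(
        [params.utilities.multipliers[s].subsequent_years for s in SITES]
    )
    first_cost = np.array([params.costs.fracture_first_year[s] for s in SITES])
    max_tx_cycles = int(round(tp.max_duration / cl))
    # continuation probability after k completed on-treatment cycles, k=1..max
    from .treatment import continuation_probability

    cont = np.zeros(max_tx_cycles + 1)
    for k in range(1, max_tx_cycles + 1):
        cont[k] = continuation_probability(k, params)
    monitoring = params.costs.gp_visit_cost / 2.0 + params.costs.dxa_cost / 4.0
    tx_cost_first = (
        params.costs.drug_per_cycle
        + monitoring
        + params.costs.side_effect_gp_visits_first_cycle * params.costs.gp_visit_cost
    )
    tx_cost_later = (
        params.costs.drug_per_cycle
        + monitoring
        + params.costs.side_effect_gp_visits_later_cycle * params.costs.gp_visit_cost
    )

    excess_window = params.conventions.excess_mortality_duration_cycles
    death_weight = 1.0 if params.conventions.death_cycle_payoff == "full" else 0.5
    worst_rule = params.conventions.longterm_utility_rule == "worst"
    orr = params.mortality.fls_mortality_or if arm == "FLS" else None
    fee_val = params.costs.fls_fee if fee is None else fee
    baseline_u = params.utilities.baseline
    p_nursing = params.costs.nursing_home_probability
    u_nursing = patient_u[5]

    alive = np.ones(n, dtype=bool)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    counts = np.zeros((n, len(SITES)), dtype=np.int32)
    ever = np.zeros((n, len(SITES)), dtype=bool)
    acute_site = np.full(n, -1, dtype=np.int8)
    acute_left = np.zeros(n, dtype=np.int8)
    # excess-mortality countdown: 0 = off, -1 = lifetime, >0 = cycles left
    excess = np.zeros(n, dtype=np.int32)
    nursing = np.zeros(n, dtype=bool)
    on_tx = initiated.copy()
    cycles_on = np.zeros(n, dtype=np.int16)
    stopped = np.zeros(n, dtype=bool)
    stop_cycles = np.zeros(n, dtype=np.int16)  # cycles on therapy at stop
    since_stop = np.zeros(n, dtype=np.int16)

    # one-off FLS fee at entry, attenders only, discount factor 1
    cost += np.where(attender, fee_val, 0.0)

    for t in range(n_cycles):
        u_death = rngs["death"].random(n)
        u_frac = np.stack([rngs[s].random(n) for s in SITES])
        u_persist = rngs["persist"].random(n)
        if not alive.any():
            continue  # keep streams aligned across arms

        df_c = (1.0 + params.econ.discount_rate_costs) ** (-cl * t)
        df_q = (1.0 + params.econ.discount_rate_qalys) ** (-cl * t)

        # (1) death
        death_rate = plan.death_rate[t, g_idx]
        death_rate = np.where(excess != 0, death_rate * plan.excess_mult[g_idx], death_rate)
        p_death = -np.expm1(-death_rate * cl)
        if orr is not None:
            p_death = apply_odds_ratio(p_death, orr)
        dies = alive & (u_death < p_death)
        survives = alive & ~dies

        # (2) at most one incident fracture, severity priority hip > vertebral > wrist
        offset_frac = np.where(
            stopped & (stop_cycles > 0),
            (since_stop + 0.5) / np.maximum(stop_cycles, 1),
            1.0,
        )
        fired = np.zeros((len(SITES), n), dtype=bool)
        for s in range(len(SITES)):
            eff = np.where(on_tx, rr_site[s], 1.0)
            waning = stopped & (offset_frac < 1.0)
            eff = np.where(
                waning, rr_site[s] + (1.0 - rr_site[s]) * offset_frac, eff
            )
            rate = plan.site_rate[s, t, g_idx, op_idx] * eff
            fired[s] = survives & (u_frac[s] < -np.expm1(-rate * cl))
        hip_f = fired[0]
        vert_f = fired[1] & ~fired[0]
        wrist_f = fired[2] & ~fired[0] & ~fired[1]

        # (3) state update from the event
        first_hip = hip_f & ~ever[:, 0]
        for s, mask in enumerate((hip_f, vert_f, wrist_f)):
            if mask.any():
                acute_site[mask] = s
                acute_left[mask] = 2
                counts[mask, s] += 1
                ever[mask, s] = True
        new_excess = hip_f | vert_f
        if new_excess.any():
            excess[new_excess] = -1 if excess_window is None else excess_window
        nursing |= first_hip & (u_nursing < p_nursing)

        # (5a) utility: acute first-year multiplier, else long-term history
        if worst_rule:
            long_mult = np.ones(n)
            for s in range(len(SITES)):
                long_mult = np.where(
                    ever[:, s], np.minimum(long_mult, subs_mult[s]), long_mult
                )
        else:
            long_mult = np.ones(n)
            for s in range(len(SITES)):
                long_mult = np.where(ever[:, s], long_mult * subs_mult[s], long_mult)
        acute_now = acute_left > 0
        mult = np.where(acute_now, first_mult[np.maximum(acute_site, 0)], long_mult)
        q_cycle = baseline_u * mult * cl * df_q
        qaly += np.where(survives, q_cycle, 0.0)
        qaly += np.where(dies, death_weight * q_cycle, 0.0)

        # (5b) costs, survivors only
        c_cycle = np.where(acute_now, first_cost[np.maximum(acute_site, 0)] / 2.0, 0.0)
        nursing_pays = nursing & ~(acute_now & (acute_site == 0))
        c_cycle += np.where(nursing_pays, params.costs.hip_longterm_annual / 2.0, 0.0)
        c_cycle += np.where(
            on_tx, np.where(cycles_on == 0, tx_cost_first, tx_cost_later), 0.0
        )
        cost += np.where(survives, c_cycle * df_c, 0.0)

        # (4) treatment-state update at the cycle boundary
        was_off = stopped & ~on_tx
        completed = cycles_on + 1
        keep = (
            on_tx
            & adherent
            & (completed < max_tx_cycles)
            & (u_persist < cont[np.minimum(completed, max_tx_cycles)])
        )
        stopping = on_tx & ~keep
        cycles_on[on_tx] += 1
        stop_cycles[stopping] = cycles_on[stopping]
        since_stop[stopping] = 0
        stopped[stopping] = True
        on_tx[stopping] = False
        since_stop[was_off] += 1

        # cycle bookkeeping
        acute_left[acute_left > 0] -= 1
        if excess_window is not None:
            excess[excess > 0] -= 1
        alive = survives

    return ArmRaw(
        arm=arm,
        cost=cost,
        qaly=qaly,
        counts=counts,
        attender=attender,
        fee=fee_val,
    )


def _spawn_streams(seed: int | np.random.SeedSequence, n: int):
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    children = seed_seq.spawn(1 + len(_CYCLE_STREAMS))
    rng_patient = np.random.Generator(np.random.PCG64(children[0]))
    patient_u = rng_patient.random((_N_PATIENT_UNIFORMS, n))
    return patient_u, children[1:]


def run_comparison(
    params: ModelParameters,
    n: int,
    seed: int,
    fee: Optional[float] = None,
    max_cycles: Optional[int] = None,
) -> "_outcomes.ComparisonResult":
    """Simulate ``n`` patients per arm under common random numbers.

    The same per-patient uniforms and per-cycle streams are consumed by the
    FLS and no-FLS arms, so the comparison is fully reproducible given
    ``(params, n, seed)`` and incremental results are variance-reduced.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    patient_u, cycle_seeds = _spawn_streams(seed, n)
    fls = _run_arm("FLS", params, n, patient_u, list(cycle_seeds), fee, max_cycles)
    no_fls = _run_arm("NO_FLS", params, n, patient_u, list(cycle_seeds), fee, max_cycles)
    return _outcomes.build_comparison(fls, no_fls, params, seed=seed)


def simulate_patient(
    seed: int | np.random.SeedSequence,
    pathway: Pathway,
    params: ModelParameters,
    arm: Arm,
) -> tuple[float, float, dict[Site, int]]:
    """Simulate a single patient down a fixed decision-tree pathway.

    Returns (discounted cost, discounted QALYs, lifetime fracture counts).
    Identical seeds give identical trajectories.
    """
    patient_u, cycle_seeds = _spawn_streams(seed, 1)
    raw = _run_arm(arm, params, 1, patient_u, list(cycle_seeds), pathway=pathway)
    counts = {site: int(raw.counts[0, i]) for site, i in SITE_INDEX.items()}
    return float(raw.cost[0]), float(raw.qaly[0]), counts


# ---------------------------------------------------------------------------
# exact cohort expectation over a short horizon
# ---------------------------------------------------------------------------

_ORACLE_MAX_CYCLES = 8


def cohort_oracle(
    params: ModelParameters,
    arm: Arm = "NO_FLS",
    n_cycles: int = 8,
    fee: Optional[float] = None,
) -> tuple[float, float]:
    """Exact expected (discounted cost, discounted QALY) per patient.

    Full enumeration of the reachable state space over at most
    ``_ORACLE_MAX_CYCLES`` cycles, mixing over decision-tree pathways and
    adherence classes.  Shares the per-cycle probabilities and payoffs with
    the Monte-Carlo engine but computes the expectation by exhaustive
    branching instead of sampling.
    """
    if n_cycles > _ORACLE_MAX_CYCLES:
        raise ValueError(
            f"cohort_oracle enumerates at most {_ORACLE_MAX_CYCLES} cycles"
        )
    if params.conventions.excess_mortality_duration_cycles is not None:
        raise NotImplementedError(
            "the oracle supports only the lifetime excess-mortality convention"
        )
    n_cycles = min(n_cycles, horizon_cycles(params))
    plan = CyclePlan.build(params, n_cycles)
    total_cost = 0.0
    total_qaly = 0.0
    for pw in enumerate_pathways(arm, params).pathways:
        if pw.probability == 0.0:
            continue
        if pw.initiates_treatment:
            p_adh = (
                params.fls.adherence_fls
                if pw.attender
                else params.fls.adherence_no_fls
            )
            branches = [(True, p_adh), (False, 1.0 - p_adh)]
        else:
            branches = [(False, 1.0)]
        for adherent, p_branch in branches:
            if p_branch == 0.0:
                continue
            c, q = _oracle_single(params, plan, arm, pw, adherent, n_cycles, fee)
            total_cost += pw.probability * p_branch * c
            total_qaly += pw.probability * p_branch * q
    return total_cost, total_qaly


def _oracle_single(
    params: ModelParameters,
    plan: CyclePlan,
    arm: Arm,
    pw: Pathway,
    adherent: bool,
    n_cycles: int,
    fee: Optional[float],
) -> tuple[float, float]:
    cl = params.econ.cycle_length
    g = 0 if pw.gender == "F" else 1
    opi = 1 if pw.osteoporosis else 0
    tp = params.treatment
    rr_site = [tp.efficacy_rr[s] for s in SITES]
    first_cost = [params.costs.fracture_first_year[s] for s in SITES]
    max_tx = int(round(tp.max_duration / cl))
    from .treatment import continuation_probability

    cont = [0.0] + [continuation_probability(k, params) for k in range(1, max_tx + 1)]
    monitoring = params.costs.gp_visit_cost / 2.0 + params.costs.dxa_cost / 4.0
    tx_first = (
        params.costs.drug_per_cycle
        + monitoring
        + params.costs.side_effect_gp_visits_first_cycle * params.costs.gp_visit_cost
    )
    tx_later = (
        params.costs.drug_per_cycle
        + monitoring
        + params.costs.side_effect_gp_visits_later_cycle * params.costs.gp_visit_cost
    )
    death_weight = 1.0 if params.conventions.death_cycle_payoff == "full" else 0.5
    orr = params.mortality.fls_mortality_or if arm == "FLS" else None
    p_nh = params.costs.nursing_home_probability
    base_u = params.utilities.baseline

    def util_mult(acute, ever):
        return _history_multiplier(
            acute_site=None if acute is None else acute[0],
            ever_mask=ever,
            params=params,
        )

    # state: (tx, acute, ever, excess, nursing)
    #   tx: ("n",) | ("on", completed_cycles) | ("off", cycles_at_stop, off_cycles)
    tx0 = ("on", 0) if pw.initiates_treatment else ("n",)
    states: dict[tuple, float] = {(tx0, None, 0, False, False): 1.0}
    exp_cost = (params.costs.fls_fee if fee is None else fee) if pw.attender else 0.0
    exp_qaly = 0.0

    for t in range(n_cycles):
        df_c = (1.0 + params.econ.discount_rate_costs) ** (-cl * t)
        df_q = (1.0 + params.econ.discount_rate_qalys) ** (-cl * t)
        new_states: dict[tuple, float] = {}
        for (tx, acute, ever, excess, nursing), pr in states.items():
            death_rate = plan.death_rate[t, g] * (plan.excess_mult[g] if excess else 1.0)
            p_death = -math.expm1(-death_rate * cl)
            if orr is not None:
                p_death = float(apply_odds_ratio(p_death, orr))
            exp_qaly += (
                pr * p_death * death_weight * base_u * util_mult(acute, ever) * cl * df_q
            )
            p_alive = pr * (1.0 - p_death)
            if p_alive == 0.0:
                continue

            if tx[0] == "on":
                eff = list(rr_site)
            elif tx[0] == "off":
                frac = min((tx[2] + 0.5) / tx[1], 1.0)
                eff = [r + (1.0 - r) * frac for r in rr_site]
            else:
                eff = [1.0, 1.0, 1.0]
            p_site = [
                -math.expm1(-plan.site_rate[s, t, g, opi] * eff[s] * cl)
                for s in range(len(SITES))
            ]
            event_branches = [
                (0, p_site[0]),
                (1, (1.0 - p_site[0]) * p_site[1]),
                (2, (1.0 - p_site[0]) * (1.0 - p_site[1]) * p_site[2]),
                (None, (1.0 - p_site[0]) * (1.0 - p_site[1]) * (1.0 - p_site[2])),
            ]
            for event, p_event in event_branches:
                if p_event == 0.0:
                    continue
                p_branch = p_alive * p_event
                if event == 0 and not ever & 1:
                    nursing_branches = [(True, p_nh), (False, 1.0 - p_nh)]
                else:
                    nursing_branches = [(nursing, 1.0)]
                for nursing2, p_nb in nursing_branches:
                    p_state = p_branch * p_nb
                    if p_state == 0.0:
                        continue
                    if event is not None:
                        acute2 = (event, 2)
                        ever2 = ever | (1 << event)
                        excess2 = excess or event in (0, 1)
                    else:
                        acute2, ever2, excess2 = acute, ever, excess
                    exp_qaly += p_state * base_u * util_mult(acute2, ever2) * cl * df_q
                    c_cycle = 0.0
                    if acute2 is not None:
                        c_cycle += first_cost[acute2[0]] / 2.0
                    if nursing2 and not (acute2 is not None and acute2[0] == 0):
                        c_cycle += params.costs.hip_longterm_annual / 2.0
                    if tx[0] == "on":
                        c_cycle += tx_first if tx[1] == 0 else tx_later
                    exp_cost += p_state * c_cycle * df_c

                    acute3 = (
                        (acute2[0], acute2[1] - 1)
                        if acute2 is not None and acute2[1] > 1
                        else None
                    )
                    if tx[0] == "on":
                        completed = tx[1] + 1
                        if adherent and completed < max_tx:
                            pc = cont[completed]
                            tx_branches = [
                                (("on", completed), pc),
                                (("off", completed, 0), 1.0 - pc),
                            ]
                        else:
                            tx_branches = [(("off", completed, 0), 1.0)]
                    elif tx[0] == "off":
                        off2 = tx[2] + 1
                        nxt = ("off", tx[1], off2) if off2 + 0.5 < tx[1] else ("n",)
                        tx_branches = [(nxt, 1.0)]
                    else:
                        tx_branches = [(("n",), 1.0)]
                    for tx2, p_tx in tx_branches:
                        if p_tx == 0.0:
                            continue
                        key = (tx2, acute3, ever2, excess2, nursing2)
                        new_states[key] = (
                            new_states.get(key, 0.0) + p_state * p_tx
                        )
        states = new_states
    return exp_cost, exp_qaly
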