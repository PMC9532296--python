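"""Decision-tree pathways assigned to each patient before the Markov model.

Before entering the fracture/death simulation every patient is routed down a
decision tree that fixes gender, FLS attendance (FLS arm only), osteoporosis
status at entry, and whether anti-osteoporosis treatment is initiated.
Patients without osteoporosis never initiate treatment.  The FLS arm has
2 genders x {attender, non-attender} x {no OP, OP without treatment, OP with
treatment} = 12 pathways and the no-FLS arm has 6, for 18 in total.

Osteoporosis status is assigned once, from the prevalence band at the
starting age, and is never re-evaluated while the patient ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .parameters import ModelParameters, lookup

Arm = Literal["FLS", "NO_FLS"]
ARMS: tuple[Arm, ...] = ("FLS", "NO_FLS")


@dataclass(frozen=True)
class Pathway:
    arm: Arm
    gender: Literal["F", "M"]
    attender: bool
    osteoporosis: bool
    initiates_treatment: bool
    probability: float

    def __post_init__(self) -> None:
        if self.arm == "NO_FLS" and self.attender:
            raise ValueError("no-FLS patients cannot be FLS attenders")
        if self.initiates_treatment and not self.osteoporosis:
            raise ValueError("patients without osteoporosis do not initiate treatment")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("pathway probability must lie in [0, 1]")


@dataclass
class PathwaySet:
    arm: Arm
    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 12 if self.arm == "FLS" else 6
        if len(self.pathways) != expected:
            raise ValueError(
                f"{self.arm} arm must have {expected} pathways, got {len(self.pathways)}"
            )
        total = math.fsum(p.probability for p in self.pathways)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pathway probabilities sum to {total!r}, not 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": [p.arm for p in self.pathways],
                "gender": [p.gender for p in self.pathways],
                "attender": [p.attender for p in self.pathways],
                "osteoporosis": [p.osteoporosis for p in self.pathways],
                "initiates_treatment": [p.initiates_treatment for p in self.pathways],
                "probability": [p.probability for p in self.pathways],
            }
        )


def enumerate_pathways(arm: Arm, params: ModelParameters) -> PathwaySet:
    """All decision-tree branches of one arm with their probabilities.

    Branch probability = P(gender) x [P(attendance) in the FLS arm]
    x P(osteoporosis | start age, gender) x P(initiation | branch), where
    attenders initiate with ``initiation_fls`` and non-attenders / no-FLS
    patients with ``initiation_no_fls``.
    """
    start_age = params.demographics.start_age
    p_female = params.demographics.proportion_female
    fls = params.fls
    pathways: list[Pathway] = []
    for gender, p_gender in (("F", p_female), ("M", 1.0 - p_female)):
        prevalence = lookup(params.osteoporosis_prevalence, start_age, gender) / 100.0
        attendance_branches = (
            [(True, fls.attendance), (False, 1.0 - fls.attendance)]
            if arm == "FLS"
            else [(False, 1.0)]
        )
        for attender, p_attend in attendance_branches:
            p_init = fls.initiation_fls if attender else fls.initiation_no_fls
            branches = [
                (False, False, 1.0 - prevalence),
                (True, False, prevalence * (1.0 - p_init)),
                (True, True, prevalence * p_init),
            ]
            for osteoporosis, initiates, p_branch in branches:
                pathways.append(
                    Pathway(
                        arm=arm,
                        gender=gender,
                        attender=attender,
                        osteoporosis=osteoporosis,
                        initiates_treatment=initiates,
                        probability=p_gender * p_attend * p_branch,
                    )
                )
    return PathwaySet(arm=arm, pathways=pathways)


def sample_pathway(rng: np.random.Generator, pathway_set: PathwaySet) -> Pathway:
    """Draw one pathway; consumes exactly one uniform from ``rng``."""
    u = rng.random()
    cumulative = 0.0
    for pathway in pathway_set.pathways:
        cumulative += pathway.probability
        if u < cumulative:
            return pathway
    return pathway_set.pathways[-1]
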