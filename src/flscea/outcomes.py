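"""Decision-analytic outputs: ICER, dominance, avoided fractures, fee thresholds.

The primary outcome is the incremental cost-effectiveness ratio between the
FLS and no-FLS strategies, Delta cost / Delta QALY.  A strategy with lower
cost and more QALYs than its comparator is *dominant*; higher cost and
fewer QALYs is *dominated*.  Because the one-off FLS fee enters total cost
linearly (it is charged once, at entry, to attenders only), the maximum fee
at which FLS stays cost-saving (Delta cost = 0) or cost-effective at the
willingness-to-pay threshold (Delta cost = WTP x Delta QALY) is solved in
closed form from a single base run and confirmed by a same-seed rerun.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Union

import numpy as np
import pandas as pd

from .parameters import ModelParameters, SITES, Site

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ArmRaw, ArmResult

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

IcerValue = Union[float, str]


def icer(delta_cost: float, delta_qaly: float) -> IcerValue:
    """ICER or a dominance label.

    ``dominant`` iff Delta cost < 0 and Delta QALY > 0; ``dominated`` iff
    Delta cost > 0 and Delta QALY < 0; ``undefined`` when Delta QALY = 0;
    otherwise the ratio.
    """
    if delta_qaly == 0.0:
        return UNDEFINED
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return DOMINANT
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def fractures_avoided_per_100(
    fls: "ArmResult", no_fls: "ArmResult"
) -> dict[Site, float]:
    """Lifetime fractures avoided by FLS per 100 patients, per site."""
    if fls.n != no_fls.n:
        raise ValueError("arms must simulate the same number of patients")
    return {
        site: no_fls.fractures_per_100[site] - fls.fractures_per_100[site]
        for site in SITES
    }


@dataclass
class ComparisonResult:
    """Two-arm Monte-Carlo comparison under common random numbers."""

    fls: "ArmResult"
    no_fls: "ArmResult"
    delta_cost: float
    delta_qaly: float
    se_delta_cost: float
    se_delta_qaly: float
    icer: IcerValue
    fractures_avoided_per_100: dict[Site, float]
    mean_fee_burden: float  # realized discounted fee per FLS-arm patient
    attendance_realized: float
    fee: float
    n: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "fee": self.fee,
            "fls": {
                "mean_cost": self.fls.mean_cost,
                "mean_qaly": self.fls.mean_qaly,
                "se_cost": self.fls.se_cost,
                "se_qaly": self.fls.se_qaly,
                "fractures_per_100": self.fls.fractures_per_100,
            },
            "no_fls": {
                "mean_cost": self.no_fls.mean_cost,
                "mean_qaly": self.no_fls.mean_qaly,
                "se_cost": self.no_fls.se_cost,
                "se_qaly": self.no_fls.se_qaly,
                "fractures_per_100": self.no_fls.fractures_per_100,
            },
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "se_delta_cost": self.se_delta_cost,
            "se_delta_qaly": self.se_delta_qaly,
            "icer": self.icer,
            "fractures_avoided_per_100": self.fractures_avoided_per_100,
            "mean_fee_burden": self.mean_fee_burden,
            "attendance_realized": self.attendance_realized,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in (self.fls, self.no_fls):
            rows.append(
                {
                    "arm": arm.arm,
                    "mean_cost": arm.mean_cost,
                    "mean_qaly": arm.mean_qaly,
                    "se_cost": arm.se_cost,
                    "se_qaly": arm.se_qaly,
                    **{
                        f"fractures_per_100_{s}": arm.fractures_per_100[s]
                        for s in SITES
                    },
                }
            )
        return pd.DataFrame(rows)


def build_comparison(
    fls_raw: "ArmRaw",
    no_fls_raw: "ArmRaw",
    params: ModelParameters,
    seed: int,
) -> ComparisonResult:
    """Assemble a :class:`ComparisonResult` with paired (CRN) standard errors."""
    from .simulate import ArmResult

    fls = ArmResult.from_raw(fls_raw)
    no_fls = ArmResult.from_raw(no_fls_raw)
    n = fls.n
    d_cost = fls_raw.cost - no_fls_raw.cost
    d_qaly = fls_raw.qaly - no_fls_raw.qaly
    delta_cost = float(d_cost.mean())
    delta_qaly = float(d_qaly.mean())
    return ComparisonResult(
        fls=fls,
        no_fls=no_fls,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        se_delta_cost=float(d_cost.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        se_delta_qaly=float(d_qaly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        icer=icer(delta_cost, delta_qaly),
        fractures_avoided_per_100=fractures_avoided_per_100(fls, no_fls),
        mean_fee_burden=fls.mean_fee_burden,
        attendance_realized=fls.attendance_realized,
        fee=fls_raw.fee,
        n=n,
        seed=seed,
    )


def max_fee_cost_saving(result: ComparisonResult, params: ModelParameters) -> float:
    """Fee f* at which Delta cost(f*) = 0.

    Delta cost is linear in the fee: Delta cost(f) = Delta cost(f0) +
    (a / f0)(f - f0), with a the realized mean discounted fee burden per
    FLS-arm patient at the base fee f0.
    """
    a = result.mean_fee_burden
    if a == 0.0:
        raise ValueError("no finite threshold: realized fee burden is zero")
    f0 = result.fee
    return f0 - result.delta_cost * f0 / a


def max_fee_cost_effective(result: ComparisonResult, params: ModelParameters) -> float:
    """Fee f** at which Delta cost(f**) = WTP x Delta QALY."""
    a = result.mean_fee_burden
    if a == 0.0:
        raise ValueError("no finite threshold: realized fee burden is zero")
    f0 = result.fee
    return f0 + (params.econ.wtp * result.delta_qaly - result.delta_cost) * f0 / a


@dataclass
class ThresholdReport:
    base: ComparisonResult
    fee_cost_saving: float
    fee_cost_effective: float
    confirmed_delta_cost_at_fee_saving: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "fee_base": self.base.fee,
            "delta_cost": self.base.delta_cost,
            "delta_qaly": self.base.delta_qaly,
            "mean_fee_burden": self.base.mean_fee_burden,
            "fee_cost_saving": self.fee_cost_saving,
            "fee_cost_effective": self.fee_cost_effective,
            "confirmed_delta_cost_at_fee_saving": self.confirmed_delta_cost_at_fee_saving,
            "n": self.base.n,
            "seed": self.base.seed,
        }


def solve_fee_thresholds(
    params: ModelParameters,
    n: int,
    seed: int,
    confirm: bool = True,
    base: Optional[ComparisonResult] = None,
) -> ThresholdReport:
    """Solve f* and f** from one base run; optionally confirm f* by rerun.

    The confirmatory rerun repeats the comparison with the same seed at the
    solved cost-saving fee; under common random numbers its Delta cost is
    exactly the linear extrapolation, so it should vanish to floating-point
    precision.
    """
    from .simulate import run_comparison

    if base is None:
        base = run_comparison(params, n, seed)
    f_star = max_fee_cost_saving(base, params)
    f_star2 = max_fee_cost_effective(base, params)
    confirmed = None
    if confirm:
        rerun = run_comparison(params, n, seed, fee=f_star)
        confirmed = rerun.delta_cost
    return ThresholdReport(
        base=base,
        fee_cost_saving=f_star,
        fee_cost_effective=f_star2,
        confirmed_delta_cost_at_fee_saving=confirmed,
    )
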