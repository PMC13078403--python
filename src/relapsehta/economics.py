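"""Discounted costs, QALYs, relapse burden, incremental results and NMB.

Accrual conventions
-------------------
There is no half-cycle correction; instead each quantity is tied to a
well-defined point of the cycle, and both choices are exposed as toggles:

* **Costs** accrue on the occupancy *after* each cycle's transition
  (``Accrual.costs = "end"``).  State costs here are care costs triggered by
  the events of the cycle — a relapse or a treatment cycle is paid for when
  it happens — so they follow the state a person moves into.
* **Utilities** accrue on the occupancy *before* the transition
  (``Accrual.outcomes = "start"``): a cycle's quality of life reflects the
  state in which it is lived.  Full-year utilities contribute one quarter
  per cycle.

Both streams are discounted with the factor of the cycle's start,
``(1 + r)^(-(c - 1)/4)``; the first cycle is undiscounted.

Relapse burden is counted as expected person-cycles spent in the relapse
state (end-of-cycle relapse occupancy summed over the horizon).  Per-cycle
*entries* into relapse remain available on the trace for flow analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .markov import CohortTrace, horizon_cycles, run_cohort
from .parameters import PathwayParams, space_for
from .pathways import Arm, matrix_builder

OccupancyPoint = Literal["start", "end"]


@dataclass(frozen=True)
class Accrual:
    """Which occupancy row each stream accrues on ("start" or "end")."""

    costs: OccupancyPoint = "end"
    outcomes: OccupancyPoint = "start"

    def __post_init__(self) -> None:
        for v in (self.costs, self.outcomes):
            if v not in ("start", "end"):
                raise ValueError(f"accrual point must be 'start' or 'end', got {v!r}")


DEFAULT_ACCRUAL = Accrual()


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Present-value factor of a 1-based cycle at an annual discount rate."""
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    return float((1.0 + annual_rate) ** (-(cycle - 1) / 4.0))


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one arm over one horizon."""

    qalys: float
    costs: float
    relapses: float


@dataclass(frozen=True)
class EconResult:
    """Per-arm and incremental results of one evaluation.

    Incrementals are intervention minus comparator; ``nmb`` is
    ``wtp_per_qaly * d_qalys - d_costs``.  ``savings_per_relapse_avoided``
    is ``None`` when the intervention does not reduce relapse burden.
    """

    model_id: str
    horizon_years: int
    soc: ArmOutcome
    app: ArmOutcome
    wtp_per_qaly: float

    @property
    def d_qalys(self) -> float:
        return self.app.qalys - self.soc.qalys

    @property
    def d_costs(self) -> float:
        return self.app.costs - self.soc.costs

    @property
    def d_relapses(self) -> float:
        return self.app.relapses - self.soc.relapses

    @property
    def nmb(self) -> float:
        return self.wtp_per_qaly * self.d_qalys - self.d_costs

    @property
    def savings_per_relapse_avoided(self) -> float | None:
        if self.d_relapses >= 0:
            return None
        return -self.d_costs / -self.d_relapses


def net_monetary_benefit(d_qalys: float, d_costs: float,
                         wtp_per_qaly: float = 20_000.0) -> float:
    """QALY impact valued at the willingness-to-pay threshold, net of cost."""
    return wtp_per_qaly * d_qalys - d_costs


def accumulate(trace: CohortTrace, params: PathwayParams, arm: Arm,
               accrual: Accrual = DEFAULT_ACCRUAL) -> tuple[float, float, float]:
    """Discounted (qalys, costs, relapses) of one arm's cohort trace.

    The device charge applies per provisioned cycle to the cohort mass alive
    at the cycle's start (everyone alive keeps the device, whatever their
    state; the dead are not charged) and only in the intervention arm.
    """
    space = trace.space
    n = trace.n_cycles
    costs_by_state = np.array([params.state_cost_per_cycle.get(s, 0.0)
                               for s in space.states])
    utils_by_state = np.array([params.utility_full_year.get(s, 0.0)
                               for s in space.states])

    cycles = np.arange(1, n + 1)
    df_cost = (1.0 + params.discount_rate_costs) ** (-(cycles - 1) / 4.0)
    df_out = (1.0 + params.discount_rate_outcomes) ** (-(cycles - 1) / 4.0)

    occ_cost = trace.occupancy[1:] if accrual.costs == "end" else trace.occupancy[:-1]
    occ_out = trace.occupancy[1:] if accrual.outcomes == "end" else trace.occupancy[:-1]

    state_costs = occ_cost @ costs_by_state
    charge = np.zeros(n)
    if arm is Arm.SOC_PLUS_APP and params.app_cost_per_cycle > 0:
        k = min(params.app_active_cycles, n)
        alive = 1.0 - trace.occupancy[:k, space.index("death")]
        charge[:k] = params.app_cost_per_cycle * alive
    costs = float(df_cost @ (state_costs + charge))
    qalys = float(df_out @ (occ_out @ utils_by_state) / 4.0)
    relapses = float(trace.relapse_occupancy.sum())
    return qalys, costs, relapses


def run_arm(model_id: str, params: PathwayParams, arm: Arm,
            horizon_years: int) -> CohortTrace:
    """Cohort trace of one arm over a whole-year horizon."""
    space = space_for(model_id)
    params.validate(space)
    builder = matrix_builder(space, params, arm)
    return run_cohort(space, builder, horizon_cycles(horizon_years))


def evaluate(model_id: str, params: PathwayParams, horizon_years: int,
             accrual: Accrual = DEFAULT_ACCRUAL) -> EconResult:
    """Run both arms and assemble incremental results and NMB."""
    outcomes = {}
    for arm in (Arm.SOC, Arm.SOC_PLUS_APP):
        trace = run_arm(model_id, params, arm, horizon_years)
        q, c, r = accumulate(trace, params, arm, accrual)
        outcomes[arm] = ArmOutcome(qalys=q, costs=c, relapses=r)
    return EconResult(
        model_id=model_id,
        horizon_years=int(horizon_years),
        soc=outcomes[Arm.SOC],
        app=outcomes[Arm.SOC_PLUS_APP],
        wtp_per_qaly=params.wtp_per_qaly,
    )


def population_nmb(result: EconResult, eligible_population: float) -> float:
    """Scale the per-patient NMB to an eligible population count."""
    if eligible_population < 0:
        raise ValueError("eligible_population must be >= 0")
    return result.nmb * eligible_population


def with_price_and_effect(params: PathwayParams, annual_price: float,
                          effect_reduction: float) -> PathwayParams:
    """Copy of ``params`` with a new annual device price and relapse effect."""
    if annual_price < 0:
        raise ValueError("annual price must be >= 0")
    if not 0.0 <= effect_reduction <= 1.0:
        raise ValueError("effect reduction must be in [0, 1]")
    return replace(params,
                   app_cost_per_cycle=annual_price / 4.0,
                   app_effect_multiplier=1.0 - effect_reduction)
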