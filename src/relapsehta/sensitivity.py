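"""One-way sensitivity analysis, two-way price-effect grids, break-even price.

The one-way analysis re-evaluates the model with a single parameter moved to
its published lower then upper limit (all others at base) and ranks
parameters by the larger absolute NMB departure from base — the ordering of
a tornado diagram.  Parameters whose printed limits coincide with the base
value (notably the device price, which the two-way analysis owns) are
skipped.

The two-way threshold analysis maps NMB over a grid of annual device prices
and relapse-rate reductions.  NMB is affine in the annual price for a fixed
effect (the charge applies to a price-independent alive mass), which gives
break-even prices in closed form from evaluations at two prices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import (DEFAULT_ACCRUAL, Accrual, evaluate,
                        with_price_and_effect)
from .parameters import (PathwayParams, SchemaError, SensitivityLimits,
                         get_param, set_param, space_for)

DEFAULT_PRICES = (100.0, 250.0, 350.0, 700.0)
DEFAULT_REDUCTIONS = (0.05, 0.10, 0.15, 0.20)

#: Parameters owned by other analyses, never varied one-way.
OWSA_EXCLUDED = ("app_cost_per_cycle",)


@dataclass(frozen=True)
class OWSAEntry:
    """Tornado bar: one parameter swung to its printed limits."""

    parameter: str
    base_value: float
    lower_value: float
    upper_value: float
    nmb_at_lower: float
    nmb_at_upper: float
    base_nmb: float

    @property
    def spread(self) -> float:
        """Largest absolute NMB departure from base (tornado bar length)."""
        return max(abs(self.nmb_at_lower - self.base_nmb),
                   abs(self.nmb_at_upper - self.base_nmb))


@dataclass(frozen=True)
class OWSAResult:
    """Tornado-ordered one-way sensitivity entries (widest bar first)."""

    model_id: str
    horizon_years: int
    base_nmb: float
    entries: tuple[OWSAEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"parameter": e.parameter, "base_value": e.base_value,
              "lower_value": e.lower_value, "upper_value": e.upper_value,
              "nmb_at_lower": e.nmb_at_lower, "nmb_at_upper": e.nmb_at_upper,
              "base_nmb": e.base_nmb, "spread": e.spread}
             for e in self.entries])


def owsa(model_id: str, params: PathwayParams, limits: SensitivityLimits,
         horizon_years: int, accrual: Accrual = DEFAULT_ACCRUAL) -> OWSAResult:
    """One-way sensitivity analysis over the published parameter limits."""
    space = space_for(model_id)
    base = evaluate(model_id, params, horizon_years, accrual)
    entries = []
    for name in limits.names():
        if name in OWSA_EXCLUDED:
            continue
        lo, hi = limits[name]
        base_value = get_param(space, params, name)  # raises on unknown name
        if lo == hi == base_value:
            continue  # not varied one-way (e.g. structural zeros)
        nmbs = {}
        for bound in (lo, hi):
            varied = set_param(space, params, name, bound)
            nmbs[bound] = evaluate(model_id, varied, horizon_years, accrual).nmb
        entries.append(OWSAEntry(
            parameter=name, base_value=base_value,
            lower_value=lo, upper_value=hi,
            nmb_at_lower=nmbs[lo], nmb_at_upper=nmbs[hi],
            base_nmb=base.nmb))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return OWSAResult(model_id=model_id, horizon_years=int(horizon_years),
                      base_nmb=base.nmb, entries=tuple(entries))


@dataclass(frozen=True)
class ThresholdGrid:
    """NMB over annual price x relapse-rate reduction."""

    model_id: str
    horizon_years: int
    prices_per_annum: tuple[float, ...]
    effect_reductions: tuple[float, ...]
    nmb: np.ndarray  # effects x prices

    def cell(self, effect_reduction: float, price_per_annum: float) -> float:
        i = self.effect_reductions.index(effect_reduction)
        j = self.prices_per_annum.index(price_per_annum)
        return float(self.nmb[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.nmb,
            index=pd.Index([f"{e:.0%} reduction in relapse rates"
                            for e in self.effect_reductions],
                           name="effect"),
            columns=pd.Index([f"{int(p)}" for p in self.prices_per_annum],
                             name="annual_price_gbp"))


def threshold_grid(model_id: str, params: PathwayParams,
                   prices_per_annum=DEFAULT_PRICES,
                   effect_reductions=DEFAULT_REDUCTIONS,
                   horizon_years: int = 1,
                   accrual: Accrual = DEFAULT_ACCRUAL) -> ThresholdGrid:
    """Two-way threshold analysis over device price and relapse reduction."""
    prices = tuple(float(p) for p in prices_per_annum)
    effects = tuple(float(e) for e in effect_reductions)
    if any(p < 0 for p in prices):
        raise ValueError("prices must be >= 0")
    if any(not 0.0 <= e <= 1.0 for e in effects):
        raise ValueError("effect reductions must be in [0, 1]")
    nmb = np.empty((len(effects), len(prices)))
    for i, e in enumerate(effects):
        for j, p in enumerate(prices):
            varied = with_price_and_effect(params, p, e)
            nmb[i, j] = evaluate(model_id, varied, horizon_years, accrual).nmb
    return ThresholdGrid(model_id=model_id, horizon_years=int(horizon_years),
                         prices_per_annum=prices, effect_reductions=effects,
                         nmb=nmb)


NMB_ZERO = "nmb_zero"
COST_NEUTRAL = "cost_neutral"


def breakeven_price(model_id: str, params: PathwayParams,
                    effect_reduction: float, horizon_years: int,
                    criterion: str = NMB_ZERO,
                    accrual: Accrual = DEFAULT_ACCRUAL) -> float:
    """Annual price at which the intervention breaks even.

    ``NMB_ZERO`` solves ``nmb(price) = 0`` (cost-effectiveness frontier);
    ``COST_NEUTRAL`` solves ``d_costs(price) = 0`` (cost-saving frontier).
    Both quantities are affine in the annual price, so two evaluations give
    the root exactly.
    """
    if criterion not in (NMB_ZERO, COST_NEUTRAL):
        raise ValueError(f"unknown criterion {criterion!r}")

    def value(price: float) -> float:
        res = evaluate(model_id, with_price_and_effect(params, price,
                                                       effect_reduction),
                       horizon_years, accrual)
        return res.nmb if criterion == NMB_ZERO else -res.d_costs

    p0, p1 = 0.0, 400.0
    v0, v1 = value(p0), value(p1)
    slope = (v1 - v0) / (p1 - p0)
    if abs(slope) < 1e-12:
        raise SchemaError("degenerate break-even: price has no effect "
                          "(no alive cohort mass is charged)")
    return p0 - v0 / slope
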