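"""Random valid parameter sets and an individual-level microsimulation oracle.

``random_parameter_set`` draws structurally valid parameterisations for
property tests: banded relapse probabilities that do not increase across
bands, utilities ordered abstinence >= treatment >= relapse, non-negative
costs, plausible relative mortality rates.  It is a test instrument, not a
population model.

``microsim`` pushes individual trajectories through exactly the transition
matrices the cohort engine uses, accruing the same discounted costs and
utilities and counting relapse person-cycles, so the Monte-Carlo means
estimate what the deterministic engine computes in expectation — an
independent oracle for the engine/economics arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .economics import DEFAULT_ACCRUAL, Accrual
from .markov import horizon_cycles
from .parameters import BandedRate, PathwayParams, space_for
from .pathways import Arm, build_matrix

_BAND_STARTS = {"aud": (1, 5, 13), "oud": (1, 2, 5, 9)}


def random_parameter_set(model_id: str, seed: int) -> PathwayParams:
    """Structurally valid random parameters, deterministic in ``seed``."""
    space = space_for(model_id)
    rng = np.random.default_rng(seed)

    def draw(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    starts = _BAND_STARTS[space.model_id]
    band_probs = sorted((draw(0.01, 0.5) for _ in starts), reverse=True)
    bands = BandedRate(tuple(zip(starts, band_probs)))

    spontaneous = draw(0.0, 0.05)
    seeking = draw(0.0, 1.0 - spontaneous)
    u_abst, u_treat, u_rel = sorted((draw(0.3, 1.0) for _ in range(3)),
                                    reverse=True)
    treatment = space.treatment_states

    utilities = {"abstinence": u_abst, "relapse": u_rel,
                 **{s: u_treat for s in treatment}}
    costs = {s: draw(0.0, 5000.0) for s in space.transient}
    rrs = {s: draw(0.5, 10.0) for s in space.transient}

    return PathwayParams(
        relapse_rate=bands,
        treatment_seeking=seeking,
        treatment_continuation=draw(0.0, 1.0),
        recovery_after_treatment=draw(0.0, 1.0),
        spontaneous_recovery=spontaneous,
        mortality_rr=rrs,
        prop_male=draw(0.0, 1.0),
        state_cost_per_cycle=costs,
        utility_full_year=utilities,
        baseline_annual_mortality_male=draw(0.0, 0.01),
        baseline_annual_mortality_female=draw(0.0, 0.01),
        discount_rate_costs=draw(0.0, 0.05),
        discount_rate_outcomes=draw(0.0, 0.05),
        app_effect_multiplier=draw(0.5, 1.1),
        app_cost_per_cycle=draw(0.0, 200.0),
        app_active_cycles=int(rng.integers(0, 9)),
    )


@dataclass(frozen=True)
class MicrosimEstimate:
    """Monte-Carlo means and standard errors for one arm and horizon."""

    model_id: str
    arm: Arm
    horizon_years: int
    n_individuals: int
    seed: int
    means: Mapping[str, float]   # qalys, costs, relapses
    ses: Mapping[str, float]

    def within(self, key: str, reference: float, n_se: float = 3.0) -> bool:
        """Is ``reference`` within ``n_se`` standard errors of the mean?"""
        return abs(self.means[key] - reference) <= n_se * max(self.ses[key], 1e-12)


def microsim(model_id: str, params: PathwayParams, arm: Arm,
             horizon_years: int, n_individuals: int, seed: int,
             accrual: Accrual = DEFAULT_ACCRUAL) -> MicrosimEstimate:
    """Simulate individual trajectories through the per-cycle matrices."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    space = space_for(model_id)
    params.validate(space)
    n_cycles = horizon_cycles(horizon_years)
    rng = np.random.default_rng(seed)

    n_states = space.n_states
    start_idx = space.index("abstinence")
    death = space.index("death")
    relapse = space.index("relapse")
    costs_by_state = np.array([params.state_cost_per_cycle.get(s, 0.0)
                               for s in space.states])
    utils_by_state = np.array([params.utility_full_year.get(s, 0.0)
                               for s in space.states])

    states = np.full(n_individuals, start_idx, dtype=np.int64)
    qalys = np.zeros(n_individuals)
    costs = np.zeros(n_individuals)
    relapses = np.zeros(n_individuals)

    for c in range(1, n_cycles + 1):
        tm = build_matrix(space, params, c, arm)
        cum = np.cumsum(tm.matrix, axis=1)
        cum[:, -1] = 1.0  # guard against rounding in the final column
        df_cost = (1.0 + params.discount_rate_costs) ** (-(c - 1) / 4.0)
        df_out = (1.0 + params.discount_rate_outcomes) ** (-(c - 1) / 4.0)

        pre = states
        if arm is Arm.SOC_PLUS_APP and c <= params.app_active_cycles:
            costs += df_cost * params.app_cost_per_cycle * (pre != death)
        if accrual.outcomes == "start":
            qalys += df_out * utils_by_state[pre] / 4.0
        if accrual.costs == "start":
            costs += df_cost * costs_by_state[pre]

        u = rng.random(n_individuals)
        post = np.empty_like(pre)
        for s in range(n_states):
            mask = pre == s
            if mask.any():
                post[mask] = np.searchsorted(cum[s], u[mask], side="right")
        states = post

        if accrual.outcomes == "end":
            qalys += df_out * utils_by_state[post] / 4.0
        if accrual.costs == "end":
            costs += df_cost * costs_by_state[post]
        relapses += (post == relapse)

    samples = {"qalys": qalys, "costs": costs, "relapses": relapses}
    means = {k: float(v.mean()) for k, v in samples.items()}
    ses = {k: float(v.std(ddof=1) / np.sqrt(n_individuals))
           if n_individuals > 1 else 0.0
           for k, v in samples.items()}
    return MicrosimEstimate(model_id=space.model_id, arm=arm,
                            horizon_years=int(horizon_years),
                            n_individuals=int(n_individuals), seed=int(seed),
                            means=means, ses=ses)
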