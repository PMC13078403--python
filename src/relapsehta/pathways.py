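"""Per-cycle transition matrices for the alcohol and opioid pathways.

Both models share a skeleton: an abstinent cohort faces a banded relapse
risk; people in relapse may seek treatment, recover spontaneously, or stay
relapsed; treatment has a first phase followed by either continuation or
dropout back to relapse; completing (or, for opioids, leaving maintenance
by) treatment returns people to abstinence.  Death is possible from every
state via state-specific relative mortality rates applied to a sex-blended
baseline.

Competing-risk rule: death is applied first each cycle at the state's
per-cycle probability ``q_s``; the printed transition probabilities are
conditional on surviving the cycle and are scaled by ``1 - q_s``, so every
row is stochastic by construction.

The intervention arm multiplies the relapse transition (and, through hooks
that default to 1, the treatment-seeking and recovery transitions) during
the provisioned cycles only — the device is supplied for the first year of
abstinence and is not re-issued.
"""

from __future__ import annotations

import enum

import numpy as np

from .markov import MatrixBuilder, TransitionMatrix
from .parameters import (AUD, OUD, BandedRate, ParameterRangeError,
                         PathwayParams, StateSpace, space_for)


class Arm(enum.Enum):
    """Comparator (standard of care) vs intervention arm."""

    SOC = "soc"
    SOC_PLUS_APP = "soc_plus_app"


def relapse_band_lookup(rate: BandedRate, cycle: int) -> float:
    """Relapse probability of the band containing ``cycle``."""
    return rate.at(cycle)


def _effect(params: PathwayParams, cycle: int, arm: Arm,
            multiplier: float) -> float:
    if arm is Arm.SOC_PLUS_APP and cycle <= params.app_active_cycles:
        return multiplier
    return 1.0


def _conditional_rows(space: StateSpace, params: PathwayParams, cycle: int,
                      arm: Arm) -> np.ndarray:
    """Transition rows conditional on surviving the cycle (death column 0)."""
    if cycle < 1:
        raise ParameterRangeError(f"cycle must be >= 1, got {cycle}")
    a = relapse_band_lookup(params.relapse_rate, cycle)
    a *= _effect(params, cycle, arm, params.app_effect_multiplier)
    if a > 1.0:
        raise ParameterRangeError(
            f"cycle {cycle}: relapse probability {a} exceeds 1 after applying "
            "the effect multiplier")
    # Hook multipliers are clipped at the probability ceiling: the base rates
    # already sit at or near 1 and the published sensitivity range (0.8-1.2)
    # is interpreted as "up to certainty".
    b = min(params.treatment_seeking
            * _effect(params, cycle, arm, params.seeking_effect_multiplier), 1.0)
    d = min(params.recovery_after_treatment
            * _effect(params, cycle, arm, params.recovery_effect_multiplier), 1.0)
    c = params.treatment_continuation
    e = params.spontaneous_recovery
    if b + e > 1.0 + 1e-12:
        raise ParameterRangeError(
            f"cycle {cycle}: treatment-seeking + spontaneous recovery "
            f"= {b + e} exceeds 1")

    idx = {s: i for i, s in enumerate(space.states)}
    n = space.n_states
    rows = np.zeros((n, n))
    A, R = idx["abstinence"], idx["relapse"]
    t1, t2 = (idx[s] for s in space.treatment_states)

    rows[A, R] = a
    rows[A, A] = 1.0 - a
    rows[R, t1] = b
    rows[R, A] = e
    rows[R, R] = 1.0 - b - e
    if space.model_id == AUD:
        # treatment_start -> continuation or dropout to relapse;
        # continuation -> recovered (abstinent) or relapse.
        rows[t1, t2] = c
        rows[t1, R] = 1.0 - c
        rows[t2, A] = d
        rows[t2, R] = 1.0 - d
    else:
        # msw -> moud or relapse; moud -> abstinence or stay on maintenance
        # (no relapse from maintenance).
        rows[t1, t2] = c
        rows[t1, R] = 1.0 - c
        rows[t2, A] = d
        rows[t2, t2] = 1.0 - d
    death = idx["death"]
    rows[death, death] = 1.0
    return rows


def cycle_mortality(space: StateSpace, params: PathwayParams) -> np.ndarray:
    """Per-cycle death probability by state (0 for the death state itself)."""
    q0 = params.baseline_cycle_mortality()
    q = np.zeros(space.n_states)
    for s in space.transient:
        q[space.index(s)] = min(params.mortality_rr[s] * q0, 1.0)
    return q


def build_matrix(space: StateSpace, params: PathwayParams, cycle: int,
                 arm: Arm) -> TransitionMatrix:
    """Row-stochastic matrix for one cycle of either model and arm."""
    rows = _conditional_rows(space, params, cycle, arm)
    q = cycle_mortality(space, params)
    death = space.index("death")
    m = rows * (1.0 - q)[:, None]
    m[:, death] += q
    m[death] = 0.0
    m[death, death] = 1.0
    return TransitionMatrix(cycle_index=cycle, matrix=m)


def aud_matrix(params: PathwayParams, cycle: int, arm: Arm) -> TransitionMatrix:
    return build_matrix(space_for(AUD), params, cycle, arm)


def oud_matrix(params: PathwayParams, cycle: int, arm: Arm) -> TransitionMatrix:
    return build_matrix(space_for(OUD), params, cycle, arm)


def matrix_builder(space: StateSpace, params: PathwayParams,
                   arm: Arm) -> MatrixBuilder:
    """Builder closure for :func:`relapsehta.markov.run_cohort`."""
    def build(cycle: int) -> TransitionMatrix:
        return build_matrix(space, params, cycle, arm)
    return build
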