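"""Deterministic cohort engine.

Propagates expected state occupancy of a closed cohort through per-cycle
row-stochastic transition matrices supplied by a builder, recording the
expected mass flowing into the relapse state each cycle.  The engine is
model-agnostic: everything pathway-specific lives in the matrix builder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .parameters import StateSpace

ROW_SUM_TOL = 1e-12


class MatrixError(ValueError):
    """A transition matrix is malformed (names state and cycle)."""


@dataclass(frozen=True)
class TransitionMatrix:
    """One cycle's row-stochastic matrix over the model's states."""

    cycle_index: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise MatrixError(f"cycle {self.cycle_index}: matrix must be square")

    def validate(self, space: StateSpace) -> None:
        m = self.matrix
        if m.shape[0] != space.n_states:
            raise MatrixError(
                f"cycle {self.cycle_index}: expected {space.n_states} states")
        neg = np.argwhere((m < 0) | (m > 1))
        if neg.size:
            i, j = neg[0]
            raise MatrixError(
                f"cycle {self.cycle_index}: entry {space.states[i]}->"
                f"{space.states[j]} = {m[i, j]} outside [0, 1]")
        sums = m.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            s = bad[0]
            raise MatrixError(
                f"cycle {self.cycle_index}: row {space.states[s]} sums to "
                f"{sums[s]!r}, not 1")
        for name in space.absorbing:
            i = space.index(name)
            row = np.zeros(space.n_states)
            row[i] = 1.0
            if not np.array_equal(m[i], row):
                raise MatrixError(
                    f"cycle {self.cycle_index}: absorbing state {name} must "
                    "have an identity row")


MatrixBuilder = Callable[[int], TransitionMatrix]


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over cycles plus per-cycle relapse inflow.

    ``occupancy`` has ``n_cycles + 1`` rows; row 0 is the initial
    distribution and row ``c`` the distribution after cycle ``c``.
    ``relapse_entries[c-1]`` is the expected mass entering the relapse state
    during cycle ``c`` from any other state (re-entries count again).
    """

    space: StateSpace
    occupancy: np.ndarray
    relapse_entries: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def relapse_occupancy(self) -> np.ndarray:
        """Relapse-state mass at the end of each cycle (person-cycle weights)."""
        return self.occupancy[1:, self.space.index("relapse")]

    @property
    def death_occupancy(self) -> np.ndarray:
        return self.occupancy[:, self.space.index("death")]

    def alive_at_cycle_start(self, cycle: int) -> float:
        """Surviving cohort mass when cycle ``cycle`` (1-based) begins."""
        return 1.0 - self.occupancy[cycle - 1, self.space.index("death")]


def horizon_cycles(years: int) -> int:
    """Number of 3-month cycles in a whole-year horizon."""
    if years < 1:
        raise ValueError(f"horizon must be a positive number of years, got {years}")
    return 4 * int(years)


def run_cohort(space: StateSpace, builder: MatrixBuilder, n_cycles: int,
               initial: Sequence[float] | None = None) -> CohortTrace:
    """Propagate the cohort for ``n_cycles`` cycles.

    ``initial`` defaults to the whole cohort in abstinence.  Each cycle's
    matrix is validated (row-stochastic, entries in [0, 1], absorbing rows
    identity) before use.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    n = space.n_states
    if initial is None:
        start = np.zeros(n)
        start[space.index("abstinence")] = 1.0
    else:
        start = np.asarray(initial, dtype=float)
        if start.shape != (n,):
            raise ValueError("initial distribution has wrong length")
        if np.any(start < 0) or abs(start.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must be non-negative and sum to 1")

    occ = np.empty((n_cycles + 1, n))
    occ[0] = start
    entries = np.empty(n_cycles)
    r = space.index("relapse")
    for c in range(1, n_cycles + 1):
        tm = builder(c)
        if tm.cycle_index != c:
            raise MatrixError(f"builder returned cycle {tm.cycle_index} for {c}")
        tm.validate(space)
        m = tm.matrix
        occ[c] = occ[c - 1] @ m
        inflow = occ[c - 1] @ m[:, r]
        entries[c - 1] = inflow - occ[c - 1, r] * m[r, r]
    return CohortTrace(space=space, occupancy=occ, relapse_entries=entries)
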