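"""Time-inhomogeneous cohort state-transition engine.

The engine is deliberately generic: a model is a list of expanded state names,
a rule mapping cycle index to a row-stochastic transition matrix, and a value
map assigning a monthly cost (EUR) and an annual utility weight to each state.
Tunnel states (one compartment per month of residence) are produced by
:func:`expand_tunnels`; the model-specific wiring lives in
:mod:`psma_cua.models`.

Accrual conventions: monthly cycles; a cycle's value uses the life-table
within-cycle correction (mean of start- and end-of-cycle occupancy) by
default; the discount factor for cycle ``c`` (the cycle ending at month
``c``) is ``(1 + r)^(−c/12)`` for an annual rate ``r``; utilities are annual
QALY weights credited at 1/12 per monthly cycle; totals are reported per
patient (divided by cohort size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace", "TransitionRule", "CohortTrace", "ValueMap", "EconOutcome",
    "expand_tunnels", "run_cohort", "accrue",
]

_ROW_TOL = 1e-12


class ModelDefinitionError(ValueError):
    """A generated transition matrix violates the stochasticity contract."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered health states, optional tunnel bounds, and absorbing states."""

    states: tuple
    tunnels: Mapping[str, int] = field(default_factory=dict)
    absorbing: frozenset = frozenset()

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ValueError("state names must be unique")
        for s, bound in self.tunnels.items():
            if s not in self.states:
                raise ValueError(f"tunnel state {s!r} not in state list")
            if bound < 1:
                raise ValueError(f"tunnel bound for {s!r} must be >= 1")
        for s in self.absorbing:
            if s not in self.states:
                raise ValueError(f"absorbing state {s!r} not in state list")


def expand_tunnels(space: StateSpace) -> list[str]:
    """Expand tunnel states into per-month compartments ``name[1]..name[bound]``.

    Non-tunnelled states map one-to-one; a bound of 1 yields a single
    compartment equivalent to an untunnelled state.
    """
    out: list[str] = []
    for s in space.states:
        bound = space.tunnels.get(s, 0)
        if bound:
            out.extend(f"{s}[{j}]" for j in range(1, bound + 1))
        else:
            out.append(s)
    return out


# A TransitionRule maps a cycle index to an (S x S) row-stochastic matrix.
TransitionRule = Callable[[int], np.ndarray]


@dataclass
class CohortTrace:
    """State occupancy (cohort counts) at every cycle boundary 0..N."""

    occupancy: np.ndarray         # shape (n_cycles + 1, n_states)
    states: tuple

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != len(self.states):
            raise ValueError("occupancy must be (cycles+1, n_states)")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    def state_occupancy(self, name: str) -> np.ndarray:
        """Occupancy summed over the compartments of a (possibly tunnelled) state."""
        cols = [i for i, s in enumerate(self.states)
                if s == name or s.startswith(f"{name}[")]
        if not cols:
            raise KeyError(name)
        return self.occupancy[:, cols].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.index.name = "cycle"
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path)


@dataclass
class ValueMap:
    """Per-state monthly cost (EUR) and annual utility weight."""

    costs: Mapping[str, float]
    utilities: Mapping[str, float]

    def __post_init__(self):
        for s, c in self.costs.items():
            if c < 0:
                raise ValueError(f"cost for {s!r} must be >= 0")
        for s, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for {s!r} must lie in [0, 1]")

    def vectors(self, states: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Cost/utility vectors over expanded states; tunnel compartments
        inherit the base state's values unless given explicitly."""
        cost = np.empty(len(states))
        util = np.empty(len(states))
        for i, s in enumerate(states):
            base = s.split("[", 1)[0]
            try:
                cost[i] = self.costs.get(s, self.costs[base])
                util[i] = self.utilities.get(s, self.utilities[base])
            except KeyError:
                raise KeyError(f"no cost/utility defined for state {s!r}") from None
        return cost, util


@dataclass
class EconOutcome:
    """Discounted per-patient totals for one strategy."""

    total_cost: float
    total_qaly: float
    trace: CohortTrace
    label: str = ""

    def to_dict(self) -> dict:
        return {"strategy": self.label, "cost": self.total_cost, "qaly": self.total_qaly}

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_cohort(rule: TransitionRule, init: np.ndarray, n_cycles: int,
               states: Sequence[str]) -> CohortTrace:
    """Propagate the cohort: ``occupancy(c+1) = occupancy(c) @ matrix(c)``.

    Every matrix row must sum to 1 within 1e−12 with entries in [0, 1];
    violations raise :class:`ModelDefinitionError` naming cycle and state.
    """
    init = np.asarray(init, dtype=float)
    S = len(states)
    if init.shape != (S,):
        raise ValueError("init occupancy length must match state count")
    occ = np.empty((n_cycles + 1, S))
    occ[0] = init
    for c in range(n_cycles):
        M = np.asarray(rule(c), dtype=float)
        if M.shape != (S, S):
            raise ModelDefinitionError(f"cycle {c}: matrix shape {M.shape} != ({S},{S})")
        rows = M.sum(axis=1)
        bad = np.where(np.abs(rows - 1.0) > 1e-9)[0]
        if bad.size:
            raise ModelDefinitionError(
                f"cycle {c}: row for state {states[bad[0]]!r} sums to {rows[bad[0]]!r}")
        if np.any(M < -_ROW_TOL) or np.any(M > 1 + 1e-9):
            i = np.argwhere((M < -_ROW_TOL) | (M > 1 + 1e-9))[0]
            raise ModelDefinitionError(
                f"cycle {c}: entry {states[i[0]]!r}->{states[i[1]]!r} outside [0,1]")
        occ[c + 1] = occ[c] @ M
    return CohortTrace(occ, tuple(states))


def discount_factors(n_cycles: int, annual_rate: float) -> np.ndarray:
    """Factors for cycles 1..N: ``(1+r)^(−c/12)`` with monthly cycles."""
    c = np.arange(1, n_cycles + 1, dtype=float)
    return np.power(1.0 + annual_rate, -c / 12.0)


def accrue(trace: CohortTrace, values: ValueMap, annual_discount: float = 0.03,
           correction: str = "life_table", label: str = "") -> EconOutcome:
    """Discounted cost and QALY totals per patient from a cohort trace.

    ``correction`` selects the occupancy credited to each cycle:
    ``life_table`` (mean of start and end, the recommended within-cycle
    correction), ``start``, ``end``, or ``none`` (alias of ``end``).
    """
    occ = trace.occupancy
    if correction == "life_table":
        credited = (occ[:-1] + occ[1:]) / 2.0
    elif correction == "start":
        credited = occ[:-1]
    elif correction in ("end", "none"):
        credited = occ[1:]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    cost_vec, util_vec = values.vectors(trace.states)
    disc = discount_factors(trace.n_cycles, annual_discount)
    size = trace.cohort_size
    total_cost = float(disc @ (credited @ cost_vec)) / size
    total_qaly = float(disc @ (credited @ (util_vec / 12.0))) / size
    return EconOutcome(total_cost, total_qaly, trace, label=label)
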