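"""The two cohort models: strategy construction from packaged parameters.

Model I compares PRLT plus standard of care (SoC) against SoC alone as
third-line treatment of metastatic castration-resistant prostate cancer;
each arm has states {treatment (8-month tunnel), stable after treatment,
progression, death} driven by the VISION-trial survival fits. Model II
compares PRLT against cabazitaxel in second line (TheraP-trial fits); after
first progression the cohort splits (base case 75% SoC / 25% PRLT + SoC)
into third-line sub-models replicating Model I's structure and survival
laws.

Transition rule shared by all alive pre-progression states: the per-cycle
death probability is the overall-survival conditional event probability
``1 − S_os(t+1)/S_os(t)``; the progression probability is the full
progression-free-survival conditional event probability (capped at
``1 − p_death`` so rows stay stochastic); staying is the remainder. Death
applies with the same OS-derived probability from every alive state (the
equal-mortality simplification), so the traced death occupancy follows the
input OS law exactly.

Third-line transitions in Model II evaluate the Model I laws on the model
clock (time since model start); this is the convention that reproduces the
published totals. A variant with the survival clock reset to zero at
third-line entry — realised by indexing third-line compartments by months
since entry — is selectable via ``third_line_clock="reset"`` as a structural
sensitivity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .engine import (CohortTrace, EconOutcome, ModelDefinitionError, StateSpace,
                     ValueMap, accrue, expand_tunnels, run_cohort)
from .survival import AnySurvival, conditional_event_prob, distribution_from_dict

__all__ = [
    "ModelConfig", "StrategyModel", "load_parameters", "apply_overrides",
    "transition_probs", "build_model_I", "build_model_II", "build_pair",
]

THIRD_LINE_DURATION = 8   # months of third-line treatment tunnel (both drugs)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def load_parameters(path: str | Path | None = None) -> dict:
    """Load the packaged base-case parameter file, or a user-supplied one."""
    if path is None:
        text = (resources.files("psma_cua") / "data" / "parameters.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def apply_overrides(params: dict, overrides: dict) -> dict:
    """Return a deep copy of ``params`` with dotted-path overrides applied.

    Example: ``{"values.model_I.prlt.treatment.cost": 21303}``.
    """
    out = copy.deepcopy(params)
    for dotted, value in (overrides or {}).items():
        node = out
        *head, leaf = dotted.split(".")
        for part in head:
            if part not in node:
                raise KeyError(f"override path {dotted!r}: no key {part!r}")
            node = node[part]
        if leaf not in node:
            raise KeyError(f"override path {dotted!r}: no key {leaf!r}")
        node[leaf] = value
    return out


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: 60 monthly cycles, 3% discount, 1,000 patients."""

    horizon_cycles: int = 60
    cycle_length_months: float = 1.0
    annual_discount: float = 0.03
    cohort_size: float = 1000.0

    def __post_init__(self):
        if self.horizon_cycles < 1:
            raise ValueError("horizon must be >= 1 cycle")
        if self.annual_discount < 0:
            raise ValueError("discount rate must be >= 0")

    @classmethod
    def from_params(cls, params: dict, **overrides) -> "ModelConfig":
        cfg = params.get("config", {})
        kw = dict(
            horizon_cycles=int(cfg.get("horizon_cycles", 60)),
            cycle_length_months=float(cfg.get("cycle_length_months", 1)),
            annual_discount=float(cfg.get("annual_discount", 0.03)),
            cohort_size=float(cfg.get("cohort_size", 1000)),
        )
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def transition_probs(os_law: AnySurvival, pfs_law: AnySurvival, cycle: int,
                     clock_offset: float = 0.0):
    """Per-cycle (p_progress, p_death, p_stay) from the OS and PFS laws.

    With ``t0 = clock_offset + cycle`` and ``t1 = t0 + 1``: death takes the
    OS conditional event probability; progression takes the PFS conditional
    event probability, capped at ``1 − p_death``; staying is the remainder.
    """
    t0 = clock_offset + cycle
    t1 = t0 + 1.0
    p_death = float(conditional_event_prob(os_law, t0, t1))
    p_pfs = float(conditional_event_prob(pfs_law, t0, t1))
    p_progress = min(p_pfs, 1.0 - p_death)
    p_stay = 1.0 - p_progress - p_death
    if not (0.0 <= p_death <= 1.0 and 0.0 <= p_progress <= 1.0 and p_stay >= -1e-12):
        raise ModelDefinitionError(
            f"invalid transition probabilities at t0={t0:g}: "
            f"death={p_death}, progress={p_progress}")
    return p_progress, p_death, max(p_stay, 0.0)


class _CycleProbs:
    """Vectorized per-cycle (p_progress, p_death, p_stay), extended on demand."""

    def __init__(self, os_law, pfs_law, horizon: int):
        self._os, self._pfs = os_law, pfs_law
        self._n = 0
        self._extend(max(int(horizon), 1))

    def _extend(self, n: int):
        grid = np.arange(n + 1, dtype=float)
        ls_os = np.asarray(self._os.log_survival(grid))
        ls_pfs = np.asarray(self._pfs.log_survival(grid))
        p_death = -np.expm1(np.diff(ls_os))
        p_pfs = -np.expm1(np.diff(ls_pfs))
        p_prog = np.minimum(p_pfs, 1.0 - p_death)
        self._death, self._prog = p_death, p_prog
        self._stay = np.maximum(1.0 - p_prog - p_death, 0.0)
        self._n = n

    def __call__(self, cycle: int):
        if cycle >= self._n:
            self._extend(2 * (cycle + 1))
        return self._prog[cycle], self._death[cycle], self._stay[cycle]


# ---------------------------------------------------------------------------
# Strategy container
# ---------------------------------------------------------------------------

@dataclass
class StrategyModel:
    """A fully wired treatment arm ready to run through the engine."""

    name: str
    states: tuple
    init: np.ndarray
    rule: object                    # TransitionRule
    values: ValueMap
    config: ModelConfig
    os_law: AnySurvival = None
    pfs_law: AnySurvival = None

    def run(self, n_cycles: int | None = None) -> CohortTrace:
        n = int(n_cycles if n_cycles is not None else self.config.horizon_cycles)
        return run_cohort(self.rule, self.init, n, self.states)

    def outcome(self, correction: str = "life_table",
                n_cycles: int | None = None) -> EconOutcome:
        trace = self.run(n_cycles)
        return accrue(trace, self.values, self.config.annual_discount,
                      correction=correction, label=self.name)


def _laws(params: dict, model: str, arm: str):
    node = params["survival"][model][arm]
    return distribution_from_dict(node["os"]), distribution_from_dict(node["pfs"])


# ---------------------------------------------------------------------------
# Model I
# ---------------------------------------------------------------------------

_ARM_KEY_I = {"PRLT_SoC": "prlt", "SoC": "soc"}


def build_model_I(arm: str, params: dict | None = None,
                  config: ModelConfig | None = None) -> StrategyModel:
    """Build a Model I arm (``PRLT_SoC`` or ``SoC``)."""
    if arm not in _ARM_KEY_I:
        raise ValueError(f"Model I arm must be one of {sorted(_ARM_KEY_I)}")
    params = params if params is not None else load_parameters()
    config = config or ModelConfig.from_params(params)
    key = _ARM_KEY_I[arm]
    os_law, pfs_law = _laws(params, "model_I", key)
    duration = int(params["treatment_duration"]["prlt" if key == "prlt" else "soc"])

    space = StateSpace(states=("treatment", "stable", "progression", "death"),
                       tunnels={"treatment": duration},
                       absorbing=frozenset({"death"}))
    states = tuple(expand_tunnels(space))
    idx = {s: i for i, s in enumerate(states)}
    S = len(states)

    probs = _CycleProbs(os_law, pfs_law, config.horizon_cycles)

    def rule(cycle: int) -> np.ndarray:
        p_prog, p_death, p_stay = probs(cycle)
        M = np.zeros((S, S))
        for j in range(1, duration + 1):
            row = idx[f"treatment[{j}]"]
            nxt = idx[f"treatment[{j + 1}]"] if j < duration else idx["stable"]
            M[row, nxt] = p_stay
            M[row, idx["progression"]] = p_prog
            M[row, idx["death"]] = p_death
        M[idx["stable"], idx["stable"]] = p_stay
        M[idx["stable"], idx["progression"]] = p_prog
        M[idx["stable"], idx["death"]] = p_death
        M[idx["progression"], idx["death"]] = p_death
        M[idx["progression"], idx["progression"]] = 1.0 - p_death
        M[idx["death"], idx["death"]] = 1.0
        return M

    vals = params["values"]["model_I"][key]
    values = ValueMap(
        costs={"treatment": vals["treatment"]["cost"],
               "stable": vals["stable"]["cost"],
               "progression": vals["progression"]["cost"],
               "death": 0.0},
        utilities={"treatment": vals["treatment"]["utility"],
                   "stable": vals["stable"]["utility"],
                   "progression": vals["progression"]["utility"],
                   "death": 0.0},
    )
    init = np.zeros(S)
    init[idx["treatment[1]"]] = config.cohort_size
    return StrategyModel(arm, states, init, rule, values, config, os_law, pfs_law)


# ---------------------------------------------------------------------------
# Model II
# ---------------------------------------------------------------------------

_ARM_KEY_II = {"PRLT_SoC": "prlt", "CBZ": "cabazitaxel"}


def build_model_II(arm: str, params: dict | None = None,
                   config: ModelConfig | None = None,
                   third_line_clock: str = "model") -> StrategyModel:
    """Build a Model II arm (``PRLT_SoC`` or ``CBZ``).

    Second-line transitions run on the model clock (TheraP fits); upon first
    progression the cohort splits by the configured third-line mix into SoC
    and PRLT sub-models with Model I's structure, values and survival laws.
    ``third_line_clock`` selects whether those laws are evaluated on the
    model clock (``"model"``, the base case) or on a clock reset to zero at
    third-line entry (``"reset"``).
    """
    if arm not in _ARM_KEY_II:
        raise ValueError(f"Model II arm must be one of {sorted(_ARM_KEY_II)}")
    if third_line_clock not in ("model", "reset"):
        raise ValueError("third_line_clock must be 'model' or 'reset'")
    params = params if params is not None else load_parameters()
    config = config or ModelConfig.from_params(params)
    key = _ARM_KEY_II[arm]
    dur2 = int(params["treatment_duration"]["prlt" if key == "prlt" else "cabazitaxel"])
    mix = params["third_line_mix"]
    w_soc, w_prlt = float(mix["soc"]), float(mix["prlt"])
    if abs(w_soc + w_prlt - 1.0) > 1e-9:
        raise ValueError("third-line mixture weights must sum to 1")

    os2, pfs2 = _laws(params, "model_II", key)
    laws3 = {"soc3l": _laws(params, "model_I", "soc"),
             "prlt3l": _laws(params, "model_I", "prlt")}

    if third_line_clock == "model":
        states, init, rule = _model_ii_shared_clock(
            config, dur2, w_soc, w_prlt, os2, pfs2, laws3)
    else:
        states, init, rule = _model_ii_reset_clock(
            config, dur2, w_soc, w_prlt, os2, pfs2, laws3)

    v2 = params["values"]["model_II"][key]
    v3 = params["values"]["model_II"]["third_line"]
    costs = {"treatment2l": v2["treatment"]["cost"],
             "stable2l": v2["stable"]["cost"], "death": 0.0}
    utils = {"treatment2l": v2["treatment"]["utility"],
             "stable2l": v2["stable"]["utility"], "death": 0.0}
    for pfx, node in (("soc3l", v3["soc"]), ("prlt3l", v3["prlt"])):
        for role, vkey in (("treatment", "treatment"), ("stable", "stable"),
                           ("progression", "progression")):
            costs[f"{pfx}_{role}"] = node[vkey]["cost"]
            utils[f"{pfx}_{role}"] = node[vkey]["utility"]
    values = ValueMap(costs=costs, utilities=utils)
    return StrategyModel(arm, tuple(states), init, rule, values, config, os2, pfs2)


def _second_line_rows(M, idx, dur2, cycle, probs2, w_soc, w_prlt,
                      i_soc_entry, i_prlt_entry, i_death):
    p_prog, p_death, p_stay = probs2(cycle)
    for j in range(1, dur2 + 1):
        row = idx[f"treatment2l[{j}]"]
        nxt = idx[f"treatment2l[{j + 1}]"] if j < dur2 else idx["stable2l"]
        M[row, nxt] = p_stay
        M[row, i_soc_entry] = w_soc * p_prog
        M[row, i_prlt_entry] = w_prlt * p_prog
        M[row, i_death] = p_death
    row = idx["stable2l"]
    M[row, row] = p_stay
    M[row, i_soc_entry] = w_soc * p_prog
    M[row, i_prlt_entry] = w_prlt * p_prog
    M[row, i_death] = p_death


def _model_ii_shared_clock(config, dur2, w_soc, w_prlt, os2, pfs2, laws3):
    """Base-case wiring: third-line laws evaluated at time since model start."""
    dur3 = THIRD_LINE_DURATION
    states = [f"treatment2l[{j}]" for j in range(1, dur2 + 1)] + ["stable2l"]
    for pfx in ("soc3l", "prlt3l"):
        states += [f"{pfx}_treatment[{j}]" for j in range(1, dur3 + 1)]
        states += [f"{pfx}_stable", f"{pfx}_progression"]
    states.append("death")
    idx = {s: i for i, s in enumerate(states)}
    S = len(states)
    i_death = idx["death"]
    probs2 = _CycleProbs(os2, pfs2, config.horizon_cycles)
    probs3 = {pfx: _CycleProbs(os3, pfs3, config.horizon_cycles)
              for pfx, (os3, pfs3) in laws3.items()}

    def rule(cycle: int) -> np.ndarray:
        M = np.zeros((S, S))
        _second_line_rows(M, idx, dur2, cycle, probs2, w_soc, w_prlt,
                          idx["soc3l_treatment[1]"], idx["prlt3l_treatment[1]"],
                          i_death)
        for pfx in laws3:
            p_prog, p_death, p_stay = probs3[pfx](cycle)
            for j in range(1, dur3 + 1):
                row = idx[f"{pfx}_treatment[{j}]"]
                nxt = (idx[f"{pfx}_treatment[{j + 1}]"] if j < dur3
                       else idx[f"{pfx}_stable"])
                M[row, nxt] = p_stay
                M[row, idx[f"{pfx}_progression"]] = p_prog
                M[row, i_death] = p_death
            row = idx[f"{pfx}_stable"]
            M[row, row] = p_stay
            M[row, idx[f"{pfx}_progression"]] = p_prog
            M[row, i_death] = p_death
            row = idx[f"{pfx}_progression"]
            M[row, i_death] = p_death
            M[row, row] = 1.0 - p_death
        M[i_death, i_death] = 1.0
        return M

    init = np.zeros(S)
    init[idx["treatment2l[1]"]] = config.cohort_size
    return states, init, rule


def _model_ii_reset_clock(config, dur2, w_soc, w_prlt, os2, pfs2, laws3):
    """Structural alternative: third-line clock restarts at entry.

    Every third-line compartment is indexed by the month of residence since
    entry (treatment months 1..8, then stable from month 9, progression from
    month 2), so the transition rows depend only on that local clock and the
    expanded state count stays bounded by the horizon.
    """
    H = config.horizon_cycles
    dur3 = THIRD_LINE_DURATION
    states = [f"treatment2l[{j}]" for j in range(1, dur2 + 1)] + ["stable2l"]
    for pfx in ("soc3l", "prlt3l"):
        states += [f"{pfx}_treatment[{j}]" for j in range(1, dur3 + 1)]
        states += [f"{pfx}_stable[{j}]" for j in range(dur3 + 1, H + 1)]
        states += [f"{pfx}_progression[{j}]" for j in range(2, H + 1)]
    states.append("death")
    idx = {s: i for i, s in enumerate(states)}
    S = len(states)
    i_death = idx["death"]

    base = np.zeros((S, S))
    for pfx, (os3, pfs3) in laws3.items():
        for j in range(1, dur3 + 1):
            row = idx[f"{pfx}_treatment[{j}]"]
            p_prog, p_death, p_stay = transition_probs(os3, pfs3, 0, float(j - 1))
            stay_name = (f"{pfx}_treatment[{j + 1}]" if j < dur3
                         else f"{pfx}_stable[{j + 1}]")
            base[row, idx.get(stay_name, row)] += p_stay
            base[row, idx.get(f"{pfx}_progression[{j + 1}]", row)] += p_prog
            base[row, i_death] += p_death
        for j in range(dur3 + 1, H + 1):
            row = idx[f"{pfx}_stable[{j}]"]
            p_prog, p_death, p_stay = transition_probs(os3, pfs3, 0, float(j - 1))
            base[row, idx.get(f"{pfx}_stable[{j + 1}]", row)] += p_stay
            base[row, idx.get(f"{pfx}_progression[{j + 1}]", row)] += p_prog
            base[row, i_death] += p_death
        for j in range(2, H + 1):
            row = idx[f"{pfx}_progression[{j}]"]
            p_death = float(conditional_event_prob(os3, j - 1.0, float(j)))
            base[row, idx.get(f"{pfx}_progression[{j + 1}]", row)] += 1.0 - p_death
            base[row, i_death] += p_death
    base[i_death, i_death] = 1.0

    probs2 = _CycleProbs(os2, pfs2, config.horizon_cycles)

    def rule(cycle: int) -> np.ndarray:
        M = base.copy()
        _second_line_rows(M, idx, dur2, cycle, probs2, w_soc, w_prlt,
                          idx["soc3l_treatment[1]"], idx["prlt3l_treatment[1]"],
                          i_death)
        return M

    init = np.zeros(S)
    init[idx["treatment2l[1]"]] = config.cohort_size
    return states, init, rule


def build_pair(model: str, params: dict | None = None,
               config: ModelConfig | None = None, **kwargs):
    """(intervention, comparator) pair: Model ``"I"`` -> (PRLT_SoC, SoC);
    Model ``"II"`` -> (PRLT_SoC, CBZ)."""
    params = params if params is not None else load_parameters()
    if model == "I":
        return (build_model_I("PRLT_SoC", params, config),
                build_model_I("SoC", params, config))
    if model == "II":
        return (build_model_II("PRLT_SoC", params, config, **kwargs),
                build_model_II("CBZ", params, config, **kwargs))
    raise ValueError("model must be 'I' or 'II'")
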