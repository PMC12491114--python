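"""Incremental cost-effectiveness comparison and plane classification."""

from __future__ import annotations

from dataclasses import dataclass

from .engine import EconOutcome

__all__ = ["IncrementalResult", "compare"]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental costs/effects of an intervention against a comparator.

    ``icer`` is numeric (EUR per QALY) only in the north-east and south-west
    quadrants of the cost-effectiveness plane; a cheaper-and-more-effective
    intervention is ``dominant`` (SE), a costlier-and-less-effective one
    ``dominated`` (NW). The ratio is always formed from unrounded totals.
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str | None
    quadrant: str | None

    @property
    def is_dominant(self) -> bool:
        return self.label == DOMINANT

    @property
    def is_dominated(self) -> bool:
        return self.label == DOMINATED

    def summary(self) -> str:
        if self.label == DOMINANT:
            verdict = "intervention dominates"
        elif self.label == DOMINATED:
            verdict = "intervention is dominated"
        elif self.icer is None:
            verdict = "no ICER defined"
        else:
            verdict = f"ICER {self.icer:,.0f} EUR/QALY"
        return (f"Δcost {self.delta_cost:,.0f} EUR, "
                f"Δeffect {self.delta_effect:.4f} QALYs ({verdict})")

    def to_dict(self) -> dict:
        return {"delta_cost": self.delta_cost, "delta_effect": self.delta_effect,
                "icer": self.icer, "label": self.label, "quadrant": self.quadrant}


def compare(intervention, comparator) -> IncrementalResult:
    """Incremental comparison of two strategy outcomes (or (cost, qaly) pairs)."""
    ci, ei = _totals(intervention)
    cc, ec = _totals(comparator)
    dc, de = ci - cc, ei - ec
    quadrant = (("N" if dc > 0 else "S") if dc != 0 else "") + \
               (("E" if de > 0 else "W") if de != 0 else "")
    icer, label = None, None
    if de > 0 and dc < 0:
        label = DOMINANT
    elif de < 0 and dc > 0:
        label = DOMINATED
    elif de != 0:
        icer = dc / de
    elif dc == 0:
        label = "equivalent"
    # de == 0, dc != 0: label-only result, no division
    elif dc > 0:
        label = DOMINATED
    else:
        label = DOMINANT
    return IncrementalResult(dc, de, icer, label, quadrant or None)


def _totals(x):
    if isinstance(x, EconOutcome):
        return x.total_cost, x.total_qaly
    cost, qaly = x
    return float(cost), float(qaly)
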