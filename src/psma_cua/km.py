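"""Pseudo individual-patient data from digitized Kaplan–Meier curves.

Published survival curves only show the product-limit estimate and the
numbers-at-risk table. To refit parametric models one needs patient-level
event/censoring times; the iterative reconstruction scheme of Guyot and
colleagues recovers a pseudo dataset whose Kaplan–Meier estimate passes back
through the digitized coordinates while honouring the risk table: within each
risk-table interval, censoring is spread uniformly, event counts are solved
from the digitized survival drops, and the censoring count is adjusted until
the implied number at risk matches the next table entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["DigitizedKM", "PseudoIPD", "KMCurve", "reconstruct_ipd", "km_estimator"]


class ReconstructionError(ValueError):
    """Digitized curve and risk table cannot be reconciled."""


@dataclass
class PseudoIPD:
    """Patient-level (time, event) records; event 1 = observed, 0 = censored."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if not np.all(np.isin(self.events, [0, 1])):
            raise ValueError("events must be 0 or 1")

    def __len__(self):
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


@dataclass
class DigitizedKM:
    """Digitized survival coordinates plus the numbers-at-risk table.

    Coordinates are snapped monotone non-increasing on construction (running
    minimum) because digitization noise can invert adjacent points, and a
    (0, 1) anchor is prepended if absent.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    total_events: int | None = None
    recipe: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.size == 0:
            raise ValueError("times and survival must be equal-length, non-empty")
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
        if t[0] > 0:
            t = np.insert(t, 0, 0.0)
            s = np.insert(s, 0, 1.0)
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        s[0] = min(s[0], 1.0)
        self.times, self.survival = t, s
        rt = np.asarray(self.risk_times, dtype=float)
        nr = np.asarray(self.n_at_risk, dtype=float)
        if rt.shape != nr.shape or rt.size < 1:
            raise ValueError("risk table must be non-empty with matching lengths")
        if np.any(np.diff(rt) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(nr) > 0):
            raise ValueError("numbers at risk must be non-increasing")
        self.risk_times, self.n_at_risk = rt, nr.astype(int)

    def to_csv(self, points_path, risk_path):
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            points_path, index=False)
        pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk}).to_csv(
            risk_path, index=False)

    @classmethod
    def from_csv(cls, points_path, risk_path, total_events=None) -> "DigitizedKM":
        pts = pd.read_csv(points_path)
        rt = pd.read_csv(risk_path)
        return cls(pts["time"].to_numpy(), pts["survival"].to_numpy(),
                   rt["time"].to_numpy(), rt["n_at_risk"].to_numpy(),
                   total_events=total_events)


class KMCurve:
    """Right-continuous product-limit step function."""

    def __init__(self, times: np.ndarray, survival: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.survival = np.asarray(survival, dtype=float)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, self.times.size - 1)
        out = np.where(np.asarray(t) < self.times[0], 1.0, self.survival[idx])
        return float(out) if out.ndim == 0 else out


def km_estimator(ipd: PseudoIPD) -> KMCurve:
    """Product-limit estimate (censorings after events at tied times)."""
    if len(ipd) == 0:
        raise ValueError("km_estimator requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    return KMCurve(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy())


def reconstruct_ipd(km: DigitizedKM) -> PseudoIPD:
    """Reconstruct pseudo-IPD from digitized coordinates and the risk table.

    Within each risk-table interval censoring times are spread uniformly and
    the censoring count is iteratively adjusted until the implied number at
    risk at the next risk time equals the published value. Event counts at
    each digitized coordinate are solved from the ratio of the digitized
    survival to the running reconstructed Kaplan–Meier estimate, which keeps
    integer-rounding drift from accumulating. In the final interval, if the
    total event count is known the allocation is adjusted to match it;
    otherwise no censoring is assumed before the last coordinate and all
    remaining patients are censored there.
    """
    t, s = km.times, km.survival
    trisk, nrisk = km.risk_times, km.n_at_risk
    # risk entries beyond the digitized range carry no usable information
    keep = trisk <= t[-1] + 1e-12
    trisk, nrisk = trisk[keep], nrisk[keep]
    if trisk.size == 0:
        raise ReconstructionError("no risk-table entry within the digitized range")
    if trisk.size < 2 and km.total_events is None:
        # single risk entry: treat the whole curve as one closed interval
        trisk = np.array([trisk[0]])
        nrisk = np.array([nrisk[0]])
    K = t.size
    # index of first digitized point at/after each risk time
    if np.any(np.diff(nrisk) > 0):
        i = int(np.where(np.diff(nrisk) > 0)[0][0])
        raise ReconstructionError(
            f"risk table increases at interval {i} ({nrisk[i]} -> {nrisk[i+1]})")

    # A digitized point AT a risk time carries the survival drop that happened
    # just before it, so interval i owns the coordinates in (trisk_i, trisk_i+1].
    starts = np.searchsorted(t, trisk, side="right")
    d = np.zeros(K, dtype=int)
    cens_times_all: list[np.ndarray] = []
    km_hat = np.ones(K)       # reconstructed KM at each coordinate

    n_int = trisk.size
    for i in range(n_int):
        lo = int(starts[i])
        is_last = i == n_int - 1
        hi = K - 1 if is_last else int(starts[i + 1]) - 1
        t_lo = trisk[i]
        t_next = t[K - 1] if is_last else trisk[i + 1]
        if hi < lo:
            if not is_last and nrisk[i + 1] != nrisk[i]:
                cens_times_all.append(
                    np.full(int(nrisk[i] - nrisk[i + 1]), (t_lo + t_next) / 2.0))
            continue

        if is_last:
            n_cens = 0
        else:
            base = s[lo - 1] if lo > 0 and s[lo - 1] > 0 else 1.0
            n_cens = int(round(nrisk[i] * s[hi] / base)) - int(nrisk[i + 1])
            n_cens = max(n_cens, 0)

        for _ in range(max(2 * int(nrisk[i]) + 10, 50)):
            # spread censorings uniformly over the interval
            if n_cens > 0:
                c_times = t_lo + (np.arange(1, n_cens + 1) / (n_cens + 1)) * (t_next - t_lo)
            else:
                c_times = np.empty(0)
            # censors in [t_k, t_k+1) leave after the events at t_k (Guyot's
            # ordering); those landing before the first coordinate leave first
            c_pre = int(np.sum(c_times < t[lo]))
            c_counts = np.zeros(hi - lo + 1, dtype=int)
            for k in range(lo, hi + 1):
                right_edge = t[k + 1] if k < hi else np.inf
                c_counts[k - lo] = int(np.sum((c_times >= t[k]) & (c_times < right_edge)))

            n_run = int(nrisk[i]) - c_pre
            km_prev = km_hat[lo - 1] if lo > 0 else 1.0
            for k in range(lo, hi + 1):
                if n_run > 0 and km_prev > 0:
                    d[k] = int(round(n_run * (1.0 - s[k] / km_prev)))
                    d[k] = int(np.clip(d[k], 0, n_run))
                else:
                    d[k] = 0
                if n_run > 0 and d[k] > 0:
                    km_hat[k] = km_prev * (1.0 - d[k] / n_run)
                    km_prev = km_hat[k]
                else:
                    km_hat[k] = km_prev
                n_run = n_run - d[k] - c_counts[k - lo]
            if is_last:
                break
            diff = n_run - int(nrisk[i + 1])
            if diff == 0:
                break
            if n_cens + diff < 0:
                # cannot remove censoring that is not there: the digitized
                # drops alone overshoot; accept the nearest allocation
                if n_cens == 0:
                    break
                n_cens = 0
            else:
                n_cens += diff

        cens_times_all.append(c_times)

    # everyone not yet accounted for survived the curve: censor at its end
    n_alloc = int(d.sum()) + sum(c.size for c in cens_times_all)
    leftover = int(nrisk[0]) - n_alloc
    if km.total_events is not None:
        # rebalance the tail to a known event total (published variant):
        # convert the latest events into end-of-follow-up censorings
        excess = int(d.sum()) - int(km.total_events)
        for k in range(K - 1, -1, -1):
            if excess <= 0:
                break
            take = min(d[k], excess)
            d[k] -= take
            excess -= take
            leftover += take
    if leftover > 0:
        cens_times_all.append(np.full(leftover, t[K - 1]))

    ev_times = np.repeat(t, d)
    c_all = np.concatenate(cens_times_all) if cens_times_all else np.empty(0)
    times = np.concatenate([ev_times, c_all])
    events = np.concatenate([np.ones(ev_times.size, dtype=int),
                             np.zeros(c_all.size, dtype=int)])
    order = np.argsort(times, kind="stable")
    return PseudoIPD(times[order], events[order])
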