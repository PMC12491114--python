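"""Synthetic inputs for every stage of the pipeline.

The trial curves behind the published fits and the insurer claims data
behind the cost inputs are not redistributable, so every test and the PSA
survival-resampling chain run on synthetic stand-ins: event/censoring times
drawn from the packaged survival laws, digitized-Kaplan–Meier fixtures with
numbers-at-risk tables (emulating plot digitization of a published figure),
and right-skewed per-patient cost samples from the gamma mean/SD pairs.
Everything is reproducible from a seed, and each fixture carries its recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .km import DigitizedKM, PseudoIPD, km_estimator
from .sensitivity import gamma_from_mean_sd
from .survival import AnySurvival

__all__ = ["SimulationRecipe", "simulate_ipd", "make_km_fixture",
           "simulate_cost_samples"]

# default fixture sizes mirroring the source trials' arms
TRIAL_ARM_SIZES = {"vision_prlt": 551, "vision_soc": 280,
                   "therap_prlt": 100, "therap_cbz": 100}


@dataclass(frozen=True)
class SimulationRecipe:
    """How a synthetic survival fixture is generated."""

    n: int = 551
    censor_at: float = 24.0          # administrative censoring, months
    grid_step: float = 1.0           # digitization grid, months
    risk_interval: float = 3.0       # spacing of the numbers-at-risk table
    jitter_sd: float = 0.0           # digitization noise on survival values
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 subjects")
        if self.grid_step <= 0 or self.risk_interval <= 0:
            raise ValueError("grid steps must be positive")


def simulate_ipd(dist: AnySurvival, n: int, censor_at: float | None = None,
                 seed: int = 0) -> PseudoIPD:
    """Draw right-censored event times from ``dist`` by inverse-CDF sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    if hasattr(dist, "ppf"):
        t = np.asarray(dist.ppf(u), dtype=float)
    else:   # piecewise law: invert the stitched survival numerically
        t = _invert_survival(dist, u)
    events = np.ones(n, dtype=int)
    if censor_at is not None:
        cens = t > censor_at
        t = np.where(cens, censor_at, t)
        events = np.where(cens, 0, 1)
    return PseudoIPD(t, events)


def _invert_survival(dist, u, t_max=4000.0):
    grid = np.linspace(0.0, t_max, 80001)
    s = dist.survival(grid)
    # S is non-increasing; find first grid time with S <= 1-u
    target = 1.0 - np.asarray(u)
    idx = np.searchsorted(-s, -target, side="left")
    return grid[np.clip(idx, 0, grid.size - 1)]


def make_km_fixture(ipd: PseudoIPD, grid_step: float = 1.0,
                    risk_interval: float = 3.0, jitter_sd: float = 0.0,
                    seed: int = 0, recipe: dict | None = None) -> DigitizedKM:
    """Sample the product-limit curve of ``ipd`` on a grid, as a digitizer would.

    Optional Gaussian jitter emulates digitization noise; the DigitizedKM
    constructor re-snaps the curve monotone, as the reconstruction requires.
    The risk table counts subjects still under observation at each tick.
    """
    curve = km_estimator(ipd)
    t_max = float(ipd.times.max())
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    surv = curve(grid)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.normal(0.0, jitter_sd, size=surv.shape)
        surv[0] = 1.0
    risk_t = np.arange(0.0, t_max + 1e-9, risk_interval)
    n_at_risk = np.array([(ipd.times >= rt).sum() for rt in risk_t])
    keep = n_at_risk > 0
    return DigitizedKM(grid, surv, risk_t[keep], n_at_risk[keep],
                       total_events=int(ipd.events.sum()),
                       recipe=recipe or {"grid_step": grid_step,
                                         "risk_interval": risk_interval,
                                         "jitter_sd": jitter_sd, "seed": seed})


def simulate_cost_samples(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """Right-skewed per-patient monthly cost draws with the given mean/SD.

    Emulates the claims-derived state-cost estimates at the summary level:
    a gamma law moment-matched to the published mean and standard deviation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    shape, rate = gamma_from_mean_sd(mean, sd)
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, 1.0 / rate, size=n)
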