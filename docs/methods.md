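# Methods

This note documents the models implemented in `psma_cua`, the conventions
behind their numbers, and what the synthetic-data machinery does and does
not establish.

## The decision problem

Metastatic castration-resistant prostate cancer (mCRPC) patients who have
exhausted an androgen-receptor-pathway inhibitor and taxane chemotherapy can
receive ¹⁷⁷Lu-PSMA-617 radioligand therapy (PRLT). The package quantifies,
from the perspective of the German statutory health insurance system, the
incremental cost per quality-adjusted life year (QALY) of:

* **Model I** — PRLT plus standard of care (SoC) versus SoC alone in third
  line; survival inputs from the VISION trial.
* **Model II** — PRLT versus cabazitaxel in second line; survival inputs
  from the TheraP trial, with third-line follow-on treatment (75% SoC / 25%
  PRLT by default) modelled by nesting Model I's structure.

## Cohort state-transition engine

Both models are discrete-time Markov cohort models: 1,000 patients, monthly
cycles, a 60-month horizon, and a 3% annual discount rate for costs and
effects. States are expanded into tunnel compartments (one per month of
residence) wherever duration matters — treatment lasts up to 8 months
(PRLT and SoC) or 7 months (cabazitaxel), after which survivors move to
"stable after treatment".

Per-cycle transition probabilities come from parametric survival laws
*S*(t) fitted to the trials' overall survival (OS) and progression-free
survival (PFS) curves:

* death (from **every** alive state): `p_death = 1 − S_os(t+1)/S_os(t)`,
* progression (from pre-progression states):
  `p_prog = min(1 − S_pfs(t+1)/S_pfs(t), 1 − p_death)`,
* staying: the remainder.

Equal mortality from stable and progressed states is the standard
simplification of this model family; it makes the traced death occupancy
reproduce the input OS law exactly (a property the tests exploit). The
progression probability is the **full** PFS conditional event probability,
not the PFS-minus-death excess: with the published parameter tables only
this convention reproduces the published ICER (€69,418/QALY comes out as
€69,414 here, versus €66,125 under the subtraction convention). Since a PFS
event can be a death, this double-counts a small death flux as progression;
at these hazards the effect on value accrual is below the reporting
precision and the convention evidently matches the original computation.

**Model II wiring.** Upon first progression the cohort splits by the
third-line mix directly into the nested third-line sub-models (no
intermediate progression dwell). Third-line transitions use Model I's
survival laws evaluated on the **model clock** (time since model start).
This too was inferred from the published results: evaluating the nested
laws on a clock reset at third-line entry inflates both arms' totals by
roughly 7%, while the shared clock reproduces every published Model II cell
to <0.3% (including the 97.7% death fraction). A reset-clock variant — the
arguably more literal reading of "subsequent treatment according to
Model I" — remains available via `build_model_II(..., third_line_clock=
"reset")`; it is implemented by indexing every third-line compartment by
months since entry, which bounds the expansion at the horizon.

**Accrual.** Cycle values use the life-table within-cycle correction: the
mean of start- and end-of-cycle occupancy (selectable: `start`, `end`,
`none`). Costs are EUR per state-month; utilities are annual QALY weights
credited at 1/12 per cycle. The discount factor for the cycle ending at
month *c* is `(1.03)^(−c/12)`; annual-step alternatives shift totals by
under 1%. Totals are reported per patient.

## Survival laws

Seven families are supported with the parameterizations matching the
published table labels: exponential (rate), Weibull and log-logistic
(shape/scale), gamma (shape/rate), log-normal (meanlog/sdlog), Gompertz
(shape/rate), generalized gamma (mu/sigma/Q). Sanity anchor: the
third-line PRLT OS log-logistic has median = scale = 15.54 months, matching
the trial's reported 15.3-month median OS. Piecewise laws stitch segments
by conditional survival — `S(t) = S(k)·S₂(t)/S₂(k)` past the knot — so the
stitched curve is continuous and per-cycle probabilities spanning a knot
are coherent; knots sit at 3.6 months (SoC PFS) and 4.5 months
(cabazitaxel PFS). Whether the original piecewise fits were stitched
conditionally or fitted per segment is not documented; conditional
stitching is the only choice that yields a single coherent survival
function, and the base-case results confirm it.

Fitting is generic right-censored maximum likelihood on the unconstrained
scale (log of positive parameters), Nelder-Mead polished by BFGS, with the
covariance from a finite-difference observed information matrix. AIC/BIC
support family selection. The generalized-gamma parameterization is the
mu/sigma/Q form; it is only needed for exploratory alternative fits, not
the base case.

## Kaplan–Meier reconstruction

`reconstruct_ipd` implements the iterative pseudo-individual-patient-data
scheme used to convert digitized survival coordinates plus numbers-at-risk
into event/censoring times: censoring is spread uniformly within each
risk-table interval, event counts are solved from the digitized drops
against the running reconstructed product-limit estimate, and the censoring
count is adjusted until the implied number at risk matches the next table
entry. Grid-sampled coordinates carry the preceding interval's drop, so a
point at a risk time is processed before that risk check. When the total
event count is known, the tail allocation is rebalanced to match it;
otherwise survivors past the last coordinate are censored there. Digitized
inputs are snapped monotone (running minimum) because plot digitization can
invert adjacent points.

The original digitized coordinates are not public, so the base case uses
the published fitted parameters directly; the reconstruction chain is
validated end-to-end on synthetic curves (truth → KM → 1-month grid →
reconstruct → refit recovers parameters within 10% at n = 800).

## Sensitivity analyses

* **Deterministic (tornado):** costs ±50%, utilities ±25%, discount rate
  {0%, 5%}, horizon {84, 120} cycles, one at a time, ranked by ICER spread.
  Horizon and discount are one-sided/two-point variations rather than
  symmetric ranges.
* **Probabilistic:** 10,000 Monte-Carlo iterations by default; costs drawn
  from gamma laws moment-matched to the published mean/SD, utilities from
  the published beta shapes, survival parameters from a multivariate normal
  on the unconstrained scale. The normal is centred at the published
  estimates with covariance obtained by refitting the base-case family to
  pseudo-IPD reconstructed from a *synthetic* digitized curve at the trial
  arm size (VISION 551/280, TheraP ≈100 per arm, administrative censoring
  at 24 months); piecewise segments are resampled independently, and all
  parameters are drawn independently across arms and states. Because the
  true fit covariances are unpublished, probabilistic results are
  approximate by construction — the published probabilistic row (e.g.
  66.7%/79.7% quadrant shares) is a location check, not an exact target.
  A probabilistic ICER is reported as the ratio of mean incremental cost to
  mean incremental effect.
* **Scenarios:** the packaged catalogue covers the commercial drug price
  (€21,303/month under PRLT treatment), the alternative cabazitaxel cost
  source (€8,718 treatment / €4,795 stable), the Radium-223 SoC-cost blend
  (0.59 × 6,716 + 0.41 × 3,646 = €5,457.30), and third-line mix variations
  (`mix_75_25`, `mix_100_0`, `mix_0_100`, named `<PRLT%>_<SoC%>`).

## Synthetic data

The generator stands in for two closed sources: the published trial curves
(emulated as inverse-CDF samples from the packaged laws, digitized on a
1-month grid with a 3-month risk table and optional monotone-snapped
jitter) and the insurer claims data (emulated only at the state-cost
summary level, as gamma samples with the published mean/SD). Defaults
mirror the trials' arm sizes and a 24-month administrative censoring time
typical of their follow-up. What a green test establishes: the pipeline
recovers known truths through digitization, reconstruction, fitting and
cohort simulation. What it does not: fidelity of the published parameters
to the real trial data, real digitization error structure, or any
claims-data patient selection.

## Numerical choices and limitations

* Transition rows must sum to 1 within 1e−12; traces conserve the cohort to
  1e−9 and the death state is monotone.
* Probabilities are evaluated in log-survival space (`-expm1(Δ log S)`) for
  late-cycle stability.
* Degenerate inputs: `t0 = t1` gives probability 0; evaluation where
  `S = 0` raises a domain error naming the offending quantity.
* The ±5% band used by the reproduction tests reflects genuinely
  undocumented engine conventions (discount compounding variant, life-table
  flavour); the implemented conventions land within 0.3% of every published
  deterministic cell.
* Out of scope: EQ-5D-5L utility derivation, partitioned survival models,
  cure/spline survival models, olaparib or ²²⁵Ac-PSMA strategies, and
  claims-data cohort construction.
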