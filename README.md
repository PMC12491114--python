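# psma-cua

Cost-utility state-transition models for ¹⁷⁷Lu-PSMA-617 radioligand
therapy (PRLT) in metastatic castration-resistant prostate cancer (mCRPC),
from the perspective of the German statutory health insurance system.

The package is aimed at health-economic modellers who want a reproducible,
scriptable implementation of two published-style cohort models:

* **Model I** — PRLT + standard of care (SoC) vs SoC alone as third-line
  treatment (VISION-trial survival inputs);
* **Model II** — PRLT vs cabazitaxel as second-line treatment
  (TheraP-trial survival inputs), with nested third-line sub-models.

Both are time-inhomogeneous Markov cohort models (1,000 patients, 60
monthly cycles, tunnel states for treatment duration, life-table
within-cycle correction, 3% annual discount). Transitions derive from
parametric survival laws: per cycle,

```
p_death(t) = 1 − S_os(t+1)/S_os(t)          (from every alive state)
p_prog(t)  = min(1 − S_pfs(t+1)/S_pfs(t), 1 − p_death(t))
```

and strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔC/ΔE (EUR per QALY), with dominance labels on the
cost-effectiveness plane. Around the base case the package provides
one-way deterministic sensitivity analysis (tornado), probabilistic
sensitivity analysis (gamma costs, beta utilities, resampled survival
parameters), scenario analyses, Kaplan–Meier pseudo-IPD reconstruction
from digitized curves, and parametric survival fitting with AIC/BIC
selection. See `docs/methods.md` for the model conventions.

## Worked example

```python
from psma_cua import build_pair, compare

intervention, comparator = build_pair("I")     # PRLT+SoC vs SoC, Model I
o_iv, o_cp = intervention.outcome(), comparator.outcome()
print(f"PRLT+SoC: {o_iv.total_cost:,.0f} EUR, {o_iv.total_qaly:.2f} QALYs")
print(f"SoC:      {o_cp.total_cost:,.0f} EUR, {o_cp.total_qaly:.2f} QALYs")
print(compare(o_iv, o_cp).summary())
```

prints

```
PRLT+SoC: 97,491 EUR, 1.14 QALYs
SoC:      70,366 EUR, 0.75 QALYs
Δcost 27,125 EUR, Δeffect 0.3908 QALYs (ICER 69,414 EUR/QALY)
```

i.e. third-line PRLT costs about €27,000 more per patient than SoC alone
and yields 0.39 additional quality-adjusted life years — roughly €69,000
per QALY gained. The same call with `build_pair("II")` shows PRLT
*dominating* cabazitaxel in second line (≈€1,457 cheaper, 0.11 QALYs
better).

The same runs from the shell:

```
psma-cua run-base --model I --out results/
psma-cua run-dsa  --model I
psma-cua run-psa  --model II --n 10000 --seed 1
psma-cua run-scenario commercial_price
psma-cua make-fixtures --out fixtures/ --seed 1
psma-cua validate-params
```

All base-case inputs (survival parameters, state costs, utilities, scenario
overrides) ship in `src/psma_cua/data/parameters.yaml` and can be replaced
with `--params`.

## Acceptance script

`scripts/acceptance.py` rebuilds the headline quantities from the packaged
parameter file — both models' incremental costs and effects, the death
fractions at the horizon, and the three cost-scenario ICERs — and writes
them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run is deterministic; the seed is accepted for interface uniformity
and drives any probabilistic extension.
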