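# Base-case inputs for the two cohort state-transition models.
# Model I: PRLT + SoC vs SoC alone as third-line treatment (VISION-based).
# Model II: PRLT + SoC vs cabazitaxel as second-line treatment (TheraP-based),
# with Model I third-line sub-models after first progression.
# Times in months, costs in EUR per month, utilities as annual QALY weights.

config:
  horizon_cycles: 60
  cycle_length_months: 1
  annual_discount: 0.03
  cohort_size: 1000

treatment_duration:
  prlt: 8
  soc: 8
  cabazitaxel: 7

third_line_mix:
  soc: 0.75
  prlt: 0.25

survival:
  model_I:
    prlt:
      os: {family: loglogistic, shape: 1.9263, scale: 15.5377}
      pfs: {family: lognormal, meanlog: 2.1048, sdlog: 0.9841}
    soc:
      os: {family: gamma, shape: 1.6065, rate: 0.1140}
      pfs:
        piecewise:
          - {family: loglogistic, shape: 4.7332, scale: 2.3643}
          - {family: lognormal, meanlog: 2.2763, sdlog: 0.8268}
        knots: [3.6]
  model_II:
    prlt:
      os: {family: loglogistic, shape: 1.9576, scale: 18.6763}
      pfs: {family: lognormal, meanlog: 1.5854, sdlog: 0.9737}
    cabazitaxel:
      os: {family: loglogistic, shape: 2.2526, scale: 19.3004}
      pfs:
        piecewise:
          - {family: lognormal, meanlog: 0.4939, sdlog: 0.5765}
          - {family: lognormal, meanlog: 2.0563, sdlog: 0.2874}
        knots: [4.5]

# Per-state monthly costs with deterministic ranges (+-50%) and gamma
# mean/SD for probabilistic analysis; utilities with +-25% ranges and beta
# shapes. Identical blocks are repeated verbatim to mirror the source table.
values:
  model_I:
    prlt:
      treatment:
        cost: 7340
        cost_range: [3670, 11010]
        cost_gamma: {mean: 7340, sd: 2942}
        utility: 0.7492
        utility_range: [0.5619, 0.9365]
        utility_beta: {shape1: 2.6590, shape2: 0.8901}
      stable:
        cost: 3990
        cost_range: [1995, 5985]
        cost_gamma: {mean: 3990, sd: 3099}
        utility: 0.7492
        utility_range: [0.5619, 0.9365]
        utility_beta: {shape1: 2.6590, shape2: 0.8901}
      progression:
        cost: 3990
        cost_range: [1995, 5985]
        cost_gamma: {mean: 3990, sd: 3099}
        utility: 0.6440
        utility_range: [0.4830, 0.8050]
        utility_beta: {shape1: 1.8359, shape2: 1.0149}
    soc:
      treatment:
        cost: 6716
        cost_range: [3358, 10074]
        cost_gamma: {mean: 6716, sd: 3818}
        utility: 0.6946
        utility_range: [0.5210, 0.8683]
        utility_beta: {shape1: 1.7945, shape2: 0.7890}
      stable:
        cost: 4794
        cost_range: [2397, 7191]
        cost_gamma: {mean: 4794, sd: 4932}
        utility: 0.6946
        utility_range: [0.5210, 0.8683]
        utility_beta: {shape1: 1.7945, shape2: 0.7890}
      progression:
        cost: 4794
        cost_range: [2397, 7191]
        cost_gamma: {mean: 4794, sd: 4932}
        utility: 0.6460
        utility_range: [0.4845, 0.8075]
        utility_beta: {shape1: 1.5734, shape2: 0.8622}
  model_II:
    prlt:
      treatment:
        cost: 7340
        cost_range: [3670, 11010]
        cost_gamma: {mean: 7340, sd: 2942}
        utility: 0.7492
        utility_range: [0.5619, 0.9365]
        utility_beta: {shape1: 2.6590, shape2: 0.8901}
      stable:
        cost: 3990
        cost_range: [1995, 5985]
        cost_gamma: {mean: 3990, sd: 3099}
        utility: 0.7492
        utility_range: [0.5619, 0.9365]
        utility_beta: {shape1: 2.6590, shape2: 0.8901}
    cabazitaxel:
      treatment:
        cost: 14460
        cost_range: [7230, 21690]
        cost_gamma: {mean: 14460, sd: 4760}
        utility: 0.7260
        utility_range: [0.5445, 0.9075]
        utility_beta: {shape1: 1.2698, shape2: 0.4792}
      stable:
        cost: 8123
        cost_range: [4062, 12185]
        cost_gamma: {mean: 8123, sd: 12422}
        utility: 0.7260
        utility_range: [0.5445, 0.9075]
        utility_beta: {shape1: 1.2698, shape2: 0.4792}
    third_line:
      prlt:
        treatment:
          cost: 7340
          cost_range: [3670, 11010]
          cost_gamma: {mean: 7340, sd: 2942}
          utility: 0.7492
          utility_range: [0.5619, 0.9365]
          utility_beta: {shape1: 2.6590, shape2: 0.8901}
        stable:
          cost: 3990
          cost_range: [1995, 5985]
          cost_gamma: {mean: 3990, sd: 3099}
          utility: 0.7492
          utility_range: [0.5619, 0.9365]
          utility_beta: {shape1: 2.6590, shape2: 0.8901}
        progression:
          cost: 3990
          cost_range: [1995, 5985]
          cost_gamma: {mean: 3990, sd: 3099}
          utility: 0.6440
          utility_range: [0.4830, 0.8050]
          utility_beta: {shape1: 1.8359, shape2: 1.0149}
      soc:
        treatment:
          cost: 6716
          cost_range: [3358, 10074]
          cost_gamma: {mean: 6716, sd: 3818}
          utility: 0.6946
          utility_range: [0.5210, 0.8683]
          utility_beta: {shape1: 1.7945, shape2: 0.7890}
        stable:
          cost: 4794
          cost_range: [2397, 7191]
          cost_gamma: {mean: 4794, sd: 4932}
          utility: 0.6946
          utility_range: [0.5210, 0.8683]
          utility_beta: {shape1: 1.7945, shape2: 0.7890}
        progression:
          cost: 4794
          cost_range: [2397, 7191]
          cost_gamma: {mean: 4794, sd: 4932}
          utility: 0.6460
          utility_range: [0.4845, 0.8075]
          utility_beta: {shape1: 1.5734, shape2: 0.8622}

# Scenario catalogue: named override sets applied on top of the base case.
scenarios:
  commercial_price:
    description: >
      Commercially available product priced per the German benefit assessment
      (20% average rebate applied) instead of in-house production; replaces
      every monthly cost of being under PRLT treatment.
    overrides:
      values.model_I.prlt.treatment.cost: 21303
      values.model_II.prlt.treatment.cost: 21303
      values.model_II.third_line.prlt.treatment.cost: 21303
  kreis_cbz_costs:
    description: >
      Cabazitaxel cost inputs from the older Kreis et al. claims analysis,
      updated to 2022 price levels (stable assumed at 55% of treatment).
    overrides:
      values.model_II.cabazitaxel.treatment.cost: 8718
      values.model_II.cabazitaxel.stable.cost: 4795
  radium223_soc:
    description: >
      SoC cost cohort assumed to contain 59% Radium-223 recipients at the
      observed 6,716 EUR/month and 41% on other SoC at 3,646 EUR/month.
    overrides:
      values.model_I.soc.treatment.cost: 5457.30   # 0.59*6716 + 0.41*3646
  mix_75_25:
    description: Third-line split reversed to 75% PRLT + SoC / 25% SoC.
    overrides:
      third_line_mix.soc: 0.25
      third_line_mix.prlt: 0.75
  mix_100_0:
    description: All of the cohort receives PRLT + SoC as third-line therapy.
    overrides:
      third_line_mix.soc: 0.0
      third_line_mix.prlt: 1.0
  mix_0_100:
    description: All of the cohort receives SoC as third-line therapy.
    overrides:
      third_line_mix.soc: 1.0
      third_line_mix.prlt: 0.0
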