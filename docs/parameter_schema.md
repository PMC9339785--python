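# Parameter file schema

`ParameterSet` serializes to YAML (`ParameterSet.to_yaml` /
`ParameterSet.from_yaml`); `adtcea simulate` writes a complete example as
`params.yaml`.  Top-level keys, with dot-paths as used by scenario edits,
one-way perturbations and PSA distributions:

| key | fields (type, unit) |
|---|---|
| `settings` | `cycle_length_days` (float, d), `horizon_years` (float, y), `discount_rate_cost` / `discount_rate_effect` (float/y), `start_age` (float, y), `half_cycle_correction` (bool) |
| `survival` | `family` (one of exponential/weibull/loglogistic/lognormal/gompertz), `shape` (γ or σ), `scale` (λ or μ), `hr_psa_recurrence` (float > 0), `reference_arm` (arm name) |
| `second_line` | `response_rates` (map state → per-cycle probability), `chemo_skip_fraction`, `post_abiraterone_exit`, `supportive_exit` (probabilities) |
| `mortality` | `logistic_asymptote` (L), `logistic_steepness` (k, /y), `logistic_midpoint` (a0, y), `hr_post_progression`, `state_hr` (optional map state → HR), `age_min`, `age_max` |
| `drug_costs` | per-cycle and per-day drug prices (yuan), `adt_during_aa_states` (bool) |
| `management_costs` | bundled per-cycle state costs and per-item administration costs (yuan) |
| `admin_frequencies` | map state → map item → expected uses per cycle |
| `ae_costs` | map adverse-event cost item → yuan |
| `adverse_events` | list of {`name`, `cost_mix` (map item → fraction, sums to 1), `disutility` (in [−1, 0]), `incidence` (map arm → per-cycle probability), `states` (list)} |
| `utilities` | per-state utility in [0, 1] |
| `willingness` | `gdp_per_capita` (yuan), `wtp_multiplier` |
| `provenance` | map dot-path → `printed` \| `synthetic` (metadata only) |

Validation (`ParameterSet.validate`) enforces domains (probabilities and
utilities in [0, 1], costs ≥ 0, hazard ratios > 0, adverse-event mixes
summing to 1) and raises `InvalidParameterError` in strict mode.

Tabular interfaces: survival data CSV with columns `time_days,event`;
life-table CSV with columns `age,qx`.  Lines starting with `#` are headers
and ignored on read.
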