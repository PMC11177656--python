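# pbrtqc

Patient-based real-time quality control (PBRTQC) toolkit: EWMA monitoring
over truncated patient-result streams, Westgard multirules, error-detection
evaluation (Ped / FPR / FNR / ANPed / ROC-AUC), optimal-model selection, and
a seeded simulator of patient streams with injectable analytical errors.

## What it does

- **core_model** — domain types (analyte configs, result streams, risk
  events, performance reports) and CSV/YAML readers/writers.
- **truncation** — truncation-range estimation: profile-likelihood Box-Cox
  normality intervals (the "traditional" arm) and a biological-variation
  heuristic centred on the median (the "bv_heuristic" arm), plus range
  application that marks excluded results without dropping them.
- **monitor** — EWMA recursion `q_{t+1} = λ·x_t + (1−λ)·q_t`, asymptotic
  control limits, Westgard 1-2S / 1-3S / 2-2S / R-4S / 10-X rules, and alarm
  episode detection.
- **evaluation** — labels samples against half-open risk windows
  `[onset, closure)`, computes event-level Ped/FNR, sample-level FPR, ANPed,
  rank-exact ROC-AUC over the EWMA deviation score, and the optimality
  filter (Ped > 90%, FPR < 5%, then max AUC; ties prefer smaller λ).
- **simulator** — median/CV-parameterized lognormal streams with Poisson
  arrivals, plus scheduled step-bias, drift and imprecision-inflation
  events that act on the measurand before truncation.
- **cli** — `pbrtqc` command with `simulate`, `fit-truncation`, `monitor`,
  `evaluate`, `select` and `benchmark` (two truncation arms × a λ grid,
  end to end) subcommands.

## CLI quick start

```sh
# generate a stream with one injected calibration-style step bias
pbrtqc simulate --scenario scenario.yaml --seed 7 \
    --out-stream stream.csv --out-events events.csv

# full two-arm x lambda-grid comparison with model selection
pbrtqc benchmark --scenario scenario.yaml --seed 7 --cvi 6 --cvg 6 \
    --out-dir results/benchmark
```

A scenario document looks like:

```yaml
stream:
  median: 100.0
  cvi: 6.0      # within-subject biological variation, percent
  cvg: 6.0      # between-subject, percent
  cva: 5.3      # analytical imprecision, percent
  seed: 42
  n_per_day: 100
  n_days: 40
errors:
  - kind: step_bias        # step_bias | drift | imprecision_inflation
    magnitude: 3.0         # multiples of training SD (see docs per kind)
    onset_day: 28
    closure_day: 34
```

Exit codes: 0 ok, 2 validation error, 3 runtime error.

## Notes

- Alarm scoring defaults to action-level (out-of-control) alarms; warning
  records are kept in the alarm log for inspection.
- Westgard rules can be applied to the EWMA z-series via
  `rules_enabled={"limit_chart","westgard"}`, but the default PBRTQC
  surface is the limit chart alone.
- All randomness flows through explicit seeds; same seed, same bytes.
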