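# grainacoustics

Acoustic monitoring of stored-product insect activity under hermetic
storage: impulse detection, spectral-profile classification, burst-rate
statistics, and oxygen-depletion analysis, with a synthetic-data module so
the whole pipeline is testable without field recordings.

## The problem

Grain weevils such as *Sitophilus oryzae* feeding inside sealed (hermetic)
containers betray themselves acoustically: their feeding and movement
produce trains of brief, 1–10 ms sound impulses. At the same time their
respiration depletes the container's oxygen from the ambient ~21% toward
levels at which activity ceases (~5%) and mortality follows (~2%). Two
questions matter to anyone storing grain hermetically: *is the grain
infested?* and *how long until the pests stop doing economic damage?*

This package implements the analysis chain that answers both:

1. **Impulse detection** — candidate transients are found with a high-pass
   filter, a rectified smoothed envelope, and a robust
   `median + k·MAD` threshold; events outside 0.5–20 ms are discarded.
2. **Spectral-profile matching** — each impulse's 256-point Hann power
   spectrum (50% frame overlap, unit total power) is compared by least
   squares against averaged spectra of verified insect impulses
   ("profiles"); an impulse is an insect signal iff its best sum of
   squared bin differences (SSE) is at or below a calibrated threshold.
3. **Burst grouping** — runs of ≥ 3 matched impulses with consecutive gaps
   strictly under 200 ms form *bursts*, the unit of detected activity.
   Three measures summarize a segment of duration *T*: the burst rate
   *R_b* = bursts/*T*, impulses per burst *N_b*, and the within-burst
   impulse rate *R_bimp*. A segment with *R_b* ≥ 0.02 bursts·s⁻¹ is
   flagged as likely infested; a sustained fall below that threshold marks
   quiescence.
4. **Hermetic analysis** — per-treatment oxygen volume budgets (ml O₂
   consumed per insect), interpolated times to 5%/2% residual O₂, the
   depletion-rate statistic (population / days to 2%), linear models of
   activity on depletion `Log10(R_b/N_t + 1) = a + b·depletion` (rates
   normalized per insect, *N_b* fit directly), and grain-quality metrics
   (count-and-weigh weight loss, germination capacity).
5. **Synthetic data** — seeded generators for ground-truthed WAV scenes
   (damped-sinusoid impulse trains plus spectrally distinct low-frequency
   distractors over Gaussian noise) and for experiment tables (exponential
   O₂ decline with density-proportional rate, activity generated from the
   published regression coefficients).

## Worked example

```python
from grainacoustics import (
    AcousticScenario, analyze_recording, generate_recording, score_bursts,
)

scenario = AcousticScenario(duration=100.0, burst_rate=0.1,
                            distractor_rate=0.1, rng_seed=42)
waveform, truth = generate_recording(scenario)
result = analyze_recording(waveform)          # bundled profiles by default
m = result.measures
print(f"true bursts: {len(truth.burst_intervals)}")
print(f"detected bursts: {m.n_bursts}")
print(f"R_b  = {m.rb:.3f} bursts/s")
print(f"N_b  = {m.nb:.2f} impulses/burst")
print(f"R_bimp = {m.rbimp:.3f} impulses/s")
print(f"infested: {result.infested}")
score = score_bursts(truth.burst_intervals, result.bursts)
print(f"recall {score.recall:.0%}, false rate {score.false_rate:.0%}")
```

prints

```
true bursts: 10
detected bursts: 10
R_b  = 0.100 bursts/s
N_b  = 4.80 impulses/burst
R_bimp = 0.480 impulses/s
infested: True
recall 100%, false rate 0%
```

All ten generated bursts are recovered with none spurious; the measured
burst rate of 0.100 s⁻¹ sits well above the 0.02 s⁻¹ infestation
threshold, and each burst averaged 4.8 matched impulses.

## Command line

```sh
grainacoustics simulate --seed 1 --scenario scenario.yaml --out-dir out/
grainacoustics detect   --wav out/recording.wav --seed 1
grainacoustics analyze  --experiment out/experiment.csv --out-dir out/ --plots
```

`simulate` reads a YAML scenario with an `acoustic` and/or `experiment`
section and writes the WAV, ground-truth CSVs and/or the tidy experiment
table. `detect` prints per-file activity measures; `analyze` writes
`table2.csv` (O₂ budgets), `table3.csv` (depletion times/rates),
`table6.csv` (regression coefficients) and `summary.csv` (means ± SEM).

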