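# acmkit — ambulatory circadian monitoring analysis

`acmkit` turns a week of multichannel wearable recordings into an objective
assessment of a person's circadian system and chronotype.  It is written for
chronobiology and sleep researchers who run ambulatory circadian monitoring
(ACM) protocols: subjects wear a wrist temperature logger, an arm
accelerometer (motor activity and body position), and a neck-worn light /
environmental-temperature logger for 7 consecutive days under free-living
conditions, and keep a simple sleep diary.

## What it computes

All channels are resampled onto a common 10-min clock-anchored grid, cleaned
(diary-reported sensor removals masked; epochs whose rate of change exceeds
the interquartile distance of the channel removed), and combined into the
integrated variable **TAP** — the mean of normalized wrist Temperature
(inverted, since the wrist warms at night), Activity, and body Position.
TAP ≈ 0 is a sleep-like epoch, TAP ≈ 1 fully active wake.

Per subject and variable the package computes the standard non-parametric
circadian indexes

- **IS** (interdaily stability) = N·Σₕ(x̄ₕ − x̄)² / (p·Σᵢ(xᵢ − x̄)²) ∈ [0, 1],
- **IV** (intradaily variability) = N·Σ(xᵢ − xᵢ₋₁)² / ((N−1)·Σ(xᵢ − x̄)²),
  ≈ 0 for a smooth rhythm and ≈ 2 for white noise,
- **M10/L5** (or **M5/L10** for nocturnal-acrophase variables, i.e. wrist
  temperature and sleep): mean level of the most/least active consecutive
  hours of the daily waveform, by exhaustive circular window search,
- **RA** = (M − L)/(M + L) and its cohort-normalized form **NRA** (top and
  bottom 5 % recoded to 1/0, the rest rescaled),
- **CFI** = (IS + (1 − IV/2) + NRA)/3,

phase markers (**NPM**, the midpoint timing of the nocturnal 5-h window;
**DPM**, of the diurnal 10-h window), the difference from the centre of
natural darkness **DM-NPM** = circular distance(NPM, darkness centre)/12 h,
and the **Circadian Health Index**

```
CHI = (NRA + IS + (1 − DM-NPM)) / 3
```

which is 1 for a high-amplitude, stable rhythm synchronized to the solar
night and 0 for a flat, unstable, fully displaced one.

From the diary it derives the binary sleep series, cohort sleep probability,
MSFsc (midsleep on free days corrected for weekly sleep debt) and social
jetlag; from raw lux it tabulates time per day in the <10 / 10–100 /
100–1000 / >1000 lux bins across the night / morning / evening intervals.
Finally, subjects are classified into Early / Neither / Late chronotypes by
the 20/60/20 percentile rule on the TAP night phase marker, in parallel with
the same rule on MSFsc, and the two classifications are cross-tabulated.

A synthetic cohort generator (`acmkit.synthetic`) produces full 7-day
recordings plus diaries with programmed chronotype, phase jitter, weekend
delay, noise and sensor-off gaps, so every pipeline stage can be validated
against ground truth without any real recordings.

## Worked example

```python
from acmkit import generate_cohort, analyze_cohort

cohort = generate_cohort(n=50, seed=7)          # 20% E / 60% N / 20% L
result = analyze_cohort([s.recording for s in cohort])

tap = result.summaries.query("variable == 'TAP'")
print(tap[["subject_id", "IS", "IV", "NRA", "NPM_clock", "DM_NPM", "CFI", "CHI"]].head(3))
```

```
subject_id       IS       IV      NRA NPM_clock   DM_NPM      CFI      CHI
      s000 0.747637 0.104981 0.317991     04:10 0.268056 0.671046 0.599191
      s001 0.762771 0.163529 0.342936     04:20 0.281944 0.674647 0.607921
      s002 0.870105 0.110889 1.000000     04:10 0.268056 0.938220 0.867350
```

Each row is one subject's TAP rhythm: subject s000 repeats its daily pattern
fairly well (IS 0.75), is smooth rather than fragmented (IV 0.10), has a
night phase marker at 04:10 — about 3.2 h after the winter darkness centre
of 00:57, giving DM-NPM 0.27 — and an overall circadian health index of 0.60.

```python
cls = result.acm_classes
print(cls.labels.count("E"), cls.labels.count("N"), cls.labels.count("L"))
print(result.agreement.coincidence_pct)
```

```
10 30 10
96.0
```

The 20/60/20 split assigns exactly 10 early, 30 neither and 10 late types,
and agrees with the MSFsc-based classification for 96 % of this synthetic
cohort (real cohorts, with far messier diaries and behaviour, agree less).

The same pipeline is available from the shell:

```sh
acm simulate -n 50 --seed 7 -o data/        # logger-dialect CSVs + diaries
acm run      -i data/ -o out/               # full analysis bundle
acm classify -r out/results.csv -o out/     # chronotype assignments
acm report   -i data/ -o out/               # waveform + actogram figures
```

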