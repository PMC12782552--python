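# crawlkit

Analysis toolkit for the leech crawling motor pattern — from raw nerve
recordings and pose-tracking tables to the quantities that describe the
rhythm: burst duty cycles, phase-tuned motor-unit classes, premotor
membrane-potential coupling, and behavioral step structure.

## Who this is for

Neurophysiologists studying rhythmic motor patterns (fictive crawling in
isolated leech ganglia, and crawling in intact animals) who need a
reproducible path from raw data to per-cycle and per-unit tables ready for
mixed-model statistics. Everything also runs without any real data: a
ground-truthed simulator generates extracellular, intracellular and
behavioral recordings with the statistical structure the analysis assumes,
so the full pipeline is testable end to end.

## What it computes

**Ephys.** Extracellular nerve traces are spike-sorted by template matching
(threshold detection on a robust MAD noise estimate, 2-D t-SNE embedding,
density clustering, template assignment, replayable split/merge/discard
curation). DE-3 — the largest unit in the DP nerve and the reference for
the contraction phase — is segmented into bursts: maximal runs of spikes
with inter-spike intervals ≤ 0.5 s, accepted when n ≥ 10 spikes and the
mean firing frequency mFF = n/(t_last − t_first) ≥ 8 Hz. Cycles run between
first spikes (start-to-start) or last spikes (end-to-end) of consecutive
bursts; the duty cycle is burst duration over period. Each unit's binned
firing frequency (bFF, counts/bin-width) is mapped to normalized cycle
phase; rhythmic units (≥ 2 autocorrelogram peaks with r > 0.25 over the
first four cycles) are classified as in-phase, anti-phase or
in-phase-early-onset relative to the DE-3 window, with Max bFF and relative
half-width (phase width at half maximum) per unit and per epoch
(pre / test / post around a current pulse).

**Intracellular.** The nonspiking (NS) premotor potential is bin-mean
resampled onto the DE-3 bFF grid and cross-correlated per lag (Pearson, so
coefficients are bounded); the NS hyperpolarization amplitude per cycle is
the slow Gaussian baseline (σ = 5 s) at burst onset minus the trough during
the burst, exported with burst mFF, duration and interburst lags.

**Behavior.** 9-point dorsal-midline tracks (DeepLabCut CSV dialect) give
per-section lengths; steps are segmented at minima of the summed z-scored
body length and endpoint speeds; within each step the maximum section
length separates elongation from contraction and knee points (kneedle:
maximum deviation from the endpoint chord) mark elongation onset and
contraction end; behavioral duty cycles are phase durations over the
dynamic (elongation + contraction) step.

## Worked example

```sh
crawlkit run --seed 1 --out out/
```

simulates one dopamine-episode-like recording (DP nerve with three
phase-tuned units, paired NS trace, and a crawling bout) and analyzes it:

```
run: seed=1 config diff={}
done in 7.4 s -> out/
```

`out/unit_metrics.csv` then contains, for every rhythmic unit:

```
unit,epoch,class,max_bff_hz,rel_hw,onset_phase
u15,all,anti_phase,12.07,0.639,0.324
u21,all,in_phase_early_onset,13.96,0.293,0.866
u22,all,in_phase,19.02,0.315,0.962
```

u22 is DE-3 (largest template): in-phase, relative half-width 0.31 ≈ its
duty cycle; the anti-phase unit occupies 0.64 of the cycle — the
interburst/elongation window; the early-onset unit starts at phase 0.87 of
the *previous* cycle (onset wrapped past 1), before the DE-3 burst.
`out/cycles.csv` holds per-cycle period/duration/duty/mFF,
`out/ns_features.csv` the per-cycle hyperpolarization amplitudes and burst
covariates, `out/steps.csv` the behavioral step table, and
`crawlkit report --artifacts out/` renders raster, correlogram and
step-shading panels. Library use mirrors the CLI: see `crawlkit.synth`,
`crawlkit.spikesort`, `crawlkit.rhythm`, `crawlkit.phase`,
`crawlkit.intracell`, `crawlkit.kinematics`.

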