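# Methods

## The system being modelled

Crawling in the medicinal leech alternates elongation (circular-muscle) and
contraction (longitudinal-muscle) phases along the body. In an isolated
midbody ganglion bathed in dopamine, the segmental oscillator expresses a
fictive version of this rhythm: the DE-3 motoneuron (largest spike in the
DP nerve) bursts during the contraction phase, other motor units fire
in-phase, anti-phase, or in-phase-with-early-onset relative to it, and the
nonspiking premotor NS neuron hyperpolarizes in time with DE-3 bursts. In
the intact animal the corresponding behavior is the crawling step: an
isometric pause, elongation of each body section, contraction, and another
pause, repeating with a period roughly half the fictive cycle.

crawlkit implements the measurement side of this biology (spike sorting,
burst/cycle metrics, phase profiles, NS coupling, step kinematics) together
with a generator that synthesizes all three data modalities with known
ground truth.

## Synthetic-data generator

### Oscillator and spike trains

Cycles are drawn as contiguous intervals with Gaussian-jittered periods
(mean 15.22 s, CV 0.1, truncated at 20% of the mean; defaults match the
fictive rhythm in isolated ganglia) and a contraction window opening each
cycle (fraction 0.32 of the period). Default episodes contain 10 cycles —
enough for the 4-cycle analyses with margin, at tolerable simulation cost;
benchmarks that need longer episodes pass `n_cycles=20` explicitly.

Units are piecewise-constant-rate Poisson processes, thinned from a
homogeneous envelope, with a hard absolute refractory period (default 5 ms)
applied afterwards: `peak_rate` inside a wrapped phase window,
`baseline_rate` elsewhere. This is the simplest point process exhibiting
the burst phenomenology the analysis assumes; it has no interval
regularity, rate adaptation, or across-cycle correlation. Default class
windows: DE-3 and in-phase units occupy the contraction window ([0, 0.32)),
anti-phase units the interburst window ([0.36, 1.0)), early-onset units a
wrapped window ([0.9, 0.2)) starting late in the preceding cycle.

Extracellular traces are sums of template-convolved impulse trains plus
i.i.d. Gaussian noise, sampled at 10 kHz (half the typical acquisition
rate; preserves waveform structure at half the test cost). Templates are
biphasic difference-of-Gaussian lobes. The standard benchmark carries three
units with distinct widths, polarities and amplitudes at 2.0 / 1.4 / 1.0
times `SNR x noise_sd` — DE-3 largest, as in real DP recordings. SNR is
defined on the smallest unit (default 8).

### NS membrane potential

Vm = resting − hyp(t) + drift·t + noise. `hyp(t)` is a raised-cosine bump
per contraction window, Gaussian-smoothed (0.5 s). The amplitude parameter
is expressed in the measurement's own convention (`depth_reference =
"baseline"`): each cycle's bump is scaled (iteratively, since the baseline
couples the cycles) so that the slow-Gaussian-baseline measurement recovers
exactly `hyp_amplitude` on the noiseless trace. A `"trough"` mode programs
the raw trough depth below resting instead. This matters because a σ = 5 s
baseline on a ~15 s oscillation sags by roughly a fifth of the trough; the
two conventions differ correspondingly.

Noise is an Ornstein–Uhlenbeck process (τ = 0.15 s, sd 1.5 mV): membrane
fluctuations are temporally correlated, and purely white noise would be
annihilated by the 0.05 s bin-mean resampling, leaving the synthetic
correlation unrealistically clean. The default sd was set so that the
episode-level peak NS/DE-3 cross-correlation of the synthetic pairs matches
the anticorrelation observed in real episodes (≈ −0.6); with it, the
defaults encode the empirical coupling strength, not just its sign. The
generator does not model the depolarized plateaus between hyperpolarizations
beyond the smooth bump, nor cycle-to-cycle amplitude variability — recovery
tests on it therefore certify estimator correctness, not robustness to
every physiological waveform.

### Kinematics

A 9-point dorsal-midline track. Each step is iso_pre → elongation → (max) →
contraction → iso_post; all eight sections move synchronously (the
intersegmental wave is deliberately not modelled, so there is no
section-to-section lag). Section length follows piecewise-linear speed
profiles: 0.1 s acceleration blends at gesture onsets/offsets (real section
traces turn on crisply) and a time-symmetric 0.3 s turnaround at the
elongation→contraction junction — over the shared turnaround the
contraction speed mirrors the elongation deceleration, so the smoothed
length trace peaks at the programmed junction instead of drifting toward
the shallower limb. The animal advances by anchoring the rear during
elongation and the front during contraction, plus a small whole-body creep
(peak 0.5 mm/s) whose speed vanishes exactly at step boundaries, making the
segmentation score's minimum unique there.

Defaults: step 7.49 s; elongation:contraction = 0.65:0.35 of the dynamic
step (both matched to intact-animal crawling); section rest length 10 mm,
elongation gain 0.6; 60 fps; tracking jitter 0.2 mm per coordinate. The
isometric split (0.38 pre / 0.12 post of the step) is not an empirically
reported quantity; it was chosen so that, on each limb of the length curve,
plateau and ramp durations balance — the knee estimator's deviation
extremum then falls at the true gesture corner and the programmed duty
cycles are recovered without bias. Other splits shift the knees by a few
frames and bias the measured elongation duty low by up to ~0.04.

## Analysis pipelines: numerical choices

- **Detection**: noise SD as MAD/0.6745; threshold 5×; both polarities
  (rectified trace); dedup window = the 3 ms waveform window, so the
  trailing lobe of a biphasic spike never registers twice. Waveforms are
  re-aligned to the earliest lobe within 70% of the window maximum — with
  near-symmetric biphasic spikes, noise otherwise flips the alignment
  between lobes and splits one unit into two clusters.
- **Embedding/clustering**: t-SNE (PCA init, fixed seed, perplexity
  auto-reduced for small n; exact-duplicate waveforms get an imperceptible
  deterministic jitter, which otherwise crash Barnes–Hut) and HDBSCAN with
  `min_cluster_size` 20. Above 1000 events a seeded subsample is embedded
  and clustered; template matching then assigns every detected event, so
  the cap loses no spikes.
- **Template matching**: Euclidean distance after baseline subtraction and
  ±2-sample alignment search, no amplitude normalization (nerve units
  differ mainly by amplitude). Acceptance ceiling 4× the within-cluster
  median distance, with a 5%-of-template-peak floor so exact matches on
  noiseless data always pass.
- **Auto-merge**: clusters whose templates are indistinguishable under the
  same shift-tolerant distance (below 3× the larger within-cluster spread)
  are merged through the ordinary curation log — t-SNE islands of one unit
  differ only by sub-sample alignment. All curation (split/merge/discard)
  is logged as JSON lines and replayable.
- **Bursts/cycles**: thresholds inclusive (≥ 10 spikes, mFF ≥ 8 Hz, ISI ≤
  0.5 s); single-spike runs dropped before filtering; duty cycle uses the
  opening burst in start-to-start mode and the closing burst in end-to-end
  mode (which burst the original analyses used in end-to-end mode is not
  documented; both are computable).
- **Rhythmicity**: Pearson autocorrelation of the unsmoothed 0.5 s bFF over
  the first 4 cycles, lags to 2.5 periods; qualifying peaks are local
  maxima above max(0.25, 2.5/√overlap) separated by at least half a period.
  The significance floor matters: with a 4-cycle window the long-lag
  estimates rest on ~30 samples and chance maxima above the fixed 0.25
  criterion are common (a third of white-noise draws qualify without it).
- **Phase profiles**: 50 bins per cycle, each cycle binned at its own
  period and averaged over the first 4 cycles. Metrics are read from a
  circularly smoothed profile (Gaussian, σ = 2 bins — symmetric smoothing
  leaves the half-maximum crossings of a step edge in place) with linear
  interpolation between bins, so a rectangle's width is measured exactly
  and ragged 4-cycle Poisson profiles do not truncate the half-max region.
  Onset = backward crossing of 20% of max; classification: peak (circular
  center of the half-max region) inside the DE-3 window → in-phase, with
  onset wrapped earlier than 0.05 before cycle start → early-onset;
  otherwise anti-phase; two comparable separated peaks → unclassified.
- **Cross-correlation**: Pearson per lag on the overlap (bounded, matching
  the reported index); bFF smoothed with σ = 150 ms first; correlogram
  covers ± one period but the reported extremum (by |r|) is confined to ±
  half a period — the side lobes at ±T of a periodic signal duplicate the
  lag-0 structure.
- **Hyperpolarization amplitude**: baseline at the burst's first spike by
  nearest sample; trough as the minimum of the trace smoothed with 0.25 s —
  a raw minimum is biased downward by sample noise (order 1.7× noise sd for
  white noise over a burst window), while the hyperpolarization itself is
  much slower than the kernel.
- **Step segmentation**: components z-scored over the episode before
  summing (the minimal convention making mm and mm/s commensurable);
  boundaries are score minima at least 2 s apart, with below-mean body
  length (the animal also pauses at full extension; that lull is not a
  boundary) and prominence ≥ 0.5 z-units (keeps noise inside the
  between-step lull from splitting steps). Length traces are filtered
  (σ = 0.25 s) before segmentation; velocities are central differences of
  smoothed endpoint positions. Knees: kneedle with sensitivity 1.0,
  searched between the step boundary and the length maximum (rising) and
  between the maximum and the step end (falling); likelihood floor 0.9,
  interpolation gap limit 5 frames.

## Problem sizes

The test suite runs the sorter benchmark at 20 cycles × 25 seeds, the phase
classifier at 12 units × 25 seeds, NS coupling at 5 cycles × 25 seeds, and
reduced (2–3 seed) versions of the full recovery experiments; the complete
recovery experiment in `scripts/acceptance.py` uses 8 animals × 30 steps
(behavior), 6 fully sorted ganglia (ephys), and 23 five-cycle NS episodes,
chosen to mirror the sample sizes of the corresponding real experiments.

## Known limitations

- The sorter does not decompose overlapping spikes; coincident firing of
  in-phase units costs a few percent assignment accuracy at benchmark SNR.
- No drift tracking: templates are stationary over an episode.
- The behavioral generator has no intersegmental lag, no sucker-attachment
  events, and no tracking dropouts unless injected via the likelihood
  matrix.
- Phase classification assumes a unimodal tuning; genuinely bimodal units
  are reported `unclassified` rather than forced.
- The NS bump is a stand-in for an unquantified waveform; between-burst
  plateau dynamics are not reproduced.
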