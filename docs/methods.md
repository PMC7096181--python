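# Methods

`spikegamma` analyses how the timing of subthalamic-nucleus (STN) spikes
relates to the phase of cortical 60–80 Hz gamma oscillations around cued
hand grips. This note describes the models and procedures the package
implements, the choices made where the design was genuinely open, and what
its synthetic cohorts can and cannot show about real recordings.

## Coupling estimators

For a set of n spikes with coincident LFP phases φ_t, the phase-locking
value is the mean resultant length

    PLV = | (1/n) Σ_t e^{iφ_t} |,

and the pairwise phase consistency is its bias correction

    PPC = n/(n−1) · (PLV² − 1/n).

PLV is inflated at small n (E[PLV²] = 1/n + (1−1/n)·ρ² for true resultant
ρ); PPC has expectation ρ² ≥ 0 exactly and may be negative in finite
samples. Both are always computed and stored. Spike phases are read from
the 1000 Hz phase series by nearest-sample lookup; the sub-millisecond
jitter this introduces attenuates a 70 Hz PLV by ≈1%, negligible relative
to sampling noise at the spike counts used.

## Event-locked variable-window decomposition

Trials are anchored to four events (side cue, Go, grip onset, grip offset +
0.4 s). Each inter-event interval is split into 8 equidistant points
including both endpoints; merging shared endpoints gives 29 points per
trial, so averages across trials and recordings stay locked to every event
despite variable reaction times and grip durations.

Because PLV bias depends on n, windows centred on each grid point are
scaled in width so that the spike count summed across trials matches a
per-recording target: the mean within-trial firing rate × 0.3 s × number of
trials (the count a fixed 0.3 s across-trials window would capture),
floored at 50. The width search is discrete (1 ms steps, 10 ms–2 s cap);
counts are non-decreasing in width, so a bisection finds the closest count,
with ties broken toward the smaller window. Windows crossing the recording
edge are truncated rather than dropped. Points where no admissible width
captures a spike are marked missing and excluded from clustering.

Coupling is evaluated in 16 frequency bins (theta 5–8, alpha 8–12, low beta
12–20, high beta 20–30 Hz, then 20 Hz-wide bins centred at 40…150 Hz in
10 Hz steps). Band phases come from 4th-order Butterworth band-pass filters
applied forward and backward (zero phase, doubled attenuation; reflection
padding handles edges) followed by the Hilbert transform, with the cosine
convention (phase 0 at local maxima). The 16×29 maps are refined for
display by two rounds of 2× bilinear mesh subdivision — equivalently,
bilinear evaluation at 2²(n−1)+1 nodes per side — giving 61×113, and the
time axis is rescaled so each interval's length equals the cohort-average
duration.

Event-locked power maps use the squared analytic amplitude averaged in
fixed 0.3 s windows, normalized by the median of the same moving-window
statistic over the whole recording; the windowed-median normalization (as
opposed to the per-sample median) is chosen so that stationary noise maps
to ≈1 in every band. For bands holding under ~2 cycles per window the
windowed power is strongly skewed and the normalized mean sits somewhat
above 1 even for noise; comparisons are therefore always within-bin.

## Cluster-based permutation statistics

All map-level inference uses one engine: the observed statistic is
standardized cell-wise against a permutation distribution
(z = (obs − mean)/SD), cells with zero permutation variance are excluded,
4-connected suprathreshold clusters are formed at |z| ≥ 1.96 (two-sided
p < 0.05 pre-threshold), and a cluster is significant when its |Σz| exceeds
the 95th percentile of the per-permutation maximal |Σz|. Three null
constructions feed the engine:

* **Paired contrasts** (fast vs slow RT, contra vs ipsi): condition labels
  are permuted per recording, equivalently the per-recording difference
  maps are sign-flipped (default 1000 permutations).
* **Trial-shuffle nulls**: per permutation one random trial-to-trial
  reassignment pairs each trial's spikes with another trial's LFP phases,
  applied identically at every time-frequency cell so that genuine cluster
  structure survives into the null; windows and spike trains stay intact
  (default 500 permutations). Fixed points are allowed (uniform random
  permutations, not derangements). Each spike is given a single coherent
  time in the receiving trial by an event-anchored piecewise-linear warp
  (cue, Go, grip on, grip off + 0.4 s). This matters: overlapping windows
  share spikes, so in the observed map a shared spike contributes the
  *same* phase at adjacent grid points; re-anchoring spikes per window
  centre instead would decorrelate the null maps across cells and shrink
  the max-cluster null (measured single-recording family-wise error ~0.13
  instead of the nominal 0.05). With the warp, the engine+sampler
  combination is calibrated under exchangeable nulls (FWER ≈ 0.04–0.05);
  the identity-pairing configuration retains a small residual variance
  excess (~5% per cell) and measures at FWER ≈ 0.07 at 6 trials per side —
  a property of comparing the one true pairing against reassignments,
  reported by `scripts/acceptance.py` alongside the exchangeable
  calibration.
* **Sign-flip baseline tests** for firing-rate curves: per-trial
  baseline-subtracted rate curves are tested against zero by flipping the
  signs of random trial subsets.

Permutation vectors are retained for audit, and all engines are
deterministic given a seed. Thresholding is two-sided; directional
contrasts read the sign of the cluster z-sum.

## Contact selection and significance

ECoG strips are re-referenced to neighbour differences (contact_i −
contact_{i+1}; n contacts → n−1 bipolar channels). Per recording and
effector side, the bipolar channel with the highest pooled-spike 60–80 Hz
PLV in a [−0.1, 0.4] s window around grip onset is selected (ties go to the
lowest index; the pooled fixed-window PLV, not the adaptive-window map, is
the selection metric). A selected contact counts as significant only if its
movement-window PPC exceeds the (1−α) quantile, α = 0.1 one-sided each, of
both: the trial-shuffle null, and spike-count-matched resamples (without
replacement, 500 draws) from a −3 to −2 s pre-movement window. Too few
pre-movement spikes leaves the baseline criterion undefined and the contact
non-significant.

## Firing characteristics

Rates use fixed 0.3 s windows per grid point; the pattern metrics reuse the
adaptive coupling windows so their sample sizes match the coupling
estimates: robust ISI CV (median absolute deviation of ISIs / median ×
100), %burst (fraction of ISIs < 10 ms), and ISI mode (Gaussian KDE with
normal-reference bandwidth on a log-spaced 2 ms–2 s grid augmented with the
data values, after excluding burst ISIs). Baselines are medians over
whole-recording segments — 0.3 s segments for rate, equal-spike-count
segments (the coupling target) for the pattern metrics; fewer than 10
segments flags the baseline as uncertain. Units are classified as
increasing/decreasing only when the sign-flip engine finds a significant
cluster of baseline-subtracted rate (baseline: cue − 0.5 s to Go) whose
span intersects the Go-to-grip-offset grid points.

## HFA and polarity standardization

The sign of a bipolar derivation is arbitrary, so phase 0 ("gamma peak") is
not comparable across recordings. High-frequency activity — the >300 Hz
band envelope of the 30 kHz wideband channel (4th-order two-pass high-pass,
full-wave rectification or analytic amplitude, 100 Hz low-pass, downsampled
to 1000 Hz) — is a sign-invariant proxy of local population discharge whose
maxima mark the physiological gamma peak. The whole-recording gamma phase
is divided into 126 equal bins spanning the cycle (the bin count is
configurable), the mean HFA per bin is smoothed with a wrap-around 20-bin
moving average, and the signal is flipped iff the mean smoothed HFA in a
0.4π-wide window at phase 0 is lower than over the two 0.2π-wide windows at
±π. Unvisited bins are filled with the profile mean before smoothing; a
flat profile (no distinguishable peak) leaves the signal unflipped with a
warning flag.

Spiking probabilities are then computed in k = 4 phase bins (edges −π,
−π/2, 0, π/2; a k = 5 variant is provided) from spikes in the [−0.1, 0.4] s
movement window, normalized by subtracting the same-sized baseline window
starting 3 s before grip onset. Group comparisons (bin-vs-bin within side,
side-vs-side per bin) use paired t-tests, switching to Wilcoxon signed-rank
when a Lilliefors test rejects normality of the differences, with
Benjamini–Hochberg FDR within each comparison family. The omnibus
repeated-measures ANOVA is deliberately left to general statistics
packages; this module exports its input table.

## Circular statistics and phase offsets

Per recording and side, the preferred phase is the circular median of
spike-coincident standardized gamma phases in the movement window
(candidates: data angles and their antipodes; minimize mean circular
absolute deviation; ties resolved toward the circular mean; the circular
mean is also stored). Recordings enter the group analysis only when the
movement-window PPC is positive on **both** sides — a near-uniform sample
has no meaningful preferred phase on either side, and the offset needs
both. Offsets (contra − ipsi, wrapped to (−π, π]) are unweighted. The group
mean direction carries a circular-dispersion (Fisher) confidence interval,
mean ± arcsin(z·√(δ̂/n)) with δ̂ = (1 − ρ̂₂)/(2R̄²), flagged undefined when
the arcsine argument leaves [−1, 1]. Concentration around the hypothesized
180° offset is tested with the V-test, V = nR̄cos(θ̄ − μ₀),
u = V√(2/n), upper-tail normal p. A global polarity flip rotates both
sides equally and cancels in the difference, so the offset analysis is
polarity-proof by construction. A sliding-window variant (0.5 s windows,
0.05 s steps over ±1 s around grip onset; both values configurable, the
recorded data do not pin them down) traces when the offset is expressed.

## Reaction time and vigor

Trials of one side are median-split by RT (or peak force / peak yank);
values strictly below the median form the lower half, the median trial
joining the upper half. Coupling maps are recomputed per half (windows and
targets included) and contrasted with the paired cluster engine. Separately,
all spikes in the 0.5 s after the Go cue are ordered by their trial's RT
and split into 7 equal-count bins; bin PLV against the spike-weighted mean
RT gives one Pearson r per recording, Fisher-z transformed (clamped at
|r| = 1 − 10⁻⁶) and t-tested against zero across recordings.

## Synthetic cohorts

The generator emulates the study conditions: 28 recordings by default with
18 trials per side; trial starts every 4.7 ± 1.2 s; cue→Go delays uniform
on [1, 2] s; RTs truncated-lognormal with mean 0.53 s, SD 0.21 s, capped at
the 2 s validity limit; grip durations lognormal 0.98 ± 0.45 s. The strip
carries a 1/f background (slope 1), a beta oscillation common to all
contacts with per-contact gains (suppressed to 0.3× during movement,
rebounding to 1.6× after grip offset), and a 60–80 Hz narrowband
*stochastic* gamma oscillation — band-passed noise, not a sinusoid, so its
instantaneous phase is non-trivial — confined to one contact, with
amplitude rising from 0.4 to 1.5 (in background-RMS units) in the
[−0.1, 0.4] s burst window of contralateral trials only. The burst
signal-to-noise ratio is a free parameter: the recordings constrain its
existence, not its size.

Spikes are an inhomogeneous point process with conditional intensity
λ(t) = rate·(1 + m(t)cos(φ_γ(t) − μ(t))), realized by thinning at
λ_max = rate·(1 + max m), exact for bounded intensity. The base rate
defaults to 30 spikes/s (STN tonic range; power replicates use up to
90 spikes/s, the multi-unit regime). Coupling is confined to a
pre-Go-through-onset window ([Go − 0.3 s, grip onset], where the per-trial
depth m_i = clip(m + slope·(rt_i − rt_mean), 0, 1) carries the RT
dependence — the slope is dm/dRT, so negative slopes make fast grips couple
more strongly) and to the burst window (base depth m). The ipsilateral
preferred phase is offset by π by default; per-recording preferred phases
jitter by SD 0.2 rad around the configured value. The 30 kHz wideband
channel is >300 Hz high-passed noise with envelope
1 + 0.3·cos(φ_γ − φ₀) (φ₀ = 0 for 'peak' polarity, π for 'trough'), a
0.3× envelope rise in contralateral burst windows, plus the upsampled LFP
of the gamma contact. All generators derive from a single seed
(per-recording streams spawned as SeedSequence([seed, r])) and are
bit-reproducible.

What the generator does **not** emulate: non-sinusoidal waveform shape,
broadband (non-oscillatory) high-gamma power increases, movement artefacts,
electrode drift, spike-sorting contamination, cross-trial nonstationarity
of the background spectrum, or volume-conduction structure across the
strip. Passing tests on these cohorts therefore demonstrate correctness of
the estimators and inference machinery under the assumed generative model,
not robustness to every pathology of intraoperative recordings.

## Numerical and scale choices

* Filtering uses second-order sections throughout for stability; the
  Hilbert transform is computed at the next fast FFT length and truncated.
* Constant signals have undefined phase (NaN), degenerate ISI samples
  return their common value as the mode, and Fisher-z inputs are clamped at
  |r| = 1 − 10⁻⁶.
* The 60/120/180 Hz notch stage is provided but off by default, matching
  the line-noise-free synthetic data.
* Test and acceptance problem sizes are desk-scale by design: cohorts of
  6–23 recordings with 6–16 trials per side (16 recordings × 14 trials per
  side for the reaction-time power replicates), calibration at 200 null
  replicates × 200 permutations, recovery at 5000 spikes per estimate.
  These sizes give the power the properties need while keeping a full run
  in minutes; the estimators themselves are size-agnostic.
* `scripts/acceptance.py` recomputes every reported quantity from scratch
  with the seed provided on the command line.

## Known limitations

* The circular-dispersion CI is first-order; at very low concentration it
  is flagged undefined rather than reported.
* The ISI-mode KDE uses the normal-reference bandwidth on raw ISIs; heavily
  multimodal ISI distributions may need a narrower bandwidth.
* Single-recording cluster tests at very low spike counts (target at the
  50 floor) are noisy; the equal-spike contract (counts within ±2 of
  target) is only guaranteed for rate modulations ≲3×.
* The repeated-measures ANOVA on phase-bin probabilities is out of scope;
  its input table is exported instead.
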