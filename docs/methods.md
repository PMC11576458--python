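# Methods

`eegagree` implements a complete wet-versus-dry EEG comparison analysis —
auditory oddball simulation, preprocessing, mismatch-negativity (MMN) and
theta-power extraction, resting-state phase-lag-index (PLI) connectivity
with minimum-spanning-tree (MST) summaries, and Bland–Altman agreement
statistics — validated end to end on synthetic paired recordings with
known ground truth.  This note records the models, the defaults and why,
and the design choices made where the procedure left room.

## The simulated study

Each synthetic subject is "recorded" twice: once with a gel-based cap
(*wet*, 61 scalp electrodes on 10-20 positions) and once with a multipin
dry cap (*dry*, 62 electrodes on an equidistant numeric grid, including
the fronto-central site 3Z).  Both systems sample at 1,024 Hz with left
and right mastoid channels and periocular EOG electrodes (three for wet,
two for dry).

**Oddball task.** The stimulus stream holds 612 standards and 102 + 102
deviants (12.5 % each) at a stimulus-onset asynchrony of 1.555 s, with
between-deviant gaps constrained to 2–4 standards and 10 habituation
standards delivered first.  The generator samples the between-deviant
gaps uniformly from {2, 3, 4} and repairs the total with seeded
single-step adjustments; run-in and run-out segments absorb at most
`max_gap` standards each, which fixes the feasibility window
`min_gap·(n_dev−1) ≤ n_standards ≤ max_gap·(n_dev+1)`.  An independent
checker (`validate_sequence`) re-verifies every constraint from scratch.

**Signal model.** Each channel carries 1/f background noise (spectral
exponent 1, flat below 0.5 Hz), scaled to 8 µV RMS for the wet and 16 µV
for the dry system — the dry cap is the noisier device, qualitatively
matching the lower SNR reported for dry electrodes.  The per-channel
noise processes of the scalp electrodes are spatially blended with a
Gaussian-distance correlation (width 0.6 on the unit sphere) so the
background has low effective spatial rank, as volume-conducted scalp EEG
does; this is a correlation structure only, not leadfield modeling.
Periocular and mastoid channels keep independent background, reflecting
their dominance by local skin and muscle sources.  Every tone adds an
N1-like difference-of-Gaussians template, spatially weighted by a
Gaussian falloff centred on FCz/3Z.  Deviants additionally receive

* a negative Gaussian deflection of height `mmn_amplitude` (default
  −3.5 µV) peaking at `mmn_latency` (125 ms) with σ = 50 ms — the "width
  50 ms" of the mismatch component is read as the Gaussian σ; and
* a 6 Hz burst with random per-trial phase, Gaussian envelope centred at
  200 ms, scaled so the 4–8 Hz power in the analysis window rises by
  `theta_burst_gain` dB (default 3 dB) over the analytic theta content of
  the 1/f background.

**Artifacts.** Blinks are 300 ms half-sines of 100 µV across the
vertical EOG pair (0.12 s⁻¹), with 30 % cross-talk on the lateral
periocular electrode and a frontal scalp projection of gain 0.3 decaying
with distance from the eyes.  Horizontal saccades (0.25 s⁻¹, 50 µV
ramp–plateau–ramp) dominate the lateral EOG, as real lateral EOGs are
ocular-dominated — a property the EOG-correlation ICA criterion relies
on.  Dry recordings additionally receive occasional step ("jump")
artifacts of 200–500 µV on random channels.

**Resting state.** Each channel sums four band-limited oscillators
(delta 0.5–4, theta 4–8, alpha 8–13, beta 13–20 Hz) plus a pink noise
floor.  For channel pairs listed in the ground truth, the lagging
channel's band component is the leading channel's component with its
analytic phase delayed by a constant lag, mixed with an independent
component by the coupling weight `c` (`c`=1: perfect locking, `c`=0:
independent).  The independent component is always drawn so the RNG
stream — and hence every uncoupled channel — is invariant to `c`.

What the generator does **not** emulate: realistic volume conduction and
source geometry, non-stationary artifact regimes (sweat, electrode
drift), heart and muscle activity, or any dependence between task
performance and EEG.  Passing recovery tests therefore demonstrates that
the *analysis chain* is correct and unbiased under controlled conditions,
not that it would behave identically on real recordings.

## Preprocessing

Fixed stage order: mastoid-average re-reference → automated bad-channel
detection → 0.1–25 Hz band-pass → epoching (−0.1→0.5 s task; 8 s rest)
→ resampling to 512 Hz → bipolar EOG derivation → 15-component ICA with
EOG-correlation rejection (|r| > 0.2) → spherical-spline interpolation of
the flagged channels → peak-to-peak trial rejection.  A provenance log on
every epoch container records each step.

Numerical choices:

* **Filtering** — zero-phase Hamming-window FIR, realized as a high-pass
  (transition 0.1 Hz) followed by a low-pass (transition 6 Hz); symmetric
  type-I filters applied with centred FFT convolution and odd-reflection
  padding.
* **Epoch convention** — half-open `[tmin, tmax)`, so a −0.1→0.5 s epoch
  at 1,024 Hz has exactly 614 samples (307 after resampling).
* **Bad channels** — a channel is flagged when its RMS falls below
  1e−7 V ("no signal") or its robust z-score across scalp channels
  exceeds 5.  The MAD in the z-score is floored at 10 % of the median
  RMS; without the floor, near-identical channel amplitudes make the
  detector hypersensitive to benign spatial structure such as
  blink-loaded frontal sites.
* **ICA** — the scalp channels of the concatenated kept epochs (EOG and
  mastoids excluded) are reduced to 15 principal components, whitened,
  and unmixed with seeded extended infomax — the standard algorithm for
  scalp EEG, which isolates both super-Gaussian (blink, saccade) and
  sub-Gaussian sources.  FastICA variants were evaluated and rejected:
  on this class of data their unmixing was unstable, and components
  marginally crossing the rejection threshold could carry a large share
  of the evoked signal.  The unmixing is fitted on at most 80,000 time
  samples (strided subset; the signal is heavily autocorrelated) and
  applied to every sample.  Component activations are correlated with
  the bipolar vEOG and hEOG; components with |r| > 0.2 are subtracted
  from the data.  The same fitted transform cleans the wide (±1.25 s)
  epochs used for time-frequency analysis.
* **Interpolation** — Perrin-style spherical splines on unit-sphere
  positions, order m = 4, Legendre series to degree 7, ridge λ = 1e−5.
  The constant term makes splines exact on constant fields;
  leave-one-out error on a smooth dipolar field is < 15 %.
* **Trial rejection** — peak-to-peak over scalp channels against a
  configurable threshold.  The literal default is 150 mV (implausibly
  large for scalp EEG and therefore effectively permissive); a 150 µV
  preset is provided for realistic rejection behaviour.
* **Inclusion rule** — a subject's task data enters group analyses only
  with > 70 % of trials retained *and* plus–minus SNR > 1, evaluated per
  system.

## MMN, theta power, SNR

Habituation standards and standards immediately following a deviant are
excluded; both deviant types are pooled (per-type analysis is available
behind a flag); trial counts are equalized across conditions — and, per
subject, across systems — by seeded subsampling without replacement.
Evokeds are baseline-corrected on −0.1→0 s.  The difference wave
(deviant − standard) at FCz (wet) or 3Z (dry) yields the 100–150 ms mean
amplitude and the peak: by default the most negative sample (mode
`"neg"`, ties to the earliest sample), with `"abs"` as alternative,
because "maximum amplitude" is ambiguous for a negative component.

Plus–minus SNR: the signal is the deviant average in the window; the
noise reference repeats the average with the polarity of the 1st, 3rd,
5th … kept trial flipped, cancelling time-locked structure; the ratio of
the two RMS values is the SNR (infinite when the noise estimate is
exactly zero, which only happens for duplicated trials).

Time-frequency analysis uses complex Morlet wavelets with cycles rising
linearly from 3 at 1 Hz to 10 at 18 Hz, σ_t = n_cycles/(2πf), amplitude
normalization σ_t^(−1/2)·π^(−1/4), truncation at ±3σ_t, on a 1–18 Hz ×
−1.2→1.2 s grid in 1 Hz and 0.05 s bins.  Power is trial-averaged per
condition, dB-corrected against the −600→−300 ms baseline, and theta is
the inclusive mean over 4–8 Hz and 100–300 ms.  Time bins within one
wavelet half-length of an epoch edge are flagged and excluded from
window statistics.  Because task epochs for this analysis must span
±1.2 s, the pipeline re-epochs the cleaned continuous signal to ±1.25 s
and reuses the ERP-stage rejection decisions by event identity.

## Connectivity

Rest epochs are average-referenced (scalp channels only), filtered per
band with a 4th-order zero-phase Butterworth (reflection padding), and
Hilbert-transformed.  PLI between two channels is |mean sign(Δφ)| with
Δφ wrapped to (−π, π]; exact zero (mod π) differences contribute 0, and
the first/last 0.5 s of each epoch's phase series are discarded.  Pair
values are averaged over the upper triangle within an epoch, then across
epochs.  Distances default to 1 − PLI (bounded; 1/PLI is available —
both are order-reversing, so they give the same MST when it is unique).
The MST is built by Kruskal with lexicographic tie-breaking; the
diameter d (longest within-tree path, in links) is found by double BFS
and normalized as D = d/M with M = N−1 links.

## Agreement statistics

Differences are **wet − dry** (the gel system is the reference), so a
negative bias means the dry system overestimates; the convention is
recorded in every result object.  Bias = mean difference; limits of
agreement = bias ± 1.96·SD (sample SD, n−1); bias CI uses the t quantile
(z optional) with SE = SD/√n; LoA CIs use SE = SD·√(3/n).  A bias CI
excluding zero flags a systematic between-system difference.  The
2×2 within-subject ANOVA (system × tone) is computed from the exact
sums-of-squares decomposition, each effect tested against its own
subject-by-effect error term (df = 1, n−1) with partial η² as effect
size; degenerate (constant) tables return F = 0.  Paired t-tests support
one-sided alternatives with Bonferroni correction; the Wilcoxon
signed-rank alternative drops zero differences and uses the exact null
for n ≤ 25.  Cohen's d (paired) is labeled negligible/small/moderate/
large at 0.2/0.5/0.8.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → MMN/theta →
connectivity → agreement per subject and writes a tidy per-subject ×
system table, group agreement and test results, and a run report with
machine-readable exclusion reasons.  Every random element (sequence
randomization, noise, subsampling, ICA initialization) derives from the
run seed, so a config + seed pair reproduces all outputs bit-for-bit on
one platform.  Per-subject results are cached as JSON keyed by a hash of
the configuration; re-running a partially complete directory recomputes
only what is missing, and any config change invalidates the cache.
Recordings are persisted in a documented `.npz` container (volts,
channels × samples) with a TSV event table and JSON ground truth.

## Validation scales

The test suite validates parameter recovery at reduced problem sizes
chosen to keep the full run reproducible on a laptop: the
amplitude-recovery check uses 20 subjects with 408-standard/204-deviant
sequences (the same equalized trial count as the full design, 204 per
condition), and the coupling-recovery check uses five coupling levels
with 64 s of rest.  Definitional checks (PLI limits, MST topologies, dB
arithmetic, Bland–Altman worked examples) run at full precision.

## Known limitations

* The ICA stage assumes ocular-dominated EOG channels; on data where the
  EOG mirrors mostly background EEG the 0.2 correlation criterion would
  reject background components (and slightly attenuate evoked signals).
* The estimate of the theta-burst gain depends on an analytic
  approximation of the 1/f theta content; injected and recovered dB
  values agree only approximately at single-subject scale.
* Bland–Altman here is the classical independent-pairs form; repeated-
  measures and regression-based (proportional-bias) variants are out of
  scope.
* MST metrics beyond the diameter (leaf fraction, tree hierarchy) are
  not computed, though the edge list is exported for downstream use.
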