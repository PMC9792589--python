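# Methods

`orgephys` implements the signal-analysis chain used to assess whether a
human cortical organoid implanted in mouse retrosplenial cortex becomes
functionally integrated with the host visual system: stimulus-evoked LFP
propagation across a 4×4 surface microelectrode grid, spectral band power,
multi-unit event statistics with permutation nulls, and spike–field phase
locking. Because such recordings are rarely shareable, the package ships a
synthetic-data generator whose injected parameters serve as ground truth
for every analysis; this note records the models, the defaults, and the
numerical choices.

## Data model and conventions

Voltages are µV, times are seconds, sample 0 is t = 0; epoch and histogram
windows are half-open `[start, end)`. Channels sit on a 4×4 grid with
500 µm pitch and carry a manually assigned region label (`organoid`,
`cortex`, `ambiguous`) plus the 1 kHz impedance magnitude. Channels are
never dropped from the data array: exclusion (impedance > 4 MΩ) only
clears the `included` flag, and every downstream operation skips flagged
channels, so channel indices are stable across the pipeline.

## Preprocessing

**Band extraction.** LFP is the broadband signal low-passed below 250 Hz;
MUA is the 0.5–3 kHz band. Both filters are Chebyshev type II (flat
passband, 40 dB stopband per pass) applied forward–backward, so the
effective attenuation is 80 dB and the phase response is identically zero
— essential because peak-latency maps are read directly off filtered
traces. Type II was chosen over type I because passband ripple would bias
amplitude maps; the design order (8 low-pass, 6 band-pass) is the order of
the one-way filter before `filtfilt` doubling.

**Common-component removal.** Volume-conducted signal, line noise and
motion artifacts appear with near-identical weight on all pads. The
recording (decimated to 250 Hz; the mixing is a static spatial transform,
so unmixing estimated there applies at the full rate) is decomposed with
FastICA, and components whose absolute mixing-weight coefficient of
variation across channels is ≤ 0.25 are subtracted from the broadband
signal. The CV rule replaces manual component picking with a reproducible
criterion: a truly uniform component has CV 0, a single-channel source has
CV ≈ √(n−1). A config override with explicit component indices is kept for
curation.

Two safeguards keep artifact removal from damaging evoked signal. The
unmixing can be estimated on stimulus-free segments only (`fit_mask`; the
pipeline builds this mask from the stimulus protocol), since large evoked
transients violate the instantaneous-mixing model and otherwise leak into
the artifact components. And a candidate component is *protected* — not
removed — when its trial-averaged time course around pulse onsets
deviates from baseline by more than 8× the averaged-baseline noise: an
instantaneous decomposition cannot fully separate a propagating evoked
wave from a uniformly mixed artifact, and removing the uniform direction
in that situation subtracts the spatial-mean evoked wave, which flattens
latency maps (all channels collapse toward the mean wave's timing). The
protection rule is the automated analogue of a curator declining to
delete a component that visibly carries the brain's response; protected
indices are reported so the decision is auditable, and explicit
`removed_indices` override it.

When the data contain a large Gaussian-noise subspace the
FastICA iteration cannot converge there — rotations within a Gaussian
subspace are unidentifiable in principle — even though the non-Gaussian
common components are already separated; the library call raises by
default, while the pipeline proceeds and records `converged: false`.

## Evoked LFP propagation

Trials are epoched around the onset of a selected pulse within each
stimulus train; the per-channel peak is the extremum (negative by default,
matching the downward first deflection of the visual evoked response)
inside a 10–80 ms post-onset search window, which brackets the expected
~36–42 ms latencies while excluding the stimulus artifact. Amplitude is
referenced to the pre-onset baseline mean.

The propagation test asks whether the peak arrives later at one pad than
another. Observed Δ = delay_b − delay_a is compared against a null built
by permuting the 16 per-channel delays across channels (1000 draws,
without replacement) and recomputing Δ for a random pair; the p-value is
the t-tail of the studentized observed value, (Δ − null mean)/null sd,
with n_shuffles − 1 df. Both sidedness options are exposed: the
delay-growing-away-from-visual-cortex hypothesis is directional, so the
propagation analyses here use the one-sided variant; calibration on iid
delays gives a 0.048 rejection rate at α = 0.05 (two-sided, 500
replicates).

## Spectral power

Time–frequency power uses fixed-cycle complex Morlet wavelets
(n_cycles = 7, log-spaced 1–150 Hz grid) implemented as frequency-domain
Gaussian filters on the analytic signal. Power is normalized to one-sided
spectral density (µV²/Hz): white noise of variance σ² gives a flat density
2σ²/fs and a tone of amplitude A integrates to A²/2, which is what the
flat-spectrum and Parseval-style tests check. Band edges default to
delta 1–4, theta 4–8, alpha 8–12, beta 12–30, low gamma 30–60, high gamma
60–150 Hz; phase-locking analyses use the narrower 4–6 Hz theta band. The
organoid/cortex contrast normalizes each band to the cortex mean and tests
organoid < cortex across channels with a one-sided two-sample t-test.

## MUA events

MUA power is the full-wave rectified band signal, zero-phase low-passed
below 100 Hz; evoked SNR is 10·log10(peak trial-averaged power in the
response window / mean power in the 1 s pre-onset baseline). Events are
negative-going crossings of −k·sd (k ∈ [3, 4], plain sd over the whole
trace by default, median/0.6745 optionally) with a 1 ms dead time matching
the 1 ms overlap bin, so one waveform produces one event.

A calibrated caveat: for Gaussian noise occupying the 0.5–3 kHz band the
expected rate of −4σ crossings is √(m₂/m₀)·e⁻⁸ ≈ 0.6/s (Rice's formula;
the detector reproduces this within sampling error). With true spikes at
2 Hz that bounds detection precision near 0.78 even at the top of the
threshold range, while recall for −6σ spikes stays ≥ 0.95. Threshold
detection at these multipliers is a high-recall, moderate-precision
operation; rate estimates on real data include this crossing floor.

Event overlap between channels counts 1 ms bins occupied in both trains
(binary occupancy, bins aligned to t = 0). Significance comes from 10,000
circular shifts of one train, uniform on (1 s, T−1 s), preserving each
train's autostructure. The default p-value is (1 + #{null ≥ obs})/(1 +
n_shifts); because the overlap count takes few distinct values at ~2 Hz
rates, this p is discrete and conservative. A randomized tie-broken
variant — exactly uniform under the null — is provided and is what the
calibration study uses (rejection 0.07 at α = 0.05, KS uniformity p ≈ 0.2
over 200 replicates); the discreteness is a property of permutation tests
on small counts, not an implementation artifact.

Event-triggered averages (target events, all channels, −1 to +2 ms) check
spatial locality: independent channels shrink toward zero at the
±3·sd/√n CLT envelope — pointwise, a 3σ envelope is expected to be
exceeded at ~0.3% of points, so the locality check asserts the inside
fraction rather than an almost-sure bound — while a duplicated channel
shows the lag-0 deflection.

## Spike–field phase locking

LFP phase is estimated with DPSS multitapers (window 1 s, TW = 3, 5
tapers — the low end of the conventional 3–5 / 5–9 ranges — hop 50 ms,
zero-padding to the next power of two). The taper-summed complex spectrum
is read at the FFT bin nearest each requested frequency, rotated to
reference phase to the window center, and corrected by the analytically
computed taper-transform factor C(ν−f), which removes the rotation
incurred when a tone sits off the bin grid; residual phase error for an
on-grid tone is < 0.01 rad. Event phases are looked up at the nearest
window center, so a hop h attenuates measured locking by ≈ sinc(2πf·h/2);
at the default 50 ms hop and 5 Hz this is a 10% PLV attenuation, and
recovery analyses use a 10 ms hop where it is negligible.

PLV is |mean phasor|. The bootstrap follows the fixed-resample-size
convention (1000–2000 resamples of 50 events; a trial with fewer events
shrinks the resample with a flag): point estimate is the resample mean, CI
the 2.5/97.5 percentiles. The size-50 resultant has a finite-sample floor
(E[R] ≈ √(π/200) ≈ 0.125 for uniform phases), so CIs from the raw
estimator cannot cover 0 for unlocked spikes. Where the goal is recovery
of the population mean resultant length I₁(κ)/I₀(κ), `debias=True` maps
each resample through √(max(0,(mR²−1)/(m−1))) — the unbiased-R² transform,
exact for iid phases — under which the estimate recovers κ ∈ {0, 1, 2, 4}
within 0.05 at 500 events and the CI covers the truth in ≥ 90% of
replicates. The raw estimator remains the default because
condition comparisons at matched resample size cancel the bias.

Stim/no-stim comparison: events inside [pulse onset, onset + width +
100 ms] are "stim" (the partition pad is configurable). Significance per
frequency is the 95% CI of the PLV difference formed by pairing
independent bootstrap resamples excluding 0; a CI-overlap rule is provided
as a conservative alternative. The spatial map band-averages each
resample's PLV over 4–6 Hz and reuses one resample stream across field
channels, making the map a paired comparison (identical field channels
give identical entries). Rayleigh's test uses the standard series
approximation for p; at n = 67 its false-positive rate at α = 0.05 is
0.05 ± 0.01 over 10⁴ replicates.

## Synthetic data: what it emulates, and what it does not

`generate_recording` produces: biphasic evoked LFP kernels (Gaussian
lobes, 6/10 ms widths) whose latency grows linearly with distance from the
reference corner pad — defaults place cortex-proximal responses at 36 ms /
200 µV falling to 41.7 ms / 50 µV at the far corner, a 5.7 ms span, with
injected latencies snapped to the sample grid so recovery is exact;
evoked 60–100 Hz gamma bursts at pulse onsets; an ongoing 5 Hz oscillation;
Poisson spike trains (2 Hz) phase-locked to it by drawing von Mises phases
(concentration κ, trough-locked by default) and inverting them to spike
times, so true PLV is I₁(κ)/I₀(κ) by construction, with optional
stimulus-gated locking (κ inside stim windows, κ_no_stim outside); a
bursty shared source plus 60 Hz line added with identical weight
everywhere; and white + 1/f background noise in equal power (pure white
noise would make band-power tests trivially easy). The oscillation's
amplitude falls off linearly (70% by the far corner) from the reference
pad: a spatially uniform rhythm would be indistinguishable from volume
conduction (mixing CV = 0) and correctly removed by the ICA stage, and
real low-frequency rhythms attenuate away from their source. Stimulus
train onsets carry a seeded uniform jitter of one oscillation cycle
(0.2 s) so the ongoing rhythm is not phase-locked to the trial grid —
with a train period commensurate with the oscillation it would survive
trial averaging and bias evoked peak maps. Spike waveforms are
0.4 ms negative / 0.6 ms positive half-sine lobes, inside the MUA band,
with amplitude expressed in units of the channel's MUA-band background sd.
Anesthesia epochs alternate burst and suppression in whole-second blocks
(suppression envelope 5% of burst), with organoid-channel gamma *power*
scaled by `gamma_power_scale` (amplitude by its square root) and a 2%
per-channel amplitude jitter supplying the across-channel variance the
region t-test needs.

The generator is a statistical, not biophysical, model: no conduction
physics, no spike waveform diversity or bursting, no electrode drift, no
behavioral artifacts, and its noise is Gaussian — so passing tests
demonstrate that the analyses recover what they are designed to measure,
not that real recordings satisfy the generator's assumptions (the
detection-precision caveat above is one concrete example).

## Problem sizes and reproducibility

Validation runs use desk-scale sizes chosen to keep estimator noise well
inside the asserted tolerances: 20-trial noiseless evoked recordings at
20 kHz, ~500-event PLV recoveries with 100 CI replicates per κ, 500/200
replicate null calibrations, 10⁴-replicate Rayleigh calibration, 60 s
anesthesia epochs at 500 Hz. Every stochastic stage derives its RNG seed
as a stable hash of (master seed, stage name), so pipeline reruns are
bit-identical (verified by report hashing, which excludes wall time and
output location) and stage results do not depend on execution order.
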