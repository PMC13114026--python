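# Methods

This note documents the models implemented in `sevoeeg`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions used throughout.

## Recording model and conventions

A recording is a channels × samples array of potentials with an explicit
sampling rate and physical unit (default mV). The six signal sites of the
mouse montage are F1/F2 over prefrontal cortex (+1.8 mm AP, ±1.0 mm ML),
C1/C2 over anterior parietal cortex (−1.4 mm AP) and P1/P2 over posterior
parietal cortex (−2.8 mm AP), with cerebellar reference and ground screws.
The montage literature uses both a region vocabulary (prefrontal/parietal
coordinates) and a channel vocabulary (F/C/P); the mapping fixed here is
F ↔ prefrontal pair, C ↔ anterior parietal pair, P ↔ posterior parietal
pair.

Time windows are half-open `[start, end)` seconds, converted to sample
indices by `floor(t·fs)`; adjacent protocol steps therefore never share a
sample and per-step slices concatenate exactly to the parent recording.
All amplitude thresholds are unit-checked: comparing a 5 mV criterion
against a µV recording raises instead of silently comparing numbers. The
default sampling rate for synthetic data is 500 samples/s — a typical rodent
EEG acquisition rate, comfortably above the band of interest — but fs is
always carried in the data, never assumed.

The stepped exposure protocol defaults to 2.0 → 2.8 vol% sevoflurane in
0.2% increments with 5 min per step. Behavioral staircases use a 0.1 vol%
grid: MAC-type ascending from 2.5 vol%, RR-type descending from 2.0 vol%
after a nominal 20 min pre-exposure. Dwell and pre-exposure times are
bookkeeping only; no pharmacokinetic equilibration is modeled.

EDF files are written by a minimal in-package 16-bit codec (one signal per
channel, symmetric physical range covering the signal; writing refuses to
clip if an explicit range is exceeded). Round trips are exact to the 16-bit
quantization of the declared range; the test suite cross-checks the codec
against an independent EDF reader.

## Burst-suppression segmentation

A sample is sub-threshold iff |V| < threshold (default 5 mV), applied to the
raw referenced signal with no envelope smoothing — the simplest faithful
operationalization of a voltage-based threshold; an RMS-envelope mode exists
but is off by default. Maximal sub-threshold runs lasting *strictly* longer
than 0.5 s are suppression (a run of exactly 0.5 s is burst). Runs separated
by supra-threshold gaps ≤ `merge_gap_s` are merged before the duration test;
the default is no merging. Segmentations are exact partitions: interval
lengths always sum to the epoch duration, and BSR ∈ [0, 100] by
construction. BSR is computed over the full 5-min step; onset concentration
is the lowest step with BSR > ε (ε = 0). Where a study identifies
suppression epochs by visual inspection guided by the same amplitude and
duration rule, this package applies the deterministic rule only — a
substitution worth stating prominently, since manual curation can drop
artifactual events the rule keeps.

The detector default channel is F1 (frontal channels are the conventional
site for burst-suppression quantification); the channel is configurable.

## Multitaper spectral estimation

Windows are 2 s, non-overlapping, NW = 3, K = 5 = 2·NW − 1 tapers; taper
counts beyond 2·NW − 1 are leakage-dominated and refused unless explicitly
overridden. Window sample counts are floored to even length; the FFT length
equals the window length (no zero padding), giving 0.5 Hz bins at the
defaults. Per window the mean is removed (anesthesia EEG drifts; the flag
is exposed), each taper's eigenspectrum is |FFT(taper·x)|²/fs, and the K
eigenspectra are averaged uniformly (the common toolbox default;
eigenvalue-weighted averaging is available). One-sided density scaling
doubles every bin except DC and Nyquist, so the density integrates to the
windowed-signal variance (verified to 5% on white noise). dB conversion is
display-only; raw densities are retained. Group spectrograms are elementwise
medians across animals on validated identical grids.

DPSS tapers are obtained from scipy's tridiagonal formulation; the contract
(orthonormality to 1e−10, concentrations strictly decreasing in (0,1),
agreement with a brute-force eigendecomposition of the sinc concentration
kernel to 1e−8 at n = 64) is enforced by tests rather than assumed.

## Theta topography and the anteriorization index

Band power is the trapezoidal integral of the density over bins whose
centers lie in [4, 8] Hz (inclusive bounds; at 0.5 Hz resolution that is
bins 4.0 … 8.0), summarized per step and channel by the median over windows,
then averaged across animals. Maps interpolate site values over the flat
AP × ML plane by inverse-distance weighting (power 2) with a 1.5 mm mask
around the electrode hull — node-exact, and free of spherical-head
assumptions that would be inappropriate for a six-site mouse montage; an
animal missing a site is excluded from that step by default (logged).

No standard scalar for "anteriorization" exists; the index used here is the
package's own: mean(F1, F2) / mean(P1, P2) band power. It is scale-invariant
and deliberately excludes the central channels so that it contrasts the two
ends of the AP axis. Steps whose BSR exceeds a cutoff (default 5%) can be
flagged, because theta maps are meaningful for the pre-burst-suppression
regime.

## Behavioral staircases

The ascending estimator returns the concentration of the first no-movement
trial; the descending estimator the concentration of the first righting.
No mid-step interpolation is applied (some MAC protocols average the last
two trials; the first-flip convention is used here). For deterministic
agents both estimators are provably grid-quantized versions of the true
threshold — ascending is the grid ceiling, descending the grid value at or
just below — and the test suite checks this by enumeration, together with an
exact trial-sequence enumeration of the estimate distribution under
psychometric (Gaussian-CDF) agents. Righting is resolved at step
granularity: righting "during" a step maps to that step's concentration,
the first-occurrence reading of an ambiguous convention.

## Gated two-sample rule

Normality is tested per group with Shapiro–Wilk and variance homogeneity
with a two-sided F-ratio test (Levene by flag); the specific tests are this
package's documented choices where a protocol says only "tested for
normality and homogeneity of variance". All gates passing at α = 0.05
selects the pooled-variance Student's t (pooled, not Welch — the rule only
reaches t after an equal-variance gate); any failure selects the two-sided
Mann–Whitney. Constant samples fail the normality gate by convention. For
groups of ≤ 8 the Mann–Whitney p is exact: the null distribution of the
rank sum (midranks under ties) is enumerated by a subset-sum recursion
equivalent to full label permutation; beyond the exact range a tie-corrected
normal approximation is used and noted. Calibration of the full rule (type-I
error ≈ 0.05 ± 0.015 under a normal null at n = 10/group, 1000 replicates)
is part of the acceptance suite. `t_from_summary` reproduces pooled t-tests
from printed mean ± SD ± n triples, enabling re-tests of published tables.

## Synthetic generator

The generator's job is to emulate the *structure* of stepped-sevoflurane
EEG well enough that every pipeline stage can be validated against ground
truth — not to be a biophysical cortical model.

**Burst/suppression process.** Within each step the state alternates
between burst and suppression as an alternating renewal process with
exponential dwell times — the simplest process with a controllable
stationary fraction, and stationary from the first sample because
exponential dwells are memoryless. The stationary suppression fraction
follows the logistic dose-response `p(c) = 1/(1+exp(−slope·(c−EC50)))`,
gated to exactly 0 below `EC50 − 3/slope` so that low steps contain no
suppression events at all, as in real dose ramps. The mean suppression
dwell is 6 s with the burst dwell scaled per step to hit the target
fraction. Six seconds is ≥ 4× the detector's 0.5 s duration floor by
design: with exponential dwells the expected fraction of suppression time
in sub-0.5 s dwells is 1 − e^(−x)(1 + x) with x = 0.5/6, about 0.3%, so
dwell-length censoring cannot confound the 1-percentage-point recovery
property.

**Signals.** Bursts carry a 6 Hz sinusoid (random phase per channel) over a
1/f background (spectrally shaped noise, unit SD scaled to 1 mV) — a
narrowband process rather than a pure tone, so multitaper bandwidth
behavior is exercised. Site amplitudes interpolate linearly from a
posterior-dominant profile (P 24, C 16, F 10 mV; burst amplitude statistics
are not reported in this literature, so the scale is a documented free
parameter chosen to sit well above the 5 mV criterion) toward its anterior
mirror with weight `clip(shift_rate·(c − c₀), 0, 1)`. Suppression periods
carry only Gaussian noise. The noise SD defaults to threshold/4.5: any
value ≤ threshold/3.29 keeps a single sample sub-threshold with probability
≥ 0.999, but at hundreds of samples per second a 10⁻³ per-sample excursion
rate would split long suppression runs into sub-0.5 s fragments and bias
detected BSR low by several points, so the default uses a ~7·10⁻⁶ tail.

**Strain presets.** The control-like preset uses suppression EC50 2.45
vol%, theta shift rate 0.5 /vol%, MAC 2.67 / RR 1.65 vol%; the
sensitive-strain preset uses EC50 2.05, shift rate 1.5, MAC 2.68 / RR 1.10.
The sigmoid slope is 20 throughout: with the 3/slope gating floor this
places the first suppression-bearing step at 2.4 vol% for the control
preset (floor 2.30 > 2.2) and 2.0 vol% for the sensitive preset (floor
1.90 < 2.0), which is the qualitative strain contrast the presets are meant
to embody — chosen analytically from the gating formula, not fitted.
Behavioral SDs (0.05 / 0.10 vol%) follow the scale of published group SDs
for these endpoints. Cohorts draw per-subject parameters with
multiplicative Gaussian jitter (default CV 0.02 on EC50) and per-subject
seeds spawned as `SeedSequence([master, subject_index])`, so no stream is
reused.

**Topography cohorts.** Theta maps describe the pre-burst-suppression
regime, so the pipeline's mapping cohort uses a suppression-free parameter
variant (EC50 pushed above the protocol range) while keeping each strain's
theta dynamics. Without this, near-total suppression at high steps would
reduce the map to noise power rather than burst theta.

**What the generator does not emulate — and what passing tests therefore do
not show.** There is no volume conduction or inter-channel correlation
structure (channels share the brain-wide suppression state but have
independent noise), no EMG/movement artifacts, no line noise, no
within-step drift of anesthetic depth, no burst waveform diversity
(real bursts are broadband transients, not windowed theta), and behavioral
agents have no trial-to-trial memory. Recovery of programmed parameters on
these data validates the estimators' correctness, not their robustness to
artifacts; on real recordings the artifact-rejection and channel-quality
steps of an acquisition pipeline remain the user's responsibility.

## Problem sizes and numerical choices

The test suite and the acceptance script run the EEG recovery experiments at
the full study geometry (5 × 300 s steps at 500 samples/s, 50 seeds per
strain; topography at 3 × 300 s, 50 replicates per strain) — these complete
in well under a minute each. Scaled-down cohorts (60 s steps, 200 samples/s,
n = 3–5) are used only for pipeline plumbing tests where the quantity under
test is determinism, not an estimate. Degenerate inputs fail loudly:
empty recordings, protocols extending past the recording end (even by one
sample), bands above Nyquist, constant samples in the t branch, truncated
staircases without a terminating response. Ties in the exact Mann–Whitney
use midranks with doubled-rank integer arithmetic so the subset-sum
enumeration is exact; the two-sided p is the probability of a rank sum at
least as far from its null mean as observed, which coincides with the
classical doubled one-tail definition for the symmetric tie-free null.

## Known limitations

* The 5 mV suppression criterion presumes recordings in mV at unusually
  large amplitude for mouse EEG; both the threshold and its unit are
  configurable, and nothing hard-codes the pairing.
* The anteriorization index is this package's own scalar; values are
  comparable within a study but not across publications.
* The exact Mann–Whitney enumerates up to a combined n of 25; larger
  samples fall back to the tie-corrected normal approximation (noted in the
  result object).
* The EDF codec writes plain EDF (no EDF+ annotations) and requires a
  uniform sampling rate across channels.
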