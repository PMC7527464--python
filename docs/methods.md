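# Methods

`psilat` lateralizes the hemisphere containing the seizure-onset zone
(SOZ) from seizure-free (interictal) intracranial EEG recorded with
hybrid depth electrodes, using the surrogate-corrected nonlinear
predictability score ψ. This note documents the model, its parameters,
the numerical choices, what the synthetic-data generator does and does
not emulate, and the known limitations.

## The rank-based predictability score S

A scalar window x₁…x_N is delay-embedded with dimension m and delay τ
(embedding window η = (m−1)τ), giving states **x**_i for i = η+1…N. For
every reference state **x**_{i0} (i0 = η+1…N−h) the k nearest embedded
states are found among j = η+1…N−h, excluding temporally close indices
|i0−j| ≤ W (Theiler correction). Prediction quality is measured on
ranks, not amplitudes: the amplitude distances u_{i0+h,j} = |x_{i0+h} −
x_j| over j = η+1…N with |i0+h−j| > W are sorted ascending into a rank
list of size M, and the mean rank R_{i0} of the k neighbor futures
x_{j0,r+h} is compared against full predictability R_L = (k+1)/2 and
chance R^U = (M+1)/2:

    S = ⟨ (R^U − R_{i0}) / (R^U − R_L) ⟩ over i0 = η+1 … N−h.

S = 1 for periodic dynamics, S ≈ 0 for uncorrelated noise; linear
autocorrelation also raises S, which is why the surrogate correction
below is needed for specificity.

Numerical conventions:

* **Neighbor ties** are broken toward smaller j (stable order) and
  distances are compared as squared Euclidean norms — a monotone
  transform that avoids spurious ties from square-root rounding. Results
  are bit-reproducible.
* **Amplitude ties** receive mid-ranks (average of tied positions),
  which keeps R^U exact for quantized amplitudes. A constant window is
  degenerate (every distance ties) and is flagged and excluded rather
  than scored.
* **M by counting**: the rank-list cardinality is the actual candidate
  count per reference, which equals N−2W−1 in the interior and grows
  toward the edges where the Theiler band is clipped.
* **Horizon shift**: the rank list used for R_{i0} is built at the
  shifted index i0+h, with the Theiler exclusion applied at i0+h; R^U
  uses the cardinality of that same list. Neighbor futures always
  belong to it, since |i0+h − (j0,r+h)| = |i0 − j0,r| > W.
* The per-window cost is O(N²) (N = 4096 → ≈17M index pairs); the
  implementation streams one reference row at a time (never a full N×N
  table) inside a compiled kernel, ≈0.1 s per window on one core.
  Windows are independent work units with no shared mutable state.

Default parameters (for 256 Hz windows): m = 8, τ = 8 samples, k = 5,
h = 8 samples, W = 38 samples, window length 16 s (N = 4096).

## IAAFT surrogates and ψ

One iterative amplitude-adjusted (IAAFT) surrogate is drawn per window.
It embodies the null hypothesis of a stationary linear stochastic
correlated Gaussian process observed through an invertible static
measurement function: the surrogate keeps the window's amplitude
distribution exactly (multiset identity, guaranteed by ending on the
amplitude-adjustment step) and its periodogram approximately (relative
RMS deviation typically < 10⁻²; the tolerance is a repository
convention). Iteration stops at an exact fixed point of the amplitude
rank vector, or after 200 iterations (typically ~100 at N = 4096).

ψ = S_original − S_surrogate. Under the null ψ ≈ 0; nonlinear
deterministic structure gives ψ > 0; ψ < 0 can occur, e.g. under
nonstationarity. One surrogate per window makes ψ a baseline
correction, not a formal per-window test. Surrogate randomness is
counter-based: each (channel, window) derives its own stream from the
master seed, so any window is reproducible in isolation.

**Finite-sample caveat.** For oscillatory (spectrally peaked) processes
the fully converged IAAFT fixed point is slightly *more* predictable
than the original — the surrogate locks onto the window's spiky sample
periodogram — giving a small negative ψ bias. In our calibration runs
(N = 4096, default score parameters) the per-window bias was ≈ −0.008
for a sharp 10 Hz resonance (5 Hz bandwidth), ≈ −0.002 for moderately
damped resonances (20–40 Hz bandwidth), and indistinguishable from zero
(|bias| < 0.0005 at n = 400 windows) for white noise and for
non-oscillatory low-pass AR(2) processes, even strongly correlated ones
(lag-1 autocorrelation 0.78). The bias tracks oscillatory peaking, not
correlation per se, and shrinks when the iteration is stopped early.
Real EEG with sharp rhythms may sit anywhere between these regimes; ψ
maps with a common small offset still lateralize correctly because the
comparison is between hemispheres.

## Preprocessing

Macro contacts (8 per electrode, innermost→outermost) are re-referenced
to 7 bipolar channels (neighbor differences; sign is a convention, S
and ψ are affine-invariant). Micro bundles are referenced by
subtracting the mean of the 8 recording wires (the low-impedance
reference wire is not data); outputs sum to zero per sample. Signals
are band-passed 0.5–40 Hz with a 4th-order Butterworth applied forward
and backward (zero phase; effective magnitude |H|²), then decimated
2048 → 256 Hz by keeping every 8th sample — the 40 Hz edge already
guards the 128 Hz post-decimation Nyquist. Filtering uses reflective
padding of one settling length of the slow edge (3·fs/0.5 Hz); the
default scipy pad is orders of magnitude too short and leaks a
low-frequency transient into every window. Windows are non-overlapping
16 s segments anchored at the recording start; the trailing remainder
is discarded.

## Sleep-stage alignment

Hypnograms are 30 s epochs labelled W, REM, N1, N2, N3 (case-insensitive,
'R' accepted). The 16 s window grid interleaves with the 30 s epoch
grid, so a window may overlap two epochs: it inherits their common
label and is excluded when they disagree (a stage transition) or when
any overlapped time is unscored. Windows are anchored at recording
start, not re-aligned to epoch boundaries (minimal assumption; an
optional start_offset shifts the epoch grid). Note the geometry: with
alternating single-epoch stages, 8 of 15 windows per 240 s period still
fall inside a single epoch.

## Averaging and statistics

Excluded windows (transition, unscored, artifact-masked, unscorable)
never enter any mean. Averaging is two-step: per-window channel means
within an electrode (7 bipolar channels, or 8 wires of a bundle), then
per-stage time averages (SEM across windows), then unweighted averages
of electrode means within a hemisphere — electrodes count equally
regardless of channel or window counts.

Inference per night and modality: a two-way ANOVA of the per-window
electrode means with factors location (SOZ vs non-SOZ hemisphere) and
sleep stage, Type II sums of squares (robust main-effect inference in
the heavily unbalanced stage design; the all-identical degenerate case
returns F = 0, p = 1). Post-hoc per stage: two-sided Mann–Whitney U on
per-window electrode means pooled within hemisphere, exact enumeration
for small tie-free groups and the tie-corrected normal approximation
otherwise, significant iff p < 0.001 (0.05 Bonferroni-corrected for
fifty comparisons: 5 stages × 2 modalities × 5 nights).

The pooled lateralization summary counts, per level (electrode,
hemisphere) and modality, the comparisons in which the SOZ-side mean is
strictly greater than the contralateral one (exact ties count as
unfavorable, conservatively; electrode-level comparisons require a
contralateral homologue with the same anatomical label). Chance
probabilities are exact one-sided binomial upper tails at p₀ = ½,
evaluated in integer arithmetic; percentages are half-up rounded to one
decimal. A night's inferred SOZ side is the majority over the
stage × modality hemisphere-mean comparisons, with the signed sum of
differences as tie-break.

## The synthetic-night generator

No public recordings exist for this kind of data, so the generator
produces complete nights with the statistical structure the analysis
assumes:

* **Null channels** — a stationary AR(2) Gaussian process observed
  through the invertible map y = x + 0.1·x³ after per-channel
  standardization. Coefficients are derived from a (resonance frequency,
  bandwidth) pair at whatever sampling rate a channel is generated at;
  the defaults (0 Hz resonance, 60 Hz bandwidth, i.e. a double real
  pole) give a non-oscillatory 1/f-like broadband background with
  strong short-range correlation (lag-1 autocorrelation ≈ 0.78 at
  256 Hz). This choice keeps the generator inside the regime where the
  surrogate correction is unbiased (see the caveat above), which the
  null-consistency check of the whole pipeline requires; oscillatory
  backgrounds are available through the configuration.
* **SOZ channels** — the same background plus a nonlinear deterministic
  component: the first coordinate of the Rössler flow (a = b = 0.2,
  c = 5.7), integrated by RK4 at 6 time units per second so its
  dominant period is ≈1 s, well inside the analysis band. Any
  low-dimensional flow would do. Its amplitude is `effect_size` ×
  stage multiplier × the referenced-channel noise sd. Defaults:
  effect_size 2.0 (calibrated by seeded simulation: mean ψ ≈ 0.05 per
  window at multiplier 1, against a null ψ sd ≈ 0.015), stage
  multipliers N2 = N3 = 1.0 > N1 = 0.75 > W = 0.5 > REM = 0.25
  (non-REM-dominant modulation).
* **Geometry** — contacts of an electrode share a correlated AR
  background plus contact-specific AR innovations, so bipolar
  referencing is meaningful rather than cancelling everything. The
  deterministic source projects onto contacts/wires with
  polarity-alternating unit gains (a nearby dipolar source), keeping
  every raw channel's variance equal so the shared background cancels
  exactly under both reference schemes; amplitudes are solved so the
  post-reference deterministic-to-noise ratio equals `effect_size`.
  Hypnograms follow a configurable cycle of stage runs; artifact
  injection (off by default) adds half-second 10-sigma pulses listed in
  the mask.

Everything is a pure function of the configuration including its
master seed.

What the generator does **not** emulate: spindles, K-complexes,
interictal spikes and other transients; 1/f spectral slopes; volume
conduction and inter-electrode correlation of the effect;
nonstationarity of the background. Passing tests therefore demonstrate
correctness of the pipeline and the statistical behavior of ψ under
the stated null and alternative — not clinical performance on real EEG.

## Problem sizes used in validation

Full-scale nights (13.6 h, 6 electrodes per hemisphere) are the
generator defaults but are not exercised in the test suite; the
end-to-end validation uses the package's reduced conditions
(`reduced_night_config`): 10-minute nights, 1 electrode per hemisphere,
2-minute stage runs, 4 channels per electrode and modality (evenly
spaced, mirroring the study's display subsampling), one scored window
per stage. At these sizes the SOZ side is recovered in ≥90% of 20
seeded nights, and 6 zero-effect nights give hemisphere-favorable
fractions consistent with the 50% chance level. Null calibration and
deterministic discrimination use 200 windows each at the full window
geometry (16 s × 256 Hz).

## Known limitations

* The IAAFT ψ bias for narrow-band signals (above) is inherent to the
  exact-convergence scheme; surrogate ensembles or other surrogate
  classes (out of scope) would be needed to quantify it per window.
* The reduced validation nights trade statistical power per night for
  replication count; single-window stage means are noisy, and the
  night-level decision leans on the strongly modulated non-REM stages.
* Electrode-level pairing requires matching anatomical labels on both
  hemispheres; unpaired electrodes are excluded from electrode-level
  (not hemisphere-level) comparisons.
* ANOVA p-values from the heavily unbalanced real design depend on the
  sums-of-squares convention; Type II is a choice, not the only one.
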