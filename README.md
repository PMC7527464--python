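# psilat

Seizure-onset-zone (SOZ) lateralization from seizure-free (interictal)
intracranial EEG, using the surrogate-corrected nonlinear
predictability score ψ.

## The problem

In pharmacoresistant focal epilepsy, surgery requires knowing where
seizures start. Hybrid depth electrodes record EEG at two spatial
scales — eight clinical macro contacts along the shaft and a bundle of
micro wires at the tip — and quantitative analysis of the *seizure-free*
intervals can help lateralize the SOZ without waiting for seizures.
`psilat` implements such an analysis for whole-night recordings scored
into sleep stages (W, REM, N1, N2, N3): epileptic tissue tends to show
stronger nonlinear-deterministic signatures, so the hemisphere with
higher ψ is the candidate SOZ side.

## The method

For every non-overlapping 16 s window of every referenced channel
(bipolar macro montage; bundle-mean micro reference; 0.5–40 Hz
zero-phase Butterworth; 2048 → 256 Hz):

1. **Rank-based nonlinear predictability score S.** Delay-embed the
   window (dimension m = 8, delay τ = 8 samples), find each state's
   k = 5 nearest neighbors outside a Theiler window W = 38, and compare
   the mean rank R of the amplitude differences between the reference's
   future (horizon h = 8) and the neighbors' futures against chance:

       S = ⟨ (R^U − R_{i0}) / (R^U − R_L) ⟩,   R_L = (k+1)/2,  R^U = (M+1)/2

   S = 1 for periodic dynamics, S ≈ 0 for uncorrelated noise.
2. **Surrogate correction.** One iterative amplitude-adjusted (IAAFT)
   surrogate per window — same amplitude distribution exactly, same
   periodogram practically — embodies the null hypothesis of a linear
   stochastic Gaussian process seen through a static invertible
   measurement function. ψ = S_original − S_surrogate; ψ ≈ 0 under the
   null, ψ > 0 for nonlinear deterministic structure.
3. **Averaging and statistics.** ψ is averaged per sleep stage over
   channels of each electrode, then over electrodes of each hemisphere
   (transition and artifact windows excluded); per night and modality a
   two-way ANOVA (location × stage, Type II) and per-stage Mann–Whitney
   tests with Bonferroni correction (α = 0.05/50 = 0.001); pooled
   favorable-comparison counts with exact binomial chance probabilities.

Because no recordings of this kind are public, `psilat.simulate`
generates complete synthetic nights (signals, channel map, hypnogram,
artifact mask, ground-truth side) with the structure the analysis
assumes — an AR(2)-plus-static-nonlinearity null and a sleep-modulated
Rössler component on SOZ-side channels. See `docs/methods.md`.

## Worked example

Simulate a short night (10 minutes, one electrode per hemisphere, SOZ
on the left), run the full pipeline, and report:

```sh
psilat run --out demo --seed 5 --duration-hours 0.167 \
    --electrodes-per-hemisphere 1 --windows-per-stage 1 --cycle-epochs 4
```

takes about a minute and prints:

```
Ground-truth SOZ hemisphere: L
Inferred SOZ hemisphere (majority of stage x modality hemisphere means): L

Pooled favorable comparisons (SOZ side strictly greater):
  electrode  macro   4/5   = 80.0%  binomial p = 1.88e-01
  electrode  micro   5/5   = 100.0%  binomial p = 3.12e-02
  hemisphere macro   4/5   = 80.0%  binomial p = 1.88e-01
  hemisphere micro   5/5   = 100.0%  binomial p = 3.12e-02
```

Reading the output: of the 5 sleep stages, the left (true SOZ) side had
the higher mean ψ in 4/5 macro and 5/5 micro comparisons; the binomial
p is the chance probability of at least that many favorable outcomes
from fair coin flips (one short night is suggestive, not significant —
the study design pools such counts over nights and electrode pairs).
The `demo/` directory then contains the windowed dataset, the psi
profile (`profile/profile.tsv`, one row per channel × window with S_O,
S_S and ψ; `psi_matrix.tsv` in channels × windows orientation), and the
report tables (`anova.tsv`, `posthoc.tsv`, electrode/hemisphere stage
means, `summary.tsv`). With one scored window per stage per channel the
ANOVA and post-hoc cells are too small and are skipped with a warning;
longer nights populate them. For library use see
`psilat.pipeline.run_synthetic_night` and
`psilat.simulate.reduced_night_config`.

The same `preprocess → score → report` subcommands run on real data: a
directory of per-channel float32 signals with a `channels.tsv` sidecar
(or an EDF file, read through `mne` if installed), a `channel_map.yaml`
with the electrode topology and the ground-truth side, a plain-text
hypnogram (one 30 s label per line) and an optional artifact mask.

Interpretation: per-window ψ is small (order 0.01–0.05); what matters
is its consistent elevation on one side. A favorable comparison is a
stage × electrode (or hemisphere) comparison where the SOZ side's mean
ψ is strictly higher; pooling such counts across stages and nights
gives the binomial chance probabilities in the summary.

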