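# Methods

This note documents the models and estimators implemented in `mvfeeg`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Paradigm and conventions

A trial runs from the "ready" cue at −5 s through the go cue at 0 s, a 10 s
motor task, and 5 s of rest. Embodiment onset is operationalized as the
pedal-press time; the analysis window is the half-open interval
[t_pedal, t_pedal + 4 s). All windows are half-open `[start, start + dur)`,
times are seconds relative to the go cue, and sample indices are 0-based.
Trials without a pedal press, or with less than 4 s of task remaining after
it, are excluded; trials whose peak-to-peak amplitude exceeds 150 µV or
whose fitted linear drift exceeds 20 µV/s on any channel are rejected
beforehand. Left-handed subjects' recordings are mirrored channel-wise
(C3↔C4, F3↔F4, …) so that C3 always denotes the dominant/static hemisphere;
the flip is an involution and midline channels map to themselves.

Independent-component artifact decomposition is out of scope: the
amplitude/drift trial rejection above is the implemented cleaning step, and
the synthetic generator controls contamination, so downstream analyses only
require clean epochs. The hook is the rejection stage in
`preprocess`/`pipeline`.

## Montage and spatial filter

Channel positions come from MNE's idealized `standard_1020` montage,
reduced to the 32 extended-10/20 labels used here and projected
azimuthally for display. The "small" Laplacian subtracts the unweighted
mean of each channel's 4 nearest neighbors (Euclidean scalp distance);
neighbor sets are computed once per montage and frozen on the `Montage`
object, so a given montage always yields the same filter. With 4
neighbors the neighbor mean is computed in pairwise groups, which makes the
filter *exactly* zero on a spatially uniform field (no floating-point
residue). Montage subsets (used in reduced simulations) may have fewer
neighbors at the same convention.

## ERD/ERS

The band-passed signal (4th-order Butterworth, zero-phase
forward–backward; 8–13 Hz alpha, 13–26 Hz beta) is squared and averaged in
0.8 s windows slid in 0.004 s steps across the analysis window — 801
window positions for the standard parameters. The baseline is the mean of
the same quantity over −0.9..−0.1 s. The default divides the trial-mean
power curve by the trial-set mean baseline rather than each trial by its
own baseline: an 0.8 s narrowband baseline has ~8 effective samples, so
per-trial division is upward-biased by Jensen's inequality (≈ +13% of the
power ratio at alpha bandwidth) and noisy; the trial-set mean is stable.
Per-trial division remains available (`per_trial_baseline=True`).

In the pipeline, each subject's baseline is additionally pooled across
conditions (`baseline_power` + the `p_base` argument of `erd_matrix`).
The baseline interval precedes the go cue and any stimulation, so it is
condition-independent by design; sharing it removes independent baseline
noise from between-condition contrasts, which is where the statistics
operate. `compute_erd` on its own still uses the baseline of the trials it
is given.

Topography values are defined as the time-mean of the channel's ERD curve
over the analysis window and are computed through the same code path, so
the identity `topography == mean(curve)` holds exactly.

## ERSP

Per trial, 0.8 s Hann-tapered segments on the same sliding grid are
Fourier transformed; amplitude spectra are divided by the trial-set mean
baseline amplitude spectrum, *averaged across trials, and then* converted
to dB (20·log10; a power-spectrum mode with 10·log10 sits behind
`ersp_mode="power"`). The order matters: averaging log-ratios of Rayleigh-
distributed window amplitudes is biased by about −1.5 dB regardless of
trial count, whereas the mean normalized amplitude converges to 1 for
stationary input (0 dB) and to the true gain otherwise — halving the
amplitude gives the −6.02 dB plateau exactly in expectation. The taper is
configurable; Hann is the default for leakage control. The DC and Nyquist
bins have folded-normal rather than Rayleigh statistics and therefore the
largest sampling error of the map.

## PLI networks

Instantaneous phases come from the analytic signal of the 8–26 Hz
band-passed epoch. `PLI_ij` is the absolute time-average of
`sign(sin(φ_i − φ_j))` within the analysis window, computed per trial and
averaged across trials — per-trial computation avoids spurious coupling
from inter-trial discontinuities, and a zero phase difference contributes
0, which is what makes the index blind to zero-lag (volume-conduction)
coupling. When no embodiment window is set, the epoch interior is used
with 0.25 s trimmed at each end for filter/Hilbert transients.

Thresholding keeps the `round(s · n(n−1)/2)` strongest edges (round half
away from zero; ties broken by lexicographic node-pair order, making edge
sets nested across the sparsity grid 0.10:0.02:0.20). Retained weights are
unchanged. wCC is Onnela's geometric-mean triangle intensity with weights
normalized by the maximum retained weight (keeps wCC in [0, 1] at every
sparsity); nodes with degree < 2 contribute 0 and all nodes enter the
network mean — the Brain-Connectivity-Toolbox convention. wsPL uses edge
lengths 1/w and Dijkstra; disconnected pairs are excluded and flagged in
the result. On a graph whose retained weights are all equal, both metrics
reduce to their unweighted definitions. The metric formulas are isolated
behind `weighted_clustering` / `weighted_shortest_path_length` so
alternative definitions can be swapped without touching the sweep.
Whether networks should be built per trial or per condition is not fixed
by the paradigm; the pipeline builds one network per subject and condition
from the condition's trials (per-trial phase, trial-averaged PLI).

## Behavior and questionnaire

LT is pedal time minus go time, missing when there is no pedal; missing
values never enter aggregation, and condition summaries average subject
means first (matching the subject-as-random-factor design; trial pooling
is available). EQ ratings are integers on −5..+5, eight statements in four
subscales; scoring reports median and IQR per condition and statement, and
`eq_matrix` provides the paired subject × condition structure for the
nonparametric tests. Files use "NA" as the missing sentinel because the
no-pedal case is a first-class outcome.

## Statistics

The one-way repeated-measures ANOVA uses the within-subject decomposition
(subject, condition, residual sums of squares); with condition fixed and
subject random the condition test is `F = MS_cond / MS_resid` on
(k−1, (n−1)(k−1)) degrees of freedom. No sphericity correction is applied
by default (k = 3 and the balanced synthetic designs keep departures
small); the machinery is vectorized so the same decomposition powers the
pointwise maps. Identical conditions return F = 0, p = 1 (guarded against
floating-point ghosts of zero effects). Post-hocs are paired t tests with
Bonferroni over the three condition pairs.

Pointwise maps apply the ANOVA and post-hocs independently at each time
bin and report per-bin p values, uncorrected across bins — the
conventional way such maps are displayed; contiguous significant spans are
summarized by `significant_spans`.

The Friedman statistic uses mid-ranks with the standard tie correction.
For k = 3 conditions, no within-row ties, and n ≤ 25 subjects the p value
comes from the exact permutation null (built by dynamic programming over
per-subject rank permutations) with the mid-p convention
`P(S > s) + P(S = s)/2`. The exact-mid-p choice is deliberate: at n = 12
the χ² approximation has a realized size of ≈0.062 at α = 0.05 and the
plain exact test ≈0.041 because the statistic is discrete, while mid-p
lands at ≈0.055 — the calibrated choice for the study's sample size. Tied
(Likert) data and larger designs use the χ² approximation with k−1
degrees of freedom, which is also what the questionnaire pipeline path
exercises.

Wilcoxon signed-rank post-hocs drop zero differences, use the exact null
for n ≤ 25 without tied magnitudes and the normal approximation with
continuity correction otherwise, and are Bonferroni-adjusted over the
three pairs (`p_adj = min(1, 3p)`).

## Synthetic-data generator

Each channel is the sum of: pink (1/f) noise at 4 µV RMS, optional white
sensor noise at 1 µV, one band-limited Gaussian carrier per band (filtered
white noise normalized to unit variance; 10 µV alpha, 5 µV beta), and any
configured coupled components. Attenuation multiplies a carrier by
`a ∈ (0, 1]` from the trial's pedal sample to task end, so the band-power
ratio task/baseline is a² in expectation and the ground-truth ERD is
`(a²−1)·100`% — the oracle for parameter-recovery tests. Filtered-noise
carriers are non-phase-locked, which is the signal class baseline-relative
ERD/ERSP methods assume. Coupling adds a shared narrowband source to one
channel and its Hilbert-phase-shifted copy (fixed lag) to the other.

Defaults are the study conditions: 12 subjects (2 left-handed, simulated
as montage mirrors), 6 runs × 30 trials (10 per condition, shuffled per
run), 250 Hz, 32 channels; latency models N(4.4, 2.0²), N(3.7, 2.0²),
N(3.6, 2.1²) s truncated to (0, 10] by resampling, with no-pedal
probabilities 10.1/60, 7/60, 7.1/60 for NV/CV/IV; alpha attenuation ≈−30%
power at C3/F3 without vibration and ≈−40% with, ≈−40% at C4 under all
conditions, beta ≈−22..−25%, and weaker parieto-occipital alpha ERD under
intermittent vibration; EQ means ordered IV ≳ CV > NV on location,
ownership and first-agency statements with SD 1.5 on the integer grid and
a subject intercept of SD 1. Artifact injection adds, per selected trial,
either a 60 µV/s linear drift or a 300 µV spike on one channel — both
beyond the rejection thresholds by construction.

What the generator does **not** emulate: volume conduction and a forward
head model (channels are independent except for explicit coupling), eye
blinks and muscle topographies, 1/f non-stationarities, amplitude dynamics
of real mu rhythm beyond Gaussian envelopes, or any relationship between
questionnaire answers and the EEG. Passing tests therefore demonstrate
that the estimators recover what they claim from signals of the assumed
class — not that real recordings satisfy those assumptions.

## Validation studies and problem sizes

`mvfeeg.studies` packages the validation experiments used by the test
suite and `scripts/acceptance.py`:

- *ERD recovery*: 4000 direct band-noise trials per attenuation
  (1.0, 0.774, 0.5). The binding noise source is the 0.8 s baseline (~8
  effective samples per trial), giving a sampling SD of roughly
  `sqrt(0.3/N)·100·a²` percent — about ±0.9 points at N = 4000.
- *ERSP identities*: 4000 white-noise trials; the per-bin dB SD of the map
  is ≈ 8.7·0.52/√N (Rayleigh bins), ~0.07 dB, with the DC/Nyquist bins
  ~1.4× larger.
- *PLI*: pure 10 Hz tones with a π/4 or zero lag (exact 1 and 0), and 200
  independent 8–26 Hz noise trials of 4 s, where the expected per-trial
  PLI magnitude is ≈ `sqrt(2/(π·2BT))` ≈ 0.07.
- *Graph oracles*: 100 random 8-node graphs against exhaustive
  triangle enumeration and Floyd–Warshall relaxation, plus complete-graph
  closed forms and the 32-node edge-count identity (50 edges at sparsity
  0.1).
- *Null calibration*: 1000 simulations of 12 × 3 standard-normal blocks;
  the ANOVA F test is exact under these assumptions, and the Friedman
  mid-p variant is calibrated as described above.
- *Pattern recovery*: 100 replicate experiments at a reduced problem size
  chosen to keep the study tractable on one CPU — the 10 channels of the
  C3/C4 Laplacian neighborhoods, 125 Hz sampling (the alpha band only,
  with the sliding step at one sample = 8 ms), the full 6 × 30 trial
  design, and alpha attenuation planted over each regional neighborhood
  (−30% NV vs −40% CV/IV around C3; −40% everywhere around C4) so the
  Laplacian output carries the planted depth. A replicate succeeds when
  the Bonferroni-adjusted contrasts reproduce the planted structure
  exactly: CV/IV vs NV significant at C3-alpha and in LT, and no
  significant CV-vs-IV or C4 contrasts. The measured success rate is
  ≈0.9–1.0; the residual failures are almost entirely the ~1.7% per-null-
  contrast false-positive rate compounded over four null contrasts.

## Known limitations

- Channel-space only: no source localization, leakage correction, or
  volume-conduction model; PLI mitigates but does not remove common-source
  effects.
- The EDF writer is not implemented; recordings interchange as `.npz` with
  a JSON montage sidecar, and EDF files can be *read* via MNE.
- The full-scale default simulation (12 subjects × 6 runs × 30 trials × 32
  channels at 250 Hz) holds all recordings in memory — roughly 3 GB; use
  reduced montages or fewer runs on small machines.
- The pipeline's ERSP stage reports condition means at the analysis
  channels only, decimated in time for the output tables.
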