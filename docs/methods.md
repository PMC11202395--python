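# Methods

This note documents the models, conventions and parameter choices behind
the package, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic-data studies do and do not show.

## MEA signal chain

**Filtering.** Spike extraction uses a second-order high-pass Bessel filter
with cut-off 200 Hz. Bessel designs come in two dialects ("natural" phase
normalization vs magnitude normalization); this package uses the
magnitude-normalized dialect, placing the analog prototype's −3 dB point
exactly at the cut-off before bilinear discretization with frequency
prewarping. The realized response at 25 kHz sampling is −3.01 dB at 200 Hz,
below −60 dB at DC, and within 0.03 dB of unity at 2 kHz. Filtering is
causal single-pass by default, matching online acquisition; zero-phase
forward–backward filtering is available by flag with the caveat that it
doubles the effective order.

**Noise estimate.** The detection threshold needs the noise standard
deviation of the filtered trace, uncontaminated by the spikes themselves.
The default estimator is the robust median-absolute-deviation form standard
in extracellular work, σ = median(|x|)/0.6745, which a spike occupancy of a
few percent of samples barely moves (≤ 10 % inflation at 5 Hz of −50 µV
spikes on σ = 5 µV noise, verified by simulation). An iterative 3 σ-clipped
SD estimator is provided for comparison. A constant channel has no defined
noise level and is rejected.

**Spike detection.** A spike is registered when the filtered trace crosses
below −k σ with k = 4.5; the timestamp is the local minimum within the dead
time following the crossing, and no two spikes may be closer than the dead
time. The dead time defaults to 2 ms — short enough that the burst
criterion's densest admissible ISIs (≥ 5 ms in the simulated trains) are
never suppressed by detection refractoriness. Trough timestamps (rather
than crossing times) make detected times align with the simulator's
ground-truth convention to within one sample.

## Burst detection

The max-interval algorithm with the parameter set: open at an ISI ≤ 20 ms,
continue while ISIs ≤ 10 ms, merge candidates separated by gaps < 10 ms,
then discard candidates with < 4 spikes or duration < 20 ms. Three
conventions are fixed and tested:

- all ISI comparisons are inclusive (an ISI of exactly 20 ms opens, exactly
  10 ms continues);
- burst start/end are the first/last spike times, duration = last − first;
- merging runs before the count/duration filters.

Note this parameter set inverts the usual max-interval ordering (start ISI
20 ms > end ISI 10 ms, where typically end ≥ start); the numbers are
implemented as given and both are exposed as parameters. With these
defaults the merge step is provably vacuous — any inter-candidate gap is an
ISI that exceeded the 10 ms continuation limit, hence is never < 10 ms —
which is unit-tested, along with a non-default case (min IBI 15 ms) where
merging does fire. The implementation is checked for exact agreement with
an independent brute-force enumeration on 1000 random trains whose ISIs are
drawn across all rule boundaries, including exact boundary hits.

Burst features are fixed to duration, spike count, and intra-burst rate.
Burst rate is computed per second internally and reported per minute.

**Network qualification.** A culture is considered mature when at least 10
electrodes are active. "Active" requires at least one burst in the window
and temporal overlap of at least 50 % of the electrode's bursts with bursts
on other electrodes; both the minimum count and the synchrony threshold are
configuration, since synchrony admits no single canonical definition.

## Fold-change time-courses and their statistics

Per electrode, spike and burst rates over each 5-minute window are divided
by the electrode's own baseline-window rates. Baseline folds are therefore
identically 1; electrodes with a zero baseline rate have undefined folds
and are excluded from fold aggregation (flagged, not imputed). An all-zero
baseline across electrodes is an error.

Arms are compared on the fold scale with a two-way repeated-measures
design. Because each electrode belongs to exactly one arm, the model is a
mixed ANOVA: time is the within-subject factor, treatment the
between-subject factor, electrode the subject. Sphericity is tested and the
Greenhouse–Geisser-corrected p-value is used for within-involved effects
when it is rejected. Post-hoc, each arm is contrasted against the control
arm at every timepoint with Dunnett's many-to-one procedure (multivariate-t
adjusted). At a degenerate timepoint where all folds are equal across arms
(baseline by construction), the contrast is reported as p = 1 rather than
NaN. Electrodes with an incomplete timepoint series are excluded listwise.
Batch is acknowledged as an unmodeled factor: electrodes are the
repeated-measures subjects, and no random batch effect is fitted.

Dunnett's adjusted p-values come from randomized multivariate-t
integration; the integration seed is pinned so that identical inputs give
byte-identical outputs.

## The statistics ladder

Group comparisons follow the gate: Shapiro–Wilk per group at α = 0.05
(groups with < 3 observations force the nonparametric route with a
warning); if all groups pass — t-test for two groups, otherwise one-way
ANOVA with Dunnett / Tukey / Holm–Šídák post-hocs; if any group fails —
Mann–Whitney U for two groups, otherwise Kruskal–Wallis followed by Dunn's
test. Dunn's test is implemented directly (mean-rank z statistics with the
tie correction Σ(t³−t)/(12(N−1)), Bonferroni-adjusted, many-to-one or
all-pairs). For Dunnett and Tukey, the reported unadjusted p-value is the
pooled-variance contrast p (the same statistic without multiplicity), so
that adjusted ≥ unadjusted holds exactly. Significance labels use strict
thresholds: ***p < 0.001, **p < 0.01, *p < 0.05, otherwise n.s. — p = 0.05
is not significant.

Every route is calibrated by Monte Carlo under its own null (i.i.d. normal
observations): omnibus routes on the p-value, post-hoc routes on the
family-wise error (any adjusted comparison significant), and the mixed
RM-ANOVA on the treatment effect. All routes sit in [0.040, 0.051] at
nominal 0.05 in the shipped runs.

## Imaging

Otsu thresholding always uses a 256-bin histogram with intensities rescaled
to [0, 255], regardless of input bit depth, so 8- and 16-bit images are
thresholded identically; the threshold maximizes the between-class variance
w0·w1·(µ0−µ1)², ties going to the lowest bin, and is verified bin-for-bin
against exhaustive search. SNR has no canonical definition for this kind of
data; the package uses the contrast-to-noise form
(in-mask mean − background mean) / background SD with the background being
the mask complement, which is computable from the image pair alone and is
invariant under a global intensity offset. Statistics are computed per
image and intended to be averaged per well; per-cell statistics are out of
scope. Nucleus counting binarizes the nuclei channel with Otsu and counts
connected components of at least 20 px (at the simulator's default scale;
configurable).

## qPCR

Technical replicates are aggregated per (sample, gene) by arithmetic mean
after dropping replicates more than 0.5 cycles from their set's median (a
common QC heuristic; both the rule and the cut-off are configurable, and
sets left with fewer than two valid replicates are marked missing rather
than imputed). Averaging happens before ΔCT; the order only matters under
outlier removal. ΔΔCT is referenced to the arithmetic mean ΔCT of the
control group, which makes the geometric mean of control-sample folds
exactly 1 — consistent with figures that normalize controls to 1.
Amplification efficiency is fixed at 2 (the 2^(−ΔΔCT) model);
efficiency-corrected models are out of scope. Undetermined Cts are missing,
never imputed.

## The synthetic-data generator

The simulator exists to give every downstream stage inputs with known
truth; it is deliberately not a biophysical model.

**Spike trains** are a two-state renewal process per electrode: tonic
Poisson firing at `base_rate` plus burst events arriving as a Poisson
process at `burst_rate`, each emitting a fixed number of spikes at a fixed
intra-burst ISI. Treatment acts as a single multiplicative factor on both
rates per timepoint; waveforms do not change with treatment. Defaults —
2 Hz tonic, 10 bursts/min of 6 spikes at 5 ms, 60 electrodes, 25 kHz,
5-minute windows — are plausible for mature (DIV 15–30) cortical cultures
on 60-electrode arrays; no published per-culture firing statistics are
asserted, and everything is configurable.

**Voltage traces** embed each spike as a biphasic double-exponential
template (sharp ~0.3 ms negative lobe, slower positive rebound, 2 ms total
support) scaled so the negative peak equals `spike_amplitude` (60 µV
default) with the trough landing on the spike's sample, in additive white
Gaussian noise (σ = 5 µV default). Spikes closer than the template support
superpose additively. Real recordings differ in ways the simulator ignores:
colored noise, electrode drift, stimulus artifacts, unit waveform
diversity, and any treatment effect on spike shape. Passing recovery tests
therefore validates the analysis chain's correctness, not detector
performance on real noise.

**Images** are non-overlapping discs (rejection-sampled within a retry
budget) with a bright mask channel, a group-dependent Gaussian target
intensity inside cells, and one small nucleus disc per cell, plus Gaussian
noise. Real micrographs add illumination gradients, touching cells and
out-of-focus light, none of which are modeled — which is why cell
segmentation and morphology are out of scope.

**Ct tables** place the housekeeping gene at a fixed Ct and targets at
housekeeping + control ΔCT − log₂(fold), with independent N(0, sd²)
replicate noise; at sd = 0 the ΔΔCT analysis recovers configured folds
exactly, giving a closed-form end-to-end check. **Viability counts** are
binomial draws.

All generators are deterministic given (config, seed); per-channel streams
are derived from (seed, timepoint index, electrode index) so that channels
can be generated independently and the full 60 × 25 kHz × 5 min recording
never has to exist in memory.

## Problem sizes in the shipped validation runs

The validation studies are sized to run comfortably on one CPU: detection
quality on 4 electrodes × 300 s at 25 kHz; fold recovery at folds {1, 2, 3}
through the full waveform path on 10 electrodes × 300 s at 12.5 kHz; the
repeated-measures power study as 200 independent experiments (4 arms × 10
electrodes × 5 timepoints) at spike-train level — exact for the rate, fold
and statistics stages, since ground-truth trains are the very trains the
waveform path embeds; determinism on a full 4-arm waveform experiment at 10
electrodes × 30 s × 12.5 kHz run twice. Monte Carlo calibration uses 10 000
null replicates per route, except Tukey (2 500) and the mixed RM-ANOVA
(1 500), whose per-replicate cost is two orders of magnitude higher; the
binomial standard error at those sizes (≈ 0.005) is still small against the
calibration band.

## Known limitations

- The noise-segment question (whether acquisition software thresholds from
  a dedicated noise epoch or a running estimate) is left open; the
  estimator is a parameter, and no equivalence with any vendor tool is
  claimed.
- No spike sorting: threshold crossings on one electrode are treated as one
  train.
- Network bursts (array-wide events) are not a first-class object; the
  synchrony index in qualification is the only cross-electrode measure.
- The mixed ANOVA treats electrodes as independent subjects; electrodes
  within one culture are not truly independent, and batch is unmodeled.
- Image analysis assumes a usable two-class intensity histogram; Otsu on a
  nearly empty or saturated field will produce a mask, and the mask-fraction
  and SNR diagnostics should be inspected before trusting the statistics.
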