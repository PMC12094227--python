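# Methods

This note documents the models, statistics, parameter choices, and known
limitations of `omispike`. Units of time are seconds unless stated.

## Task model and synthetic data

The generator emulates a visual change-detection stimulus stream: images
drawn from a set of 8 are shown for 250 ms on a fixed cycle; a trial repeats
one image for a number of presentations drawn from a truncated geometric
distribution on [5, 11]; interior presentations are independently omitted
with probability 0.05, and the first/last presentation of a trial is never
omitted, which guarantees that every omission is flanked by identical
images. Two quantities the task family does not pin down numerically are
set here as package defaults, both configurable:

- `cycle_period_s = 0.75` (250-ms image + 500-ms gray). The omission-aligned
  windows used throughout (±1 cycle) span the flanking images at this
  cadence.
- `geometric_p = 0.3` for the truncated-geometric trial-length law.

Spike trains are inhomogeneous-Poisson realizations of archetype rate
templates composed with the schedule (time resolution 1 ms; spikes placed
uniformly within their bin). The archetypes follow the functional classes
observed in visual cortex — transient-onset, sustained, ramp-to-offset
(STIM-ON; with log-normal per-image tuning gains, SD 0.35 by default),
step-OFF/ON and ramp-OFF (STIM-OFF; untuned), plus a "hippocampal" step
responder whose rate changes only at the expected onset of an *omitted*
image and holds until the next presentation, and an unmodulated control.
Two deliberate modelling choices:

- the ramp-OFF template's inter-stimulus ramp continues linearly and
  without interruption through an omitted presentation (the visual-cortex
  signature the fitting stage must distinguish from a step);
- the sustained template decays exponentially (τ = 200 ms) after image
  offset, so its omission window sits *below* the immediately preceding
  baseline window. This reproduces the "spurious" negative omission
  modulation of stimulus-driven cells; a perfectly flat inter-stimulus rate
  would make that modulation undetectable by construction.

Behavior traces (60-Hz sampling) are AR(1) noise around a base running
speed, plus an alpha-shaped slowdown per omission whose onset lags the
omitted-slot onset by 0.5 s and whose minimum falls at 0.9 s — after the
post-omission image onset. The pupil trace constricts with the same kernel
and is median-normalized to 1.

What the generator does **not** emulate: refractoriness and bursting,
non-Poisson count variability, adaptation across repeats, representational
drift, LFP, eye movements, licking. Passing tests therefore demonstrate
correctness of the analysis machinery under the stated statistical
structure, not robustness to every property of real recordings.

## Omission statistics

PSTHs count spikes around events into 10-ms bins and divide by bin width
and event count. z-scoring uses the unit's own mean/SD over the full
displayed window (the normalization segment is not prescribed by the
analysis definition; using the displayed window keeps the statistic
self-contained). Significance of the omission-window rate change uses a
two-sample Wilcoxon rank-sum over per-event rates (omission window vs. the
immediately preceding equal-length window). Spike counts in 250-ms windows
are heavily tied, so the implementation uses the tie-corrected asymptotic
Mann-Whitney form; without tie correction the test is conservative and its
type-I rate falls visibly below α.

The ramping index `RI = log2(R_late − R_early)` is computed on z-scored
rates (the displayed quantities are z-scored; the formula is not
scale-invariant, and raw-Hz input is available via the same function). It
is undefined (NaN, flagged) when the late response does not exceed the
early one.

"Tuned to one image" is operationalized as a one-vs-rest one-sided
rank-sum win for exactly one of the 8 images with Bonferroni correction.
The specificity test then compares omission-window rates between
preferred-image and other omissions (two-sided, tie-corrected).

## Ramp vs. step fitting

Population responses are the mean z-scored PSTH of significantly
up-modulated units, ±250 ms around the expected onset. The sigmoid
`y = Δ + A/(1 + e^{−σ(x−c)})` is fitted by variable projection: for fixed
(σ, c) the model is linear in (Δ, A), solved in closed form; the outer 2-D
problem over (log₁₀σ, c) runs Nelder-Mead from a 3×3 start grid
(σ ∈ {5, 50, 500} s⁻¹ × c at the window quartiles), best-of-restarts by
training SSE with ties broken toward the smaller σ. σ is capped at
5000 s⁻¹ (a step sharper than one 10-ms bin is unidentifiable). Decreasing
traces are fitted on their negation. Cross-validated R² uses eight
contiguous blocks (random folds would leak the smooth trend), SST taken
against the training-fold mean; fold fits are warm-started from the
full-data solution. An area is *sigmoidal* when the one-sided rank-sum of
per-session sigmoid vs. linear R² is significant at α = 0.05 **and** the
sigmoid median is higher.

Slope modes: pooled fitted σ values are examined on a log₁₀ scale (σ is
positive and spans decades — linear-scale KDE bandwidths wide enough for
the step mode flatten the ramping mode entirely) with a Gaussian KDE,
Silverman bandwidth. The up-to-three largest local maxima define the
modes; KDE minima between them are the boundaries; areas are labeled
linear-ramp / intermediate / step-like by the interval containing their
median σ. A unimodal pooled distribution is flagged and all areas share
one mode.

## Cluster-number selection

Clustering operates on the rows of the unit×unit Pearson correlation
matrix of omission-aligned z-scored responses. W_k is the pooled
within-cluster dispersion (equal to the k-means inertia); the gap statistic
compares log W_k to its Monte-Carlo expectation under a reference
distribution (B = 50 draws by default; B = 20 in the recovery harnesses).
Two choices here departed from the textbook-simplest options after they
demonstrably failed on planted data:

- **Reference distribution**: uniform over the *PCA-aligned* bounding box
  of the data (Tibshirani's method b) rather than the raw feature box.
  Correlation-matrix rows are strongly anisotropic; with the raw box the
  reference dispersion declines so slowly that Gap(k) increases
  monotonically past the true k and neither the argmax nor the one-SE rule
  ever selects it.
- **Elbow**: argmax of the second discrete difference of **log** W_k. On
  raw W_k the first split always produces the largest absolute curvature
  and the elbow degenerates to k = 2; the log scale measures relative
  slope change, which is flat past the true k.

k_gap uses the one-SE rule (first k with Gap(k) ≥ Gap(k+1) − SE(k+1));
the global argmax is available via `gap_rule="max"`. The per-session
optimum is the half-up-rounded mean of k_elbow and k_gap; the final k is
the mode across sessions. Cluster semantic labels come from a one-to-one
Hungarian match between cluster mean response profiles and the archetype
template traces.

## Coupling, connectivity, cross-area models

*Population coupling*: 10-ms bins; the leave-one-out summed rate is
mean-centered and smoothed with a Gaussian of 6-ms half-width (HWHM; the
printed prescription "half width 12/2 ms" is read as 12/2 = 6 ms and the
width is configurable); the coupling index is the Pearson correlation with
the unit's own binned rate; the stPR averages the smoothed population rate
over ±0.4-s lags around the unit's spikes. Behavior scores interpolate the
behavior variable linearly onto 250-ms rate-bin centers and take |Pearson r|.

*Monosynaptic inference*: CCGs in 0.4-ms bins. Surrogates interval-jitter
the postsynaptic train within 5-ms windows (destroys monosynaptic-timescale
structure, preserves slow comodulation and per-interval counts exactly).
Excitatory connections require the observed count to exceed the
(1 − α)-quantile of the surrogate **maximum** over the +0.8 to +2.8-ms lag
window (maximum-statistic correction across bins; pointwise bands alone
inflate false positives); inhibitory connections mirror this with the
minimum over +0.8 to +4 ms. α defaults to 0.01 per directed pair;
strength is excess (deficit) pairs per presynaptic spike. The jitter
interval, lag windows, and α are free parameters of the method and are
exposed in `JitterConfig`. Count discreteness makes the band test slightly
conservative (empirical false-positive rates at or below α).

*Cross-area interaction*: spike counts in 50-ms bins over the 250-ms
window, PSTH-subtracted and unit-z-scored; ridge coefficients from the
closed form with λ selected on an inner CV within each of 10 outer folds
over a log grid 10⁻²…10³; predictive R² is 1 − SSE/SST pooled over target
units on held-out trials. Trial counts are matched across conditions by
seeded random subsampling of the larger set. CCA whitens with Cholesky
factors of the covariance blocks, adding a small diagonal loading
(10⁻³ of the mean variance) when T ≤ n_X + n_Y; canonical correlations are
the sample Pearson correlations of the paired projections.

*Decoding*: per-50-ms-bin one-vs-one linear SVMs (C = 1), stratified
10-fold CV, min-max normalization fitted on training folds with test
features clipped to [−0.5, 1.5]; folds shrink with a warning when the
smallest class has fewer examples than folds.

## Validation experiment sizes

The experiments in `omispike.experiments` (shared by the test suite and
`scripts/acceptance.py`) run at sizes chosen to make their statistical
assertions meaningful on a single CPU: a ~50,000-eligible-slot schedule for
design-parameter fidelity; a 400-trial tuned session (~95 omissions) for
decoder chance calibration — the permutation null averages five label
permutations (a single permutation retains chance class-enrichment that
informative features exploit) and the per-bin band is a simultaneous 99%
binomial CI, Bonferroni-corrected over bins; 100 replicates of 500-point sigmoid recovery
(Δ=0, A=1, σ=40 s⁻¹, c=0, noise SD 0.05); 100 meta-replicates of 20
step-like and 20 ramping sessions for area classification (sessions are
archetype traces plus Gaussian noise — the fitting stage consumes
population responses, so spiking simulation adds nothing at this level);
50 seeds of 5×24-unit planted feature populations for k-selection; one
full 150-unit spiking session for cluster-label recovery; 40 planted
synapses (~3000 presynaptic spikes) and 1000 independent pairs for
connectivity; 100 sessions per latent scenario for interaction sign; 1000
null units and 500 tuned units for type-I calibration.

## Known limitations

- The Poisson generator cannot probe robustness to refractoriness or
  bursty count statistics; the Fano factor is 1 by construction.
- Semantic cluster labels presuppose the five visual archetypes; novel
  response classes would be force-matched to the nearest template.
- The gap statistic is computed with B ≤ 50 reference draws; its SE is a
  Monte-Carlo estimate and very small B can destabilize the one-SE rule.
- Ridge interaction R² can be negative for weakly coupled areas (held-out
  definition); the interaction *difference* is the meaningful quantity.
- The specificity test conditions on the tuning call made on the same
  session's presented stimuli; tuning and omission tests are computed on
  disjoint event sets (presentations vs. omissions), so this does not bias
  the null, but very weakly tuned units are excluded rather than tested.
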