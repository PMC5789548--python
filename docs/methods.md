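# Methods

`eegrs` implements an analysis chain for auditory repetition suppression (RS)
in epoched EEG — normalized non-phase-locked signal energy, data-driven
spatial ROIs, a mixed-model repetition ladder, and single-trial decoding of
cognitive subgroups — together with a synthetic cohort generator that supplies
data with the statistical structure the chain assumes.  This note records the
models, the defaults and why they hold their values, and what the synthetic
data does and does not establish.

## The energy statistic

Signal energy of an epoch is `E = Σ |amp|²` over the 0–800 ms window (200
samples at 250 Hz by default).  Two transforms precede it, per participant
and channel:

1. **Evoked subtraction.** Each pseudoword is presented 10 times, and 18
   pseudowords share each presentation position p, so the mean waveform over
   stimuli at fixed p estimates the phase-locked (evoked) response at that
   position.  Subtracting it cancels the evoked part exactly (it is
   phase-locked, hence survives averaging) while induced activity with
   per-epoch random phase retains a fraction 1 − 1/18 ≈ 94% of its energy in
   expectation.  The remaining statistic is therefore *non-phase-locked*
   energy.  Mode `none` is available for sensitivity checks; whether the
   original analysis subtracted before or after normalization is not
   documented, and the package default (subtract first) is one documented
   choice.

2. **Repetition-series normalization.** For each (participant, channel,
   pseudoword), every sample of the 10-presentation series is divided by the
   pooled sample SD (ddof = 1) of the whole series.  Two consequences anchor
   several tests: (i) energies are scale-free (multiplying raw voltages by
   any c > 0 changes nothing), and (ii) for a mean-zero complete series the
   ten energies sum to exactly `10·T − 1`, so per-presentation mean energy
   sits near `T` — the scale regime of the study's summary tables (values
   ~186–224 at T = 200).  A corollary worth keeping in mind: normalization
   *removes* overall amplitude differences between participants and channels;
   only the within-series distribution of power across the ten presentations
   carries information.  It also constrains each series' energies to a fixed
   sum, inducing an exchangeable negative correlation (≈ −1/9) across
   presentations that the mixed model must acknowledge (below).

Rejected epochs (peak |amp| strictly above 100 μV after filtering and average
re-referencing; zero-phase 4th-order Butterworth 1–50 Hz) are excluded from
the subtraction average, the normalization pool and the output table.
Epochs are short relative to the 1-Hz edge's impulse response, so the
forward–backward filter uses Gustafsson initial-condition matching after
per-epoch mean removal; with default odd-extension padding the edge
transients would contaminate a 200-sample epoch well past 25 samples.

## Spatial PCA and ROIs

Stimulus-averaged channel energies, one row per (participant, presentation),
enter a correlation-matrix PCA per participant group.  The smallest leading
factor set reaching 60% cumulative variance is retained and Varimax-rotated;
channels join the factor carrying their largest absolute rotated loading if
it reaches 0.40 (the conventional salience cutoff; configurable).  Each
factor becomes an ROI named from the scalp centroid of its channels.  The two
groups' ROIs are pooled into one set used for all participants; ROIs are
disjoint within a group's model but may overlap across groups, and identical
electrode sets derived by both groups collapse to a single region.

## Mixed-model ladder

The outcome is stimulus-averaged ROI energy, one row per (participant,
presentation, ROI).  The baseline model has categorical presentation (10
levels), ROI and their interaction as fixed effects, and a per-participant
random slope on the numeric presentation covariate with **no** random
intercept — the normalization's fixed per-series energy sum leaves virtually
no between-participant level variance, so an intercept has nothing to absorb.
Group, NVIQ and age are added sequentially with their interactions, each
judged by a chi-square LRT at α = 0.05 on maximum-likelihood fits; the
residual covariance (identity, compound symmetry, AR(1) across the ordered
presentations within each participant × ROI series) is then selected by AIC.

The fit maximizes the profiled Gaussian marginal likelihood directly: given
the variance-ratio parameters, β and σ² are closed-form, leaving a one- or
two-parameter Nelder-Mead search with fixed tolerances (xatol 1e-5, fatol
1e-7, ≤ 800 evaluations), so results are bit-reproducible.  The slope
variance ratio is parametrized as θ² so its zero boundary is an interior
point.  Two numerical notes: optima typically sit near the compound-symmetry
edge ρ → −1/9 (the sum constraint again); the likelihood is flat along the
boundary direction there, and a fit counts as converged when the final
simplex pins −2·logLik within 1e-3 (far below the χ² ≈ 3.84 scale of any
ladder decision).  Near-singular covariance candidates (Cholesky pivots
< 1e-5) are rejected with a penalty.

During the predictor steps the working covariance is compound symmetry, not
identity: ignoring the normalization-induced negative correlation inflates
LRT and F-test sizes.  With this choice the repetition F-test's type-I rate
on null cohorts is nominal (the acceptance suite checks it lands in
[0.02, 0.10]).  Wald F statistics use a residual (n − p) denominator df —
fractional small-sample df corrections are not attempted, and exact
replication of the original F/t/df values is out of scope.  Post hoc
contrasts compare estimated marginal means of all 45 presentation pairs
(covariates at sample means, factors averaged), Bonferroni-multiplied by 45,
and are refused when the repetition main effect is not significant.

One caveat for full-scale synthetic runs: pooled ROIs overlap across groups,
so ROI energies are cross-correlated in ways the block-diagonal residual
model does not represent; on the demonstration cohort this mildly inflates
late ladder steps (age can reach p ≈ 0.02).  The ladder's error-rate checks
therefore run on cohorts with planted disjoint ROIs, where the working
covariance is correct.

## Decoding and significance

Features are single-trial energy drops `E(P1) − E(Pj)` (j = 2..10) and
`E(P2) − E(Pj)` (j = 3..10): 17 per ROI, 119 for seven ROIs, one trial per
(participant, pseudoword) — 252 trials for 14 FXS participants.  With class
sizes (8, 6), all C(8,6) = 28 balanced subsets of the larger class are
enumerated (216 trials each); within a subset every cross-class participant
pair is a test fold (36 folds: train on 10 participants' 180 trials, test on
the pair's 36).  Per feature and fold, values are z-scored with training
statistics and classified by an RBF-kernel SVM (C = 1, sklearn's `scale`
bandwidth; both fixed — the original hyperparameters are unreported).
Subset DA is the mean fold accuracy; the reported DA is the mean over
subsets and the s.e.m. is taken across subsets.  Trials with a rejected
constituent presentation are dropped per feature; folds whose training set
degenerates to one class are skipped and counted.

Chance thresholds come from the exact binomial tail (log-space summation, no
normal approximation): the smallest k with `P(X ≥ k; n, 0.5) ≤ α_eff`, as
a percentage of n.  A bare "binomial test + Bonferroni over m features"
under-determines α_eff, so the sidedness/multiplicity convention is fixed by
an explicit calibration utility that searches the convention grid for the
one reproducing a stated threshold pair; for the reference setting (n = 216,
m = 119, thresholds 62.96 / 64.35%) the unique match is a two-sided tail
Bonferroni-corrected across 2m comparisons (equivalently one-sided at
α/(4m)), which is the package default.  Flags use strict exceedance.

## The synthetic cohort generator

No EEG from the study is deposited, so the generator supplies cohorts with
the structure the analyses assume: 26 controls, 8 low-NVIQ (≤ 42) and 6
high-NVIQ (> 42) FXS participants; 18 pseudowords × 10 presentations;
99 channels × 200 samples at 250 Hz.  Each epoch is

* a fixed damped-sine evoked template (5 Hz, 250 ms decay, 6 μV peak) with a
  smooth anterior–posterior scalp gradient, identical across presentations —
  the claims under test concern energy, not ERP morphology;
* induced 10-Hz oscillations from orthogonal spatial sources,
  amplitude-modulated by per-presentation gain profiles and carrying a fresh
  uniform phase per epoch and source, so they cancel in across-trial
  averages;
* white sensor noise (10 μV), and amplitude artifacts (150 μV pulses at rate
  0.02 per epoch, matching the study's ~2% rejection rate).

**Habituation profiles** encode the study's central finding: controls drop
from gain h = 1.3 to 1.0 after presentation 1, high-NVIQ FXS after
presentation 3, low-NVIQ FXS not at all.  NVIQ is uniform within subgroup
ranges (87–129, 32–42, 52–93), ages uniform on 9–32, and sex frequencies
follow the study tables.  A master seed spawns per-participant substreams,
so cohorts are bit-reproducible and partially regenerable.

**Spatial structure.** The montage is a deterministic synthetic dense array
(concentric rings, 99 channels) partitioned into seven contiguous regions.
Sources are center-surround (zero-sum) patterns on disjoint regions: zero-sum
is what average-referenced data supports, so re-referencing leaves the
planted sources untouched, and disjoint supports make them exactly
orthogonal.  The study reports its group factor structure (two FXS factors
at 62%, five control factors at 60%, seven pooled ROIs) but none of the
underlying physics, so the source parameters were calibrated once against
that printed structure:

* controls drive the five temporal/fronto-central/occipital sources
  independently, at amplitudes (3.9, 5.0, 5.0, 3.9, 3.1 μV at the core
  channels) placed where five factors cross the 60% retention target —
  exactly five, with cumulative variance 63–65% across seeds;
* FXS participants drive all seven regions, but their per-epoch amplitude
  envelopes are coherent within two large-scale clusters (anterior-central
  vs posterior-lateral, 48/51 channels), a generative reading of the
  increased spatial spreading of synchronized activity reported in this
  population; each cluster becomes one broad factor and neither alone
  reaches 60%;
* repetition gains are regional: controls habituate over the
  anterior/temporal sources (auditory RS is fronto-central/temporal, not
  occipital), FXS over the anterior-central cluster, where the study
  localizes the group's repetition effects;
* trial-to-trial induced-power variability is lognormal with cv 0.75 for
  controls and 1.2 for FXS (elevated neural response variability in FXS);
  between-participant source strength varies with cv 0.4, though the
  normalization deliberately cancels most of its effect.

**What the generator does not emulate:** volume-conducted continuous scalp
fields from a head model, ocular/muscle artifact morphology (artifacts are
plain amplitude excursions), evoked-latency or morphology variation, 1/f
background spectra, or any dependence of NVIQ on EEG beyond the planted
group profiles.  Passing tests therefore establish that the pipeline
recovers the statistical structure it targets — gain profiles, spatial
factors, subgroup separability, calibrated error rates — not that it would
behave identically on recorded EEG.

## Problem sizes in the test suite

Monte-Carlo checks keep the study's trial structure (18 × 10, default
profiles, 26/8/6 participants) but run on reduced sensor grids: two planted
disjoint block sources over 12 channels, 50-sample epochs, per-epoch
amplitude cv 0.3, no artifacts.  At these sizes a ladder fit takes ~2 s and
a full single-feature fold plan ~2.5 s, allowing 50-simulation power checks
and 100-simulation type-I calibrations inside a normal test run.  The
decoding power check plants an early-presentation gain difference of
h = 1.8 confined to one source — a strong planted effect, sized so the
matching feature's DA clears the 62.96% reference threshold decisively, in
the spirit of the oracle checks (the study-magnitude h = 1.3 produces DA in
the high 50s at this reduced scale).  The null family-wise decoding check
uses a (4, 3)-participant fold plan with its own exact-binomial threshold
(n = 108 trials, m = 34 features, same calibrated convention), since the
full 119 × 28 × 36 plan costs minutes per cohort.  Cohort-scale factor
recovery runs once per session at full scale (99 channels, T = 200) on a
fixed seed; the five-factor/60% datum is a knife-edge in the study itself,
and seed-to-seed cumulative variance varies by a few points.

## Known limitations

* Exact replication of the study's F/t/df values and real-data decoding
  accuracies is impossible without the recordings and is not attempted.
* Degrees of freedom are residual-based; SPSS-style fractional df are not.
* The ladder's working covariance is correct for disjoint ROIs; overlapping
  pooled ROIs on full-scale cohorts mildly inflate late LRT steps.
* The binomial-threshold convention is calibrated, not derived: the package
  reproduces the printed thresholds under a documented convention rather
  than asserting which software convention the original analysis used.
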