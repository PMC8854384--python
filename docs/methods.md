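# Methods

This note documents the models, estimators and design choices behind
`dynet`, and what the synthetic validation does and does not establish.

## Pipeline order and preprocessing

The pipeline operates on parcellated BOLD matrices (regions × time) and
runs, per subject, in a fixed order: scan-quality metrics on the raw
series, nuisance regression, band-pass filtering, then all dynamic
analyses on the filtered series.

* **Framewise displacement** uses the sum-of-absolute-derivatives
  convention: the six rigid-body parameter increments, with rotations
  converted to arc length at a 50 mm head radius. The first frame is 0
  by definition. Frames with FD > 0.25 mm are flagged.
* **DVARS** is the RMS frame-to-frame signal change expressed as a
  percentage of the grand-mean signal of the *unfiltered* series. The
  percent reference is a convention choice (the threshold "2.5%"
  requires one); it is configurable. Subjects with more than 10% of
  frames flagged by either metric are marked for exclusion (strict
  inequality).
* **Nuisance regression** is plain OLS of each region on an intercept
  plus a caller-supplied regressor matrix (the pipeline uses the six
  motion parameters, their first differences, FD and DVARS). Rank
  deficiency is tolerated with a warning: residuals are invariant to
  which collinear column is dropped. Voxel-space strategies (tissue
  masks, component regressors) are out of scope; the regressor-matrix
  interface accommodates their outputs.
* **Band-pass** is a 4th-order Butterworth (0.071–0.125 Hz by default)
  applied forward–backward (`sosfiltfilt`), so the filter is zero-phase
  and cannot shift connectivity timing. Filter type and order are not
  dictated by the measures themselves; zero-phase was chosen so window
  alignment survives filtering. Measured response at TR = 3 s: gain
  1.000 at 0.1 Hz, < 1e-8 at 0.01 Hz.

## Time-resolved connectivity (MTD)

Coupling between regions *i* and *j* at derivative sample *t* is
`dz_i(t) * dz_j(t)`, where `dz` is the first difference normalised by
its own population SD computed over the whole scan (not per window —
this keeps scores comparable across windows and makes the measure
invariant to positive rescaling of any region). Windowed scores are a
rectangular moving average over 15 consecutive derivative samples
(~45 s at TR = 3 s). Windowing is "valid": only fully interior windows
are produced (T timepoints → T − 15 windows), with centres reported in
original sample units. The diagonal is zeroed and excluded downstream.

## Temporal similarity

Both pattern definitions are first-class because the source literature
uses both descriptions interchangeably:

* `activity`: one pattern per TR, the regions-long BOLD vector
  (module-level default);
* `connectivity`: one pattern per MTD window, the vectorised upper
  triangle (study-level default — see below).

S_L is the arithmetic mean of the Pearson correlations between
contiguous epoch patterns. S_G sums |r| over all ordered pairs including
the diagonal, subtracts n, and divides by n(n−1); this equals the mean
absolute off-diagonal correlation and lies in [0, 1]. S_L keeps signed
correlations, S_G takes absolute values — the asymmetry is deliberate
and preserved.

Two consequences of these definitions worth knowing:

* with sliding windows, contiguous connectivity patterns share 14 of 15
  samples, so connectivity-mode S_L has a high overlap-driven baseline
  (~0.97 in the synthetic study); group differences ride on top of it;
* activity-mode S_L of conditionally independent samples is ~0, and
  shared linear filtering adds the same autocorrelation to every
  subject, so under this package's generator activity-mode S_L carries
  no group information. The study pipeline therefore defaults to
  connectivity mode; both remain available.

## Topology

Per window, modules are found by Louvain modularity maximisation
(igraph's multilevel algorithm) on the positive-weight graph — negative
MTD weights are excluded both from community detection and from the
strength sums below (configurable in principle; the positive-graph
convention is the package default). Ten seeded restarts per window, the
best-modularity partition kept; a fixed master seed fans out to
per-window substreams, so results are reproducible.

* Participation: B_i = 1 − Σ_s (κ_is/k_i)² over positive strengths;
  isolated regions score 0. Bounded by 1 − 1/M for M realised modules.
* Module-degree z: within-module positive strength standardised within
  the region's module; singleton and zero-spread modules score 0.
* Cartographic profile: joint histogram of (B, W) over all
  region-window pairs; 100 × 100 bins on [0,1] × [−5,5], values clipped
  into range so counts are exactly conserved; bin edges travel with the
  output so group comparisons share them.
* Segregated occupancy: k-means with k = 2 on the subject's pooled
  participation values (pooling across regions and windows gives
  "segregated" a single subject-level meaning); the lower-centroid
  cluster is segregated, and each region's occupancy is the fraction of
  its windows there.
* The Louvain resolution parameter defaults to 1.0. It is unreported in
  the motivating work and is an assumption here.

## Flexibility

Labels are arbitrary per window, so consecutive windows are aligned by
a maximum-overlap assignment (Hungarian algorithm on the negative
contingency table, padded square). A new module whose best match shares
no region gets a fresh label; matching renames labels and never moves a
region. A region's switch fraction is the fraction of window
transitions at which its matched label changes; flexibility divides by
the total number of distinct matched labels in the subject's data. The
alternative normalisation (per-window module count) is recoverable from
the returned switch fractions and counts. "Total distinct labels" was
the adopted reading of an ambiguous convention; published group means
alone cannot disambiguate it.

## Behaviour: the closed-form diffusion fit

The simulator integrates a single two-boundary diffusion
(Euler–Maruyama, dt = 1 ms, diffusion coefficient fixed at 0.1) from a
midpoint start; upper-boundary hits are correct responses, trials
exceeding `max_rt` are omissions. The fit inverts the simple
three-parameter model from exactly three moments (edge-corrected
accuracy, correct-trial mean RT and RT variance) via the standard
closed-form solution; `predict_moments` is its algebraic inverse and
round trips are exact to ~1e-16. The diffusion coefficient resolves the
model's scale indeterminacy: doubling it doubles fitted drift and
boundary and changes nothing observable. Accuracy values of exactly 0,
0.5 or 1 are nudged by 1/(2n) before fitting (the raw value is kept).
Recovery at 10,000 trials is within ~3% for all three parameters;
discretisation bias at dt = 1 ms is well inside the Monte-Carlo noise.

## Statistics

Group tests residualise subject values on an intercept plus covariates
(age, sex), then permute group labels and recompute the difference of
group means — a Freedman–Lane-style approximation, which is the key
inferential assumption; p-values carry the +1 correction and are never
zero. Cohen's d is computed on the residualised values with the pooled
(n−1-weighted) SD. BH-FDR is implemented directly (and checked against
a quadratic-time oracle in the tests); Mann-Whitney U delegates to
scipy (exact for combined n ≤ 12 without ties, tie-corrected normal
otherwise; U reported for the first group). Bin-wise cartographic
correlation maps mask zero-variance bins rather than failing, and run
BH over the valid bins only. Calibration measured by the acceptance
script: type-I error 0.038–0.062 at α = 0.05 (binomial band 0.031–0.069
at 500 replicates), BH global-null mean FDP ≈ 0.05–0.06 at q = 0.05.

## Gene mapping

Expression tables are regions × genes with alignment strictly by region
label (row order never matters). The screen is a per-gene Spearman
correlation against a per-region group-difference map with BH-FDR
across the gene family (default q = 0.1); constant genes are reported
as missing and excluded from the family size. The confirmatory test
compares a gene's expression between significant and non-significant
regions with a pooled-variance t test (Shapiro–Wilk normality check
with a warning), BH-corrected across the genes tested. Spatial
autocorrelation of expression maps is *not* corrected for — regional
observations are treated as exchangeable, matching common practice; a
region-permutation null would be the extension point. The default gene
list covers adrenergic, muscarinic/nicotinic cholinergic and
dopaminergic receptor genes.

## The synthetic cohort generator

The generator exists because the motivating clinical dataset is not
publicly deposited; it produces every input the pipeline consumes with
the statistical structure the analysis assumes, plus ground truth for
recovery tests.

**BOLD model.** Each subject is a hidden-Markov construction: discrete
connectivity states with geometric dwell times (memoryless switching —
the simplest process with a controllable mean; nothing in the source
material specifies a generative law), compound-symmetric module-block
covariance per state (unit variance; `within_coupling` on same-module
pairs, `between_coupling` otherwise, so integration level is a single
knob), white observation noise, and a constant baseline of 1000 (typical
scanner units) so percent-scale DVARS is defined. `between_coupling`
may be given per state, letting a preset alternate integration levels
under a stable partition. The population correlation of a within-module
pair is `within/(1 + noise_sd²)`, which the tests verify directly.
PSD of every implied covariance is checked at construction.

**Presets.** The control-like preset has four stable modules whose
between-module coupling alternates 0.2/0.4 with mean dwell 4 samples —
a temporally variable, relatively integrated brain. The patient-like
preset dwells five times longer (20 samples), couples weakly between
modules (0.1), and its two states differ in module membership for 3
regions per module ("movers") — a stationary, segregated architecture
with genuinely unstable assignments. Cohort covariates mirror the
motivating cohort's structure: patients older (74.5 ± 6.1 vs
66.4 ± 8.5 years) and predominantly male, so covariate adjustment has a
real confound to remove. Default study size is 20 subjects/group, 60
regions, 200 timepoints at TR = 3 s (the clinical protocol's ~140
volumes also works; 200 gives the window count a comfortable margin).

**Severity pathway.** Each subject carries a latent severity
u ~ N(0,1) that multiplies dwell time by exp(0.35·u), within-module
coupling by exp(0.04·u) (clipped to keep the covariance valid), and
drift rate by exp(−0.3·u). This is the common cause linking a subject's
network stationarity to their attentional performance: higher severity
means more rigid coherence (higher S_L), slower evidence accumulation
(lower drift) and more variable RTs. The within-coupling leg exists
because subject-level S_L is nearly insensitive to dwell at these
problem sizes; its slope was set to the value that keeps the group
contrasts clearly detectable while still producing positive
S_L–RT-variability and negative S_L–drift correlations. The realised
within-group correlations (~|ρ| 0.1–0.3 at n = 20) are weaker than the
corresponding clinical report — a sharper pathway would inflate
within-group variance and erode the group contrasts, a trade-off this
generator cannot avoid.

**Motion, behaviour, expression.** Motion traces are sums of slow
sinusoids whose frame-to-frame increments stay far below the FD
threshold; spikes are sustained steps of known size at known frames, so
FD flags exactly those frames. Reaction times come from the diffusion
simulator above. Expression matrices are Gaussian-smoothed random
fields over the region index (standardised); a planted gene blends
normal scores of the target map's ranks with independent smooth noise,
with the blend weight solved numerically so the realised Spearman
correlation lands on the requested value.

## What the synthetic validation does and does not show

Passing tests establish that every estimator computes its definition
correctly (oracle equivalences at 1e-12), that the inference machinery
is calibrated, and that the pipeline end-to-end recovers planted
structure in the directions the clinical findings describe — higher
S_L and S_G, lower participation, higher segregated occupancy in the
patient-like group, and a planted receptor-expression association.

They do not show that the pipeline would detect such differences in
real fMRI: the generator draws conditionally independent samples (no
hemodynamic autocorrelation within states), its covariance is
block-uniform, and the desk-scale problem (60 regions) is far smaller
than a full cortical parcellation.

One limitation is structural and worth stating plainly. At these
problem sizes, a 15-sample window of band-limited data retains roughly
five effective degrees of freedom, so per-window community estimates
are noise-dominated and the match-then-count switch rate is governed by
a churn floor that *rises* with between-module coupling. Any
configuration that makes one group more segregated therefore also makes
its partitions more reproducible and its measured flexibility *lower*;
planted genuine switching (state-dependent membership) is smoothed away
by the 14/15 window overlap and cannot compensate. The synthetic study
consequently reproduces four of the five group contrasts; the
flexibility contrast comes out flat-to-reversed, and the corresponding
acceptance check is left failing rather than redefining the measure or
the generator to force it. Detecting a genuine flexibility excess most
likely requires many more regions and realistic temporal structure than
this desk-scale generator provides.

## Problem sizes

Defaults used throughout the tests and the acceptance script: 20
subjects per group × 60 regions × 200 timepoints for the study (≈1 min
of analysis); 5,000 permutations for study-level tests; 500 null
replicates per calibration experiment and 1,000 for BH; 200 seeds for
planted-gene detection; 10,000 trials for diffusion recovery. These
sizes were chosen so the full validation runs comfortably on a laptop
while keeping Monte-Carlo error well inside every asserted tolerance.
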