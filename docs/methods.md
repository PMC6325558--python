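# Methods

## Pipeline overview

The package implements a region-of-interest decoding analysis for
event-related fMRI: per-subject, per-condition beta maps are reduced to
region-wise feature vectors, one linear Gram matrix is formed per
(region, condition) block, and an ε-insensitive support vector regression
over a simplex-weighted combination of those kernels predicts a
continuous behavioral score.  Inference is by nested leave-one-subject-out
cross-validation with label-permutation nulls and Benjamini–Hochberg FDR
across model families.  Interpretation is at the block level: the learned
simplex weights, averaged over folds, are the region/condition weight
tables.

## First-level GLM

Each condition's events are boxcars (onset, 4 s duration by default)
convolved with the canonical double-gamma HRF (peak delay 6 s, undershoot
delay 16 s, dispersions 1 s, peak:undershoot 6, 32 s support, unit peak).
Convolution runs on a 10 ms grid — event onsets are specified to 2
decimals, so they align exactly — and is read out at the volume times.
The design appends the confound table as given, a DCT high-pass basis
(every cosine with period above the 128 s cutoff, i.e.
⌊2·N·TR/cutoff⌋ columns) and an intercept.  Estimation is voxelwise OLS
inside the atlas mask.  No temporal autocorrelation model is applied;
with condition-level regressors and nested CV at the subject level, OLS
point estimates are all the decoder consumes, and any AR structure only
affects (unused) first-level standard errors.  Rank deficiency is an
error that names the collinear columns.

## Kernels

Features are gathered per region in ascending x-fastest voxel order, so
vectors are identical across subjects, conditions and file layouts.
Kernel centering uses the feature-space training mean through the
standard kernel-centering identity; held-out rows therefore depend on
held-out features only through inner products with training features,
and perturbing a held-out subject can never change the training block
(verified bit-exactly in tests).  Normalization divides each centered
kernel by its mean training-block diagonal ("trace" mode), making the
training-block trace equal the training-set size.  This equalizes
average pattern energy across regions of very different voxel counts,
which is the stated purpose of size normalization in kernel MVPA
toolboxes; the exact formula used by any particular toolbox is a dialect
choice, so a per-voxel-count alternative (`normalization="dim"`) is
exposed.  All-zero blocks (possible in degenerate synthetic data) are
left as zero kernels and simply attract zero MKL weight.

## Solver

The ε-SVR dual is solved by SMO in the 2n-variable box form with
maximal-violating-pair selection (first-order choice of the up-variable,
second-order largest-decrease choice of the partner), KKT-gap stopping,
and the offset taken from free support vectors (mid-gap fallback when
none are free).  With one kernel the fit reproduces an established SVR
implementation to 1e-5 on identical Gram matrices.

Kernel weights follow the SimpleMKL scheme: at fixed d the dual optimum
J(d) is computed exactly; its gradient ∂J/∂d_m = −½ βᵀK_mβ drives a
reduced-gradient direction on the probability simplex (reference = the
heaviest kernel, ties resolved toward the steepest gradient, then lowest
index — a value-based rule that keeps the search path equivariant under
kernel reordering); a backtracking line search from the largest feasible
step accepts only objective decrease, so the recorded objective trace is
non-increasing by construction.  Convergence is declared when the weight
change falls below `mkl_tol` (default 1e-4) or no improving step exists.
On small instances the final objective matches a 0.02-step exhaustive
simplex grid search to well under 1e-3 relative (it is typically *below*
the grid optimum, since the grid is discretized).

Numerical guards: pair curvatures are floored at 1e-12; `solve_svr_dual`
additionally eigen-clips kernels whose smallest eigenvalue is within
−1e-8·λ_max of zero (centering leaves harmless negative dust).  The
default SMO iteration cap is 5000 per solve: near-singular Gram matrices
(e.g. rank-one signal kernels in the noiseless limit) admit flat dual
directions along which SMO crawls at large C with objective gains below
any tolerance of interest; capping was verified to leave r and MSE
unchanged across null, noisy-signal and noiseless studies while removing
order-of-magnitude slowdowns.  Explicit `solve_svr_dual` calls default to
a much higher cap for oracle-grade solves.

## Cross-validation and inference

The outer loop holds out one subject; the inner loop is leave-one-out
over the remaining n−1 (matching the outer scheme at n≈20), selecting C
from the grid [0.1, 1, 10, 100, 1000] by minimal inner MSE with ties to
the smallest C.  Kernels are re-centered and re-normalized on every
training set, and labels are standardized to zero mean/unit variance
inside every training fold (predictions are de-standardized), which
makes the fixed tube width ε = 0.1 meaningful across questionnaires
whose ranges differ by an order of magnitude.  A training fold of one
subject (the n = 3 boundary case) has zero label variance; the standard
deviation is then taken as 1 so the run completes.

Metrics: Pearson r (sign preserved — negative r means poor decoding) and
nMSE = MSE / (max − min) of the whole sample's true labels; the divisor
is recorded and reused for permutation nulls.  Out-of-fold predictions
with exactly zero variance would make r undefined; pipeline summaries
score them 0 (no linear association) while the public `pearson_r` raises.

Permutation inference shuffles the label-to-subject assignment *before*
the outer split and reruns the entire nested CV, inner C selection
included, so the null distribution reflects the full pipeline.  p-values
use the add-one correction, p = (1 + #{null ≥ observed}) / (1 + n_perm)
for r and the ≤ direction for nMSE.  Over 200 null studies at 199
permutations the α = 0.05 rejection count sits inside the exact binomial
95% interval (tested).  The r-based and nMSE-based families are
FDR-corrected separately (Benjamini–Hochberg via statsmodels).

A caveat worth knowing: under the null, leave-one-subject-out
*predictions anti-correlate* with the labels — each held-out prediction
is pulled toward the training mean, which moves opposite to the held-out
value — so null r values center below zero (mean ≈ −0.3 at n = 20 in
simulation) rather than at zero.  Published applications of this design
show the same signature (strongly negative r for non-decodable scores).
Permutation p-values are unaffected because observed and null runs share
the bias; raw negative r must simply never be interpreted as
"significantly bad" decoding.

## Weight aggregation and reporting

Fold weights d are averaged and scaled to percent, so the table sums to
100 and condition weights are within-condition sums by construction.
Ranks are within-condition, descending weight, ties broken by atlas
order.  The expected ranking (ER) is the mean of a block's 1-based
within-condition rank across folds — equal to the final rank when
selection is perfectly stable.  (Published tables of this design contain
ER values below 1, impossible under any mean-of-ranks definition; the
formula behind those numbers is unpublished, so this package documents
and tests its own self-consistent definition.)  The predictive feature
set is every block strictly above 10% weight; between-model CV reruns the
identical nested machinery on the reduced kernel set, with self-pairing
as positive control.  Reports are deterministic TSV/JSON; reruns are
byte-identical.

## Synthetic data

The generator emulates the study design the pipeline targets:
~20 subjects, Gaussian questionnaire scores (default mean 35.45,
SD 22.53, the FABQ-like scale), a box-parcellation atlas (22 regions get
the bilateral fear-circuit AAL names), and per-condition beta patterns
β_i = effect_size · z(y_i) · v + ε with a fixed unit-norm random pattern
v per region, label standardization z, and i.i.d. voxel noise.
Informative blocks are an explicit list; the empty list is the null
model, and effect_size = 0 is bit-identical to it.  noise_sd = 0 is an
exact noiseless oracle mode used by the GLM recovery tests.

Full sessions use the published acquisition/design parameters: 365
volumes at TR 2.1 s, 15 + 15 stimuli of 4 s in pseudorandom order with no
more than two identical consecutive trials (rejection sampling, 1000-draw
cap), ITIs jittered uniformly in 6–8 s.  The rating screen after each
clip is unmodeled baseline; its duration is not published, so the default
is 11 s with a 10 s lead-in, leaving trailing rest inside the session.
Voxel time series are the same HRF-convolved regressors the design
builder produces (so noiseless recovery is exact by construction), plus
optional linear drift (also written to the confound table) and white
noise.

What the generator does *not* emulate: spatial autocorrelation,
physiological noise, motion, inter-subject anatomical variability, and
realistic covariance between questionnaires.  Passing tests therefore
demonstrate correctness of the machinery and calibration of the
inference under the stated model, not decoding performance on real
patients.

## Problem sizes in the test suite

Simulation-based checks use desk-scale configurations chosen as the
smallest sizes at which each property is meaningfully exercised:
permutation calibration runs 200 null studies × 199 permutations at
n = 8 subjects, one region × two conditions, C grid [1, 100]; weight
recovery runs 50 studies at n = 20 with 4 regions × 2 conditions and the
full C grid; the power floor uses n = 16 at an effect size giving
population decoding r ≈ 0.6.  Default `n_permutations` is 1000
(full-scale analyses of this design used 16000; it is one config change).

## Known limitations

* OLS only in the first level; no AR(1) whitening (unstated in the
  design this replicates; see above for why point estimates suffice).
* The ER column of the published reference tables cannot be reproduced
  exactly (unpublished formula); all other table arithmetic is.
* Printed-table consistency checks carry a 1.0-percentage-point slack,
  the agreement actually attainable from cells printed to 0.01 and
  footnotes printed to integers.
* No parallel execution; the compiled core makes single-CPU permutation
  runs practical at desk scale.
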