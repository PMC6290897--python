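# Methods

This note documents the models, conventions and numerical choices behind
`irsigflow`, in the order the pipeline runs them. Everything described here is
implemented and exercised by the test suite; no empirical claim below goes
beyond what the tests and `scripts/acceptance.py` themselves compute.

## Preprocessing

Fluorescence is analysed on the arcsinh scale, `asinh(x / c)`. The cofactor
`c` defaults to 150 (the conventional fluorescence-cytometry choice) and is
exposed in every entry point rather than hidden, because all downstream
statistics are threshold-relative. The transform is guarded against double
application and is exactly invertible (`sinh(y)·c`), which the tests check to
1e-9 relative error.

Per-subject event tables are downsampled to a fixed event count (default
10,000) by uniform sampling without replacement, preserving row order under a
fixed seed. CSV (comma-separated, header row of channel names, no index
column) is the interchange dialect for event tables; design tables and
analyte panels travel as TSV.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a test
convenience: its defaults encode the cohort structure the analysis targets
and all planted effects that downstream stages are expected to recover.

**Design.** Four groups — uninfected younger, uninfected older, HIV+ younger,
HIV+ older — with default sizes 21/21/22/28. Subjects are assigned to staining
batches cyclically over a randomly permuted order so each batch mixes groups
(default 11 batches). One FM5 control (all reagents except the five IR
antibodies) is generated per batch.

**Events.** Each cell draws a subset (γδ T 8%, CD4 T 40%, CD8 T 25%, NK 17%,
other 10%) and Gaussian lineage intensities around subset-specific means in
arcsinh units (negative ≈ 0.3, bright ≈ 4, SD 0.4). The γδ fraction is kept
above the 5% cluster-size floor so the population is discoverable by
size-thresholded clustering, mirroring the population sizes where this kind
of analysis is informative.

**IR expression.** Each IR has a per-cell positivity log-odds:

    logit p = base + HIV·β_HIV + old·β_age + u_subject + λ·z_cell   (γδ cells)
    logit p = base + offset_nonγδ + λ·z_cell                        (other cells)

with `u_subject ~ N(0, 0.3²)` a per-(subject, IR) random intercept and
`z_cell ~ N(0,1)` a shared latent activation scalar whose per-IR loading λ
induces positive IR co-expression — without it, multi-IR fractions and
combination trajectories would be products of marginals and the combinational
analysis would be degenerate. Bimodal IRs (PD-1, TIGIT, CD160) then draw
fluorescence from a positive (mean 2.5, SD 0.45) or negative (mean 0.15, SD
0.35) Gaussian; non-bimodal IRs (TIM-3, LAG-3) are a single Gaussian whose
mean shifts continuously by `1.6·p`, so no separation into components exists
— matching the real difficulty of gating them. Default planted effects (log-
odds): HIV raises TIGIT (+1.2), TIM-3 (+0.7), CD160 (+0.4) and lowers PD-1
(−0.3); older age raises TIGIT (+0.6) and CD160 (+0.2). FM5 controls draw all
five IR channels from the negative component only, which the tests verify by
a two-sample Kolmogorov–Smirnov comparison against main-sample IR-negative
cells.

**Analytes.** Plasma concentrations are log-normal with per-analyte HIV/age
shifts and a coupling term on the subject's generative TIGIT⁺ γδ fraction.
Supernatant secretion is linear per cell — `intercept + slope_group ×
TIGIT⁺fraction` plus Gaussian noise truncated at zero — multiplied by a
cultured cell count drawn uniformly from 2,000–26,000 per well; HIV groups
carry positive slopes (4×10⁻³ pg/cell per unit fraction), uninfected groups a
zero slope except a small negative MIP-1β slope. Three rarely-secreted
analytes sit below the 1 pg/well detection limit for most subjects so the 45%
responder cutoff has something to remove.

**What the generator does not emulate:** spillover/compensation, doublets,
debris and dead cells (assumed excluded upstream by manual pre-gating), batch
drift in fluorescence scales, heavy-tailed or skewed fluorescence noise, and
any dependence structure among plasma analytes beyond the shared TIGIT
coupling. Passing tests therefore demonstrate the *statistical machinery*
recovers known effects under a clean generative model — not that the defaults
reproduce any real cohort's biology.

## Gating and signatures

IR gates are the 0.995 quantile of the per-batch FM5 distribution per channel
(≈ 0.5% background positivity). A fixed quantile makes FM5-"guided" gating
deterministic and auditable; it is a single exposed parameter, including for
the non-bimodal IRs, which are counted in the ≥k-IR fractions through the
same rule. γδ cells are extracted as CD3 > 2.0 and γδTCR > 2.0 in arcsinh
units (the valley between the generator's negative and bright components).

Combination abundances over a k-IR set enumerate all 2^k patterns (zero
counts included), so each subject's abundances form a probability vector; the
3-IR set (PD-1, TIGIT, CD160) is used for abundance modeling because the
non-bimodal IRs cannot support a defensible positive/negative split, and the
4-IR set (adding TIM-3) only as a feature block for the discriminant model.
Subjects with zero gated cells propagate missing values, never zeros: a zero
abundance is a biological claim, a missing one is not.

## Cluster association (CITRUS-style)

Pooled events are clustered by Ward linkage on Euclidean distance over the
seven lineage channels. Dendrogram nodes at or above 5% of the pool qualify;
node size is monotone up the tree so the qualifying set is closed under
ancestors. Full Ward linkage needs O(n²) memory in pooled events, so the pool
is capped at 15,000 events (≈ 0.9 GiB of condensed distances) by even
per-sample subsampling; the cap is an exposed parameter and the documented
default problem size for this package.

Features are per-sample medians of the five IR channels within each
qualifying node; a sample with no events in a node is imputed with the node's
pooled median and flagged in a mask, so the association models need no
missing-data machinery.

**Nearest shrunken centroid (PAM).** Per feature i and class k,

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n),

with `s_i` the pooled within-class SD and `s0` the median of the `s_i` (the
PAM convention). Centroids are soft-thresholded by Δ
(`d'_ik = sign·max(|d|−Δ, 0)`) and classification uses the shrunken-centroid
discriminant with class priors proportional to class sizes. Δ is chosen by
stratified cross-validation (default 10-fold) as the **largest** value
attaining the minimum CV error — the model with the fewest surviving
features among the best. A fold that loses a class is re-drawn with a new
sub-seed.

**SAM selection.** Two-class moderated difference `d_i = Δx̄_i / (s_i + s0)`
with `s0` = median of the `s_i`; the null is built from label permutations
(≥100). Estimated FDR at a cutoff is the **mean** permuted exceedance count
over the observed count — the expected number of falsely called features.
The mean, rather than the median, of permuted counts is used because at
stringent targets (1%) the median's integer granularity lets single null
features through ~half the time, which a calibration simulation in the test
suite makes visible; with the mean the global-null significant set is almost
always empty while planted 2.5-SD effects are still recovered. Significant
sets are |d|-ranked prefixes, hence nested across FDR levels.

## Abundance modeling: beta regression + minP threshold

Each combination abundance is fit by maximum likelihood as
`y ~ Beta(μφ, (1−μ)φ)` with `logit μ = β₀ + β_HIV·HIV + β_age·old`. The
optimizer is Fisher scoring on (β, log φ) with analytic gradient and expected
information, step-halving, and a BFGS fallback; Wald standard errors come
from a finite-difference observed-information Hessian at the optimum. The
least-squares start on the logit scale plus a moment start for φ makes the
fit fast enough for the permutation loop (~1 ms per fit). Boundary values
(y ∈ {0,1}) are handled by the standard interior transform
`y' = (y(n−1) + 0.5)/n`, applied to the whole vector and flagged.

Family-wise error over the eight subsets is controlled per model term by a
permutation minP threshold: each subject's vector of eight abundances is
permuted across the subset labels independently per subject — the reading
under which each subject's abundance inter-dependency is literally preserved,
and an exact null when subsets are exchangeable. (The alternative reading,
resampling each subset column across subjects, is available behind
`scheme="across_subjects"` but not endorsed: it breaks the within-subject
composition.) Per permutation, all eight regressions are refit and the
minimum p per term recorded; the threshold is the ⌈0.05·n_perm⌉-th smallest
minimum (the 5th smallest at the default 100 permutations, no interpolation —
reproducible and conservative at small n_perm). Subject vectors are sorted
before permuting, which leaves the permutation law unchanged under the null
and makes the realized threshold invariant to subset column order. A
non-convergent permutation fit scores p = 1 — conservative for a minimum.
One permutation stream serves both terms in a run. Significance is strict:
a subset is called for a term iff its observed Wald p < that term's
threshold.

The package's headline calibration — the empirical FWER of this procedure
under exchangeable null abundances — is recomputed from scratch by
`scripts/acceptance.py` (100 replicate 90-subject cohorts).

## PLS models

NIPALS with deflation of both X and Y (convergence tolerance 1e-10, at most
500 inner iterations), on column-z-scored blocks (sample SD; the z-scoring
parameters are stored for scoring new samples and inverse mapping).
Discriminant mode encodes classes as one indicator column per class and
decodes by argmax with ties to class order.

* **LV count.** "One-third of the dataset" holdouts are implemented as 3-fold
  CV (every sample predicted exactly once), stratified by class in
  discriminant mode; error is the RMSE of held-out predictions (regression)
  or the misclassification fraction (discriminant), minimized over the grid
  with ties to the smaller model. Columns that are constant within a
  training fold are dropped for that fold.
* **Permutation confidence.** The minimal well-formed version of the stated
  rank test: the true model's per-held-out-sample CV errors (one per sample)
  against the pooled per-sample errors of ≥20 Y-permuted rebuilds, one-sided
  Mann–Whitney U (true smaller). The LV count is re-selected inside each
  permutation by default (conservative); `reselect_a=False` freezes it.
* **VIP.** `VIP_j = √(p · Σ_a w²_ja SSY_a / Σ_a SSY_a)` with SSY_a the Y sum
  of squares captured by component a and W the unrotated, column-normalized
  weights — hence mean(VIP²) = 1 exactly, and VIP > 1 flags above-average
  contributors.
* **Rotation.** The LV basis is rotated by a product of Givens rotations in
  the (1, j) planes (a single angle search when A = 2; grid + bounded
  refinement, cyclic sweeps for A > 2) to maximize on axis 1 the
  between-class variance fraction (discriminant) or |covariance| with Y
  (regression). Scores, loadings and weights rotate together, so fitted
  values and predictions are unchanged — verified to 1e-9.
* **Score ellipses.** 95% confidence ellipses scale the 2×2 score covariance
  eigenvalues by the χ²(2 df) quantile.

## Univariate layer

Welch's unequal-variance t-test is the default two-sample comparison (the
pooled-variance variant is a flag). The four-group mode runs all six pairwise
comparisons at Bonferroni-adjusted α = 0.05/6; the displayed threshold is
truncated (not rounded) to three decimals — 0.008 — while decisions use the
untruncated value, and all threshold comparisons in the package are strict.
Pearson correlation matrices of the eight combination abundances are computed
separately for the uninfected and HIV+ strata (both age groups pooled within
each); p-values are uncorrected and labeled as such. Supernatant
concentrations are divided by each subject's cultured cell count before
modeling (double-normalization guarded); analytes detected in under 45% of
subjects are dropped before regression.

## Problem sizes

The defaults aimed at real data are 10,000 events/subject and a ~92-subject
cohort. The test suite and the acceptance script run the same code at the
package's documented desk scale: 800–1,000 events/subject, 32–40 subjects,
a 15,000-event pooled clustering cap, 100 within-subject permutations for
the minP threshold, 30–50 Y-permutations for PLS confidence, and 30–100
replicate cohorts for the calibration simulations. These sizes are the
package's own reference configuration for development and verification.

## Known limitations

* The FCS binary format is not read or written; events travel as CSV.
* The beta model has exactly the HIV and age main effects — no interaction,
  no further covariates — matching the analysis design it implements.
* SAM is two-class only; the PAM classifier supports multiple classes.
* Correlation-matrix p-values are uncorrected.
* The generator's distributional assumptions (Gaussian components in arcsinh
  space, logistic-normal positivity, log-normal analytes) are stand-ins
  chosen for transparency, not fits to any dataset; conclusions about real
  cohorts require real data through the same interfaces.
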