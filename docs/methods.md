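# Methods

## The asymmetry index

The Cortical Asymmetry Index summarises, for a single subject-visit, how
differently cortical thickness is distributed over the two hemispheres.
Each hemisphere contributes the 34 Desikan-Killiany regional mean
thickness values (mm); these are treated as a sample from a hemispheric
thickness distribution.

**Density estimation.** How a 34-value sample becomes a "distribution" is
a genuine design choice; we default to a Gaussian kernel density estimate
with the Silverman rule-of-thumb bandwidth, `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`,
because a KDE is the natural probability-density reading and is smooth at
n = 34. A histogram estimator (`counts/(n·bin width)` at the grid bins) is
provided as a configurable alternative so other conventions can be
matched. Samples are sorted before estimation so the result is bit-for-bit
invariant to region ordering.

**Shared grid.** Both hemispheres are evaluated on one grid of 128 equally
spaced points spanning the pooled min–max of the 68 values, padded by 10%
of the pooled range on each side (for a degenerate zero-range pool the pad
falls back to 10% of the pooled mean). The grid is per subject — the index
is computed individually, across hemispheres, which is what makes it
robust to between-subject offsets without any explicit normalisation.

**Divergence.** With density vectors `p`, `q` on the grid, mixture
`m = (p+q)/2`, and natural logarithms:
`KL(p‖q) = Σ pᵢ ln(pᵢ/qᵢ)`, `JS = ½KL(p‖m) + ½KL(q‖m)`, `CAI = √JS`.
The Jensen–Shannon form (divergence from the mixture, not a symmetrised
average of the two KLs) is fixed by this package; it is the standard
definition and guarantees symmetry and non-negativity for normalised
inputs. The implementation is written symmetrically so swapping arguments
is bitwise identical.

**No renormalisation.** The defining deviation from the textbook JS
distance is that the grid-evaluated density vectors are fed to the
divergence as-is, without rescaling to unit sum over grid points. The
vector sum of a KDE on a grid of step `Δ` is ≈ 1/Δ, so the unnormalised
divergence is ≈ (1/Δ)·JS of the normalised densities, and the index scales
with grid resolution. Consequences we accept and document: (a) grid
construction (128 points, 10% padding) is part of the index definition and
is recorded in every result; (b) the index is not bounded by √ln 2 the way
the normalised distance is. Setting `normalise=True` recovers the textbook
behaviour, and in that mode disjoint hemispheric supports drive the index
to √ln 2 ≈ 0.8326 (verified as a closed-form limit test).

**Numerical safeguards.** Density values are floored at 1e−12 before any
logarithm; an all-equal thickness sample (zero Silverman bandwidth) falls
back to a user-supplied fixed bandwidth and is a hard error otherwise —
degenerate inputs are never silently mapped to zero asymmetry. Tiny
negative divergence from floor round-off is clipped at 0 before the square
root.

## Cohort inference

* **Cross-sectional group comparison**: ANCOVA — a linear model
  `cai ~ group + age` with a type-II F-test on the group factor — followed
  by Tukey HSD on the covariate-adjusted group means, using the model's
  residual variance and the studentized-range distribution. With two
  groups and no covariates this collapses exactly to the pooled-variance
  t-test (used as a test oracle). Applying Tukey to adjusted rather than
  raw means is our reading of "age-corrected ANOVA with Tukey post hoc";
  it is the standard construction when a covariate is in the model.
* **Longitudinal change**: per clinical group, a linear mixed model with a
  random intercept per subject and fixed effects for the time-varying age
  at MRI, sex, and (patient groups only) age of onset. The age-at-MRI
  coefficient carries the within-subject change between visits; an
  optional `visit × age` interaction is available behind a flag for the
  stricter "interaction with age" reading. Numeric covariates are centred
  before fitting (slopes unchanged) to keep the profile likelihood
  well-conditioned at age-in-years scale; boundary/singular random-effect
  fits are flagged in the results object, never hidden.
* **Associations**: Spearman rank correlations with pairwise deletion of
  missing values; pairs with fewer than 4 complete observations are
  flagged as insufficient and carry no p-value. Missing-data policy
  elsewhere is listwise within each fitted model.
* **Biomarker group differences** (clinical-table layout): per biomarker a
  one-way ANOVA omnibus plus pairwise Welch t-tests with
  Benjamini–Hochberg adjustment across the pairwise family within each
  biomarker.
* **Subtyping**: agglomerative-nesting hierarchical clustering of the 1-D
  CAI values using Manhattan pairwise dissimilarities under the Ward
  (Lance–Williams) merge update — the AGNES pairing of Ward with a
  non-Euclidean metric; on 1-D data Manhattan and Euclidean coincide,
  which softens the textbook inconsistency. The number of clusters is the
  argmax of mean silhouette width (computed with the clustering metric)
  over k = 2…6, shrunk for small groups; k never exceeds the number of
  distinct values. Rows are pre-sorted by (CAI, subject id) so merges and
  labels are deterministic and invariant to input order. Cluster 1 is
  always the higher-mean-CAI cluster. Clustering uses CAI alone, by
  design. Cluster-biomarker contrasts z-score each biomarker within the
  disease group, then apply the Wilcoxon rank-sum (k = 2) or
  Kruskal–Wallis (k > 2) test; raw p-values are reported by default with
  an optional BH flag.
* α = 0.05 throughout.

## The synthetic cohort generator

The generator emulates the structure of a three-group memory-clinic
cohort so that every inferential stage can be validated against planted
ground truth. Defaults reproduce the reference study design: 173 CTR /
230 AD / 55 bvFTD / 21 nfvPPA / 24 svPPA, follow-up fractions per arm
(96/173, 29/230, 14/55, 7/21, 9/24) with ≈2-year (CTR, AD) or ≈1.5-year
(FTD) revisit intervals, and arm-specific age and sex distributions.

Per subject: 34 region-mean thicknesses are drawn from N(2.5, 0.25²) mm;
the left hemisphere adds independent N(0, 0.0183²) mm regional noise; the
right hemisphere equals the left plus the same noise and a planted
rightward deficit on a per-subject random subset of regions (8 regions; 10
for svPPA, drawn temporal-lobe-first to mirror its atrophy topography).
The deficit is the arm-level shift (0 CTR / 0.075 AD / 0.089 bvFTD /
0.118 nfvPPA / 0.160 svPPA mm) times a per-subject severity multiplier
~ N(1, 0.4²) truncated at 0.05. Second visits redraw the noise and add a
longitudinal increment (0.056 mm in FTD arms) to the shifted regions.
Localised (not global) shifts are deliberate: a distributional index
responds to shape changes, and focal atrophy is what these diseases
produce.

The noise level and shifts were calibrated once, by fixed-point iteration
over simulation replicates, so the simulated group-mean CAIs land on the
published cohort values 0.16 (CTR), 0.40 (AD), 0.46 (bvFTD), 0.62
(nfvPPA), 0.83 (svPPA) with the follow-up FTD mean near 0.82; they are
frozen as the config defaults. Because the unnormalised divergence
amplifies hemispheric noise by the grid factor, the control-group index
floor is set by the within-region noise — which is why that noise (0.0183
mm) is part of the calibration rather than a free parameter.

Biomarkers are drawn per subject as `mean_g + sd_g·(w·z + √(1−w²)·ε)`
where `(mean_g, sd_g)` are group-level values patterned on published
clinical summaries (e.g. CSF NfL 536/1107/2341 pg/mL for CTR/AD/FTD),
`z` is the subject's severity z-score within the diagnostic group, and the
link strength `w` encodes the planted association: CSF NfL 0.35 and plasma
NfL 0.50 in FTD, plasma GFAP 0.30 in AD, MMSE −0.35 in AD; all other
marker/group pairs are unlinked. Values are clipped at 0 (MMSE at
[0, 30]). The truth table records each subject's planted mean rightward
shift and severity, enabling recovery tests.

Randomness flows from one seed through per-subject seed sequences
(`SeedSequence(seed, spawn_key=(arm, subject))`), so any subject is
reproducible independently of cohort size and the whole pipeline is
byte-deterministic given a seed.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: spatially correlated atrophy and real
region-level covariance, scanner/protocol effects, measurement error in
FreeSurfer segmentation, left-dominant svPPA lateralisation (shifts are
rightward by convention; the index is side-blind), non-Gaussian biomarker
distributions (clinical NfL is right-skewed), informative follow-up
drop-out, and diagnostic label noise. Recovery results here validate the
statistical machinery at realistic effect sizes, not clinical performance.

## Problem sizes used in validation

The shipped validation suite runs the simulator at reduced but
statistically meaningful sizes chosen as a sensible power/runtime
trade-off: calibration checks at n = 50/arm; type-I error on 200 label
permutations of a 180-subject null cohort; power at n = 60/group over 50
replicates; longitudinal recovery with 30 two-visit FTD subjects over 50
replicates; association recovery at n = 100 FTD over 50 replicates. The
acceptance script runs the full reference design (554 subjects, 658
scans).

## Known limitations

* The index depends on the density estimator, bandwidth rule, grid size
  and padding; comparisons are only meaningful at fixed settings (the
  settings object travels with every result for this reason).
* Unnormalised divergence values are grid-scale dependent by construction;
  use `normalise=True` for a scale-free variant bounded by √ln 2.
* The ANCOVA/Tukey construction assumes homoscedastic residuals across
  groups; the clustering operates on a single feature and inherits the
  usual instability of silhouette selection on weakly separated data.
* Mixed models use a random intercept only; with exactly two visits a
  random slope is not identifiable anyway.
* Diagnostic performance (sensitivity/specificity of the index) is out of
  scope.
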