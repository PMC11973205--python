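# Methods

This note documents the models and procedures implemented in `spatialtme`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Input model and geometry

The unit of data is a *cell table*: one row per segmented cell with planar
coordinates in µm (origin top-left, y down — image convention), a region
(ROI) id, a patient id, and a type label from a fixed 10-type vocabulary
(three tumor classes: epithelial, p53+, proliferative; stromal/fibroblast;
six immune classes: proliferative immune, macrophage, B cell, ILC/NK,
CD4+ T, CD8+ T). Regions carry extent and optionally tumor purity; patients
carry MSI status, recurrence, and overall survival. Unknown clinical fields
are kept as the literal category `unknown` and subset explicitly by each
comparison; rows are never dropped at load time.

Contact rules are defined between cell *borders*, but tabular input has no
segmentation masks. Each cell is therefore modeled as a disc of its
equivalent radius; absent a radius column the default is 5 µm, the scale of
a tightly packed epithelial cell section. The border distance between discs
is max(0, ‖c_i − c_j‖ − r_i − r_j), floored at zero so overlapping
(imperfectly segmented) cells count as touching. Contacts use this border
metric with an inclusive 6 µm threshold; Delaunay edges and k-NN sets use
center-to-center distance. The two metrics are deliberately distinct: the
contact rule describes membrane apposition, the neighborhood radius
describes a cell's local community.

## Tier 1 — composition

Proportions are computed per region and per patient (patient level pools a
patient's cells across regions before dividing, so larger regions weigh
more). Empty units are excluded with a logged warning, never emitted as
silent zero rows.

Group testing works on the empirical logit
y = log((n + 0.5)/(N − n + 0.5)); the half-count offset is the standard
choice that keeps y finite at n = 0 and n = N and approximately stabilizes
the variance of count-derived fractions. Because several regions per
patient are replicates, not independent samples, the model treats patient
as an exchangeable random block:

* a common intra-patient correlation ρ is estimated per category by REML
  under the block-exchangeable covariance, using the eigen-structure of the
  exchangeable block (mean direction scaled by 1 + (m−1)ρ, deviations by
  1 − ρ); per-category estimates are combined by averaging on the atanh
  scale and the result capped at |ρ| ≤ 0.99. With only singleton blocks
  there is no replicate information and ρ = 0 is returned with a warning.
* the two-condition contrast, with mean-centered tumor purity as covariate,
  is fitted per category by generalized least squares after whitening with
  ρ. Purity enters at the ROI level for ROI-level tests and as the patient
  mean for patient-level tests; missing purity values are mean-imputed with
  a warning (this removes those units' influence on the covariate without
  discarding them), and a constant or collinear covariate is dropped.
* residual variances are shrunk toward a pooled prior by the standard
  empirical-Bayes squeeze: a scaled inverse-χ² prior (d₀, s₀²) fitted by
  moment matching on log variances (digamma/trigamma inversion), posterior
  variance (d₀s₀² + d·s²)/(d₀ + d), moderated t with df = d₀ + d. d₀ is
  capped at 500 to avoid a degenerate fully pooled fit when categories are
  few or homogeneous.
* p values are Benjamini-Hochberg adjusted within one comparison (never
  pooled across comparisons).

Spearman correlograms between category proportions are computed at the
patient level; constant columns yield undefined correlations that are
reported as missing and excluded from the BH family.

## Tier 2 — interactions

For an ordered pair (A, B), the directed mean interaction is
M[A][B] = (#contact incidences counted from A's side) / #A — "how many B
neighbors a typical A cell has". The direction matters: one tumor cell
surrounded by five lymphocytes and one lymphocyte surrounded by five tumor
cells give the same contact count but different means. A homotypic contact
is counted from both endpoints, so two touching B cells give M[B][B] = 1.

The permutation test shuffles type labels over the fixed contact graph
(type counts preserved; since counts are invariant, comparing raw incidence
counts is equivalent to comparing means). Two one-tailed add-one p values
are computed per ordered pair, p = (1 + #{perm ≥/≤ obs}) / (1 + n_perm),
which are valid (P(p ≤ α) ≤ α) by construction. Label rule at α = 0.01:
p_high < α ⇒ interaction, p_low < α ⇒ avoidance; when both tails pass
(possible with discrete statistics) the smaller p wins and a tie yields no
label. Each region gets a deterministic substream derived from the global
seed. Pairs involving an absent type are left unlabeled.

Cohort summary: logFC = log₂((n_interacting + 1)/(n_avoiding + 1)) with
add-one smoothing in both counts, which keeps the summary finite, symmetric
and maps equal counts — including 0/0 — to exactly 0. Base 2 is the
conventional fold-change base.

The interaction score for an unordered pair is (#contacts joining the two
types)/(#all contacts in the region); over all pairs (homotypic included)
the scores of a region sum to 1. The small-count filter excludes a region
*for a pair* when either member type has fewer than 20 cells; reading the
filter as "any of the 10 types under 20" would exclude nearly every region
because rare types (proliferative immune ≈ 1%) almost never reach 20.
Score testing reuses the Tier-1 machinery: the logit transform is applied
to contact counts, y = log((n_pair + 0.5)/(n_total − n_pair + 0.5)); since
exclusions are pair-specific, each pair is fitted on its own included
regions, ρ is pooled across pairs on the atanh scale, and the variance
squeeze is shared with per-pair residual df.

## Tier 3 — neighborhoods, TILs, survival

A cell's neighborhood feature is the type composition of its up-to-10
nearest neighbors within 40 µm. The radius is motivated by a diagnostic the
package also provides: the modal Delaunay edge length in tissue at typical
imaging density is ≈ 10 µm, so 40 µm bounds a plausible communication
distance and prevents sparse tissue from creating spurious far neighbors.
The index cell is included in the composition by default (the neighborhood
describes the cell's local community including itself); both modes are
supported and logged. Cells with zero in-radius neighbors are flagged
isolated, excluded from clustering and from TIL denominators.

CNs are K-means clusters (squared Euclidean on composition vectors,
k-means++ with 10 restarts, fixed seed, default k = 8) pooled across the
whole cohort so classes are comparable between patients. Annotation is
rule-based on centroids: dominant type names the cluster; tumor subtypes
map to "bulk tumor" / "p53+ tumor" / "proliferative tumor";
stromal-dominant clusters with ≥ 25% summed immune fraction become
"immune-enriched stromal"; no type reaching 40% dominance gives "mixed
immune"; duplicates get an index suffix. A user rule table overrides any
cluster.

TILs are defined spatially: lymphocytes (CD4+ T, CD8+ T, B) in tumor CNs
are iTILs, in stromal CNs sTILs, everything else "none" — non-lymphocytes
never receive a TIL label and counts are conserved. Two denominator
conventions are supported for per-unit proportions: all cells in the
compartment's CNs (default — "TILs among tumor CNs"), or only the
compartment's reference cells (tumor-type cells in tumor CNs, stromal cells
in stromal CNs). Patients are dichotomized at the Otsu threshold of their
sTIL proportions (256 equal-width bins over the observed range; the method
is affine-invariant so the binning choice is scale-free), and the high/low
groups are compared with Kaplan-Meier curves, the standard
hypergeometric-variance log-rank test, and a Cox proportional-hazards fit
for the group indicator (skipped with a warning when a group has no
events).

## Synthetic tissue generator

The generator emulates the structure of a multi-patient imaging study:
two clinical arms (default MSI-H n = 9, MSS n = 33, echoing a stage III
colorectal cohort split), 2-8 regions of 500 × 500 µm per patient, and
1600-2400 cells per region, i.e. ≈ 0.008 cells/µm² — a density that
reproduces the ≈ 10 µm modal nearest-neighbor spacing of real tissue.
Cells arise from niches: Gaussian clouds (σ ≈ 60-80 µm) around centers
placed uniformly (or at user-fixed positions for planted-truth
experiments), each with its own type mixture — by default a tumor-dominated
"bulk tumor" niche, a "stromal" niche, and an "immune-enriched stromal"
niche whose balance differs between arms. Per-patient Dirichlet
perturbation (concentration 150) adds realistic between-patient composition
variability. Spatial interaction is imposed by conditional re-placement: for
an attraction (A, B, s), a fraction s/(1 + s) of B cells is moved within
contact range of a random A cell. This is deliberately not a Gibbs point
process: downstream tests need a monotone dose-response in s, not a
specific process family. A hard core forbids centroid distances below
0.8 (r_i + r_j) (radii ≈ N(4, 0.6²) µm truncated to [2, 8]), mimicking
non-overlapping segmented cells; placement failure after bounded retries
raises an error suggesting lower density.

Survival is exponential per patient with hazard
λ = λ₀ · m^(sTIL fraction), λ₀ = 0.012/month and m = 0.05 (strongly
protective across the realistic 0-0.3 sTIL range), where the sTIL fraction
is the *realized* fraction of lymphocytes among cells of
stromal-compartment niches. Censoring is administrative at the 90th
percentile of drawn times. Recurrence is logistic in the sTIL fraction
(intercept 0.2, slope −8).

What the generator does **not** emulate: segmentation error and doublets,
marker intensities, irregular region outlines, spatial gradients within
niches, and correlated clinical covariates. Passing tests therefore
demonstrate the statistical machinery's correctness and power under clean
geometry, not robustness to imaging artifacts.

Reproducibility: a single global seed; every region, patient and
cohort-level draw uses a counter-based `SeedSequence` substream, so regions
are independently reproducible and whole cohorts byte-identical across
runs.

## Problem sizes used in validation

The validation suites run at desk scale: permutation-test validity uses
1000 CSR regions of ~200 cells with 1000 permutations each; attraction
recovery uses 100 cohorts of 2 × 15 patients × 2 regions × 400 cells;
composition-shift recovery uses 200 replicates of 10 patients/arm × 2
regions on the transformed scale; niche recovery uses one cohort with three
planted, spatially separated niches; hazard-ratio recovery uses 200
replicates of 40 patients/arm. These sizes give Monte-Carlo error small
enough for the stated thresholds while keeping the full suite fast.

## Known limitations

* The disc approximation makes the 6 µm rule depend on radius quality;
  with boundary polygons a true membrane distance would be preferable.
* The exchangeable-block correlation is a single pooled ρ; strongly
  heterogeneous patients would warrant per-patient variance components.
* K-means on compositions ignores the simplex geometry; a mixture model on
  log-ratios is a possible refinement.
* Otsu thresholding assumes a roughly bimodal sTIL distribution; with
  unimodal data the split is arbitrary (the constant-input case raises).
* The CLI's score test uses the configured contrast only; arbitrary design
  matrices are available through the library API.
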