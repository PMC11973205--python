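# spatialtme

Three-tier spatial single-cell analysis of the tumor microenvironment, for
cell tables produced by multiplexed tissue imaging (imaging mass cytometry,
CODEX, and similar). Given per-cell coordinates, cell-type labels, region
metadata and clinical annotations, the package quantifies

1. **Composition** — cell-type proportions per tissue region or patient,
   compared between patient groups (e.g. MSI-H vs MSS, recurrence vs none)
   with variance-stabilized moderated tests, plus Spearman correlograms of
   proportions;
2. **Pairwise interactions** — cell-cell contacts under a membrane-distance
   rule, a histoCAT-style permutation test for per-region interaction /
   avoidance with a cohort logFC summary, and a quantitative *interaction
   score* that supports condition-level testing with regions treated as
   patient replicates;
3. **Cellular neighborhoods and TILs** — k-nearest-neighbor composition
   features, K-means cell neighborhoods (CNs), CN proportion analyses, and a
   spatial definition of tumor-infiltrating lymphocytes (intratumoral iTILs
   in tumor CNs, stromal sTILs in stromal CNs) feeding Otsu-thresholded
   high/low stratification and Kaplan-Meier / Cox survival comparison.

A synthetic tissue generator with planted ground truth (niches, pairwise
attraction, arm-specific composition, sTIL-dependent survival) makes every
stage verifiable without access to real imaging data.

## The statistics

**Contacts.** Two cells interact when their outer membranes are ≤ 6 µm
apart; with tabular input each cell is a disc of radius *r*, so the border
distance is max(0, ‖c_i − c_j‖ − r_i − r_j).

**Permutation interaction test.** Per region and ordered type pair (A, B),
the mean interaction count is M[A][B] = (#A-side contact incidences with B)
/ #A. Type labels are shuffled over the fixed contact graph (1000
permutations, type counts preserved) and two one-tailed add-one p-values are
computed: p_high = (1 + #{M_perm ≥ M_obs}) / (1 + n_perm), analogously
p_low. P < 0.01 labels the pair *interaction* or *avoidance*. Cohort
summary: logFC = log₂((n_interacting + 1) / (n_avoiding + 1)).

**Interaction score.** score(A,B) = (#contacts joining A and B) / (#all
contacts in the region) — a proportion, so scores from a patient's several
regions can be modeled together. Regions with < 20 cells of either member
type are excluded for that pair.

**Moderated group tests.** Proportions (and scores) are transformed with
the empirical logit y = log((n + 0.5)/(N − n + 0.5)). A common intra-patient
correlation ρ of regions is estimated by REML under a block-exchangeable
model (the duplicate-correlation device), the group contrast (with tumor
purity as covariate) is fitted by generalized least squares, per-category
variances are shrunk by an empirical-Bayes squeeze (scaled inverse-χ²
prior, moment-matched on log variances), and moderated t statistics with
df = d₀ + residual df are BH-adjusted.

**CNs and TILs.** Each cell's neighborhood is the type composition of its
≤ 10 nearest neighbors within 40 µm (index cell included by default);
K-means with k = 8 over all cells yields CN classes, auto-annotated from
centroid composition. Lymphocytes (CD4+ T, CD8+ T, B) in tumor CNs are
iTILs; in stromal CNs, sTILs. Per-patient sTIL proportions are split
high/low at the Otsu threshold (256-bin histogram) and compared by
log-rank / Cox.

## Worked example

```python
from spatialtme.simulate import SimulationConfig, simulate_cohort
from spatialtme.spatial import contact_pairs
from spatialtme import composition as comp, interactions as ia, neighborhoods as nb

cfg = SimulationConfig(seed=11)               # two arms: MSI-H and MSS
cfg.arms[0].n_patients = 6; cfg.arms[1].n_patients = 6
cfg.rois_per_patient = (2, 3)
cfg.roi_width_um = cfg.roi_height_um = 250.0
cfg.cells_per_roi = (450, 550)
cohort, truth = simulate_cohort(cfg)          # 14485 cells / 29 regions / 12 patients

pm = comp.proportions(cohort, level="roi")
y = comp.empirical_logit(pm)
X, units, ci = comp.make_design(pm.meta, ("msi_status", "MSI-H", "MSS"))
blocks = pm.meta.loc[units, "patient_id"].to_numpy()
rho = comp.estimate_block_correlation(y.loc[units], X, blocks)   # 0.536
res = comp.moderated_group_test(y.loc[units], X, ci, blocks, rho)
print(res.table[["effect", "t", "p", "p_adj"]].sort_values("p").head(3))
#                      effect       t       p   p_adj
# ILC/NK               0.4511  1.8431  0.0757  0.3272
# stromal             -0.1378 -1.7217  0.0960  0.3272
# proliferative tumor  0.3017  1.6498  0.1099  0.3272
```

The estimated intra-patient correlation (0.536) reflects that regions from
one tumor resemble each other; at this small scale no cell type passes
FDR ≤ 0.05 between the identically parameterized arms' composition — the
arms differ only mildly in niche balance, so this is the expected null-ish
answer. The interaction tier, on the same cohort:

```python
regions = [(contact_pairs(s.reset_index(drop=True)), s.reset_index(drop=True))
           for _, s in cohort.iter_rois()]
cls = [ia.permutation_interaction_test(s, a, cohort.type_vocab, n_perm=1000, seed=i)
       for i, (a, s) in enumerate(regions)]
print(ia.cohort_logfc(cls).sort_values("logfc", ascending=False).head(2))
#            type_a               type_b  n_interaction  n_avoidance  logfc
#  epithelial tumor           p53+ tumor              2            0  1.585
#  epithelial tumor  proliferative tumor              2            0  1.585
```

Tumor subtypes co-cluster in tumor niches, so tumor-tumor pairs top the
cohort logFC ranking. Finally the TIL tier:

```python
feats, _ = nb.cohort_cn_features(cohort)
model = nb.annotate_cns(nb.cluster_cns(feats, k=8, seed=0))
tils = nb.classify_tils(cohort.cells, model,
                        tuple(n for n in model.names.values() if n in nb.DEFAULT_TUMOR_CNS),
                        tuple(n for n in model.names.values() if n in nb.DEFAULT_STROMAL_CNS))
tp = nb.til_proportions(tils, cohort.cells, level="patient")
thr, groups = nb.otsu_split(tp["sTIL_proportion"].dropna())
sr = nb.survival_compare(cohort.clinical, groups, threshold=thr)
print(thr, sr.logrank_p)   # 0.096  0.711
```

Patients split at a sTIL proportion of 9.6%; with 12 patients the log-rank
comparison is (correctly) inconclusive.

## Command line

```bash
spatialtme simulate --config sim.yaml --out out/            # synthetic cohort
spatialtme run --cells cells.csv --rois rois.csv --clinical clin.csv --out out/
spatialtme interactions --sim-config sim.yaml --n-perm 1000 --out out/
```

Every run writes one CSV per result table plus a manifest stamped with the
configuration hash; identical config + seed reproduces all tables exactly.

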