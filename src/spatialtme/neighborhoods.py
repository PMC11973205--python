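"""Tier 3 — cellular neighborhoods (CNs), spatial TILs, and survival.

A cell's *neighborhood* is the composition (type fractions) of its up-to-10
nearest neighbors within 40 um, optionally including the index cell itself.
K-means over these composition vectors pooled across the whole cohort yields
recurring niche classes (default k = 8), which are auto-annotated from their
centroid composition ("bulk tumor", "stromal", "immune-enriched stromal",
"CD8+ T enriched", "mixed immune", ...).

Tumor-infiltrating lymphocytes (TILs) are then defined *spatially*: a
lymphocyte (CD4+ T, CD8+ T, or B cell) sitting in a tumor-dominated CN is an
intratumoral TIL (iTIL); one sitting in a stromal CN is a stromal TIL
(sTIL). Per-unit TIL proportions feed an Otsu threshold that dichotomizes
patients into high/low groups, compared by Kaplan-Meier / log-rank and an
optional Cox proportional-hazards fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from spatialtme import composition
from spatialtme.core_io import Cohort, LYMPHOCYTE_TYPES, TUMOR_CELL_TYPES
from spatialtme.spatial import NeighborSets, knn_within_radius

logger = logging.getLogger(__name__)

__all__ = [
    "CNModel",
    "TILTable",
    "SurvivalResult",
    "cn_features",
    "cohort_cn_features",
    "cluster_cns",
    "annotate_cns",
    "cn_proportion_analyses",
    "classify_tils",
    "til_proportions",
    "otsu_split",
    "survival_compare",
]

DEFAULT_TUMOR_CNS = ("bulk tumor", "p53+ tumor", "proliferative tumor")
DEFAULT_STROMAL_CNS = ("stromal", "immune-enriched stromal")


@dataclass
class CNModel:
    """Fitted K-means cell-neighborhood model.

    ``labels`` maps each clustered cell (index aligned with the feature
    matrix) to a cluster in [0, k); ``names`` maps cluster index to an
    annotation; ``cn_of_cell`` gives the named CN per cell.
    """

    k: int
    centroids: pd.DataFrame  # k x types, rows sum to 1
    labels: pd.Series  # per clustered cell, int
    names: dict[int, str] = field(default_factory=dict)
    seed: int = 0

    @property
    def cn_of_cell(self) -> pd.Series:
        if not self.names:
            raise ValueError("model not annotated; call annotate_cns first")
        return self.labels.map(self.names)


@dataclass
class TILTable:
    """Per-cell TIL class plus the CN compartment each cell sits in."""

    til_class: pd.Series  # {"iTIL", "sTIL", "none"} per cell
    compartment: pd.Series  # {"tumor", "stromal", "other", NaN} per cell


@dataclass
class SurvivalResult:
    """Two-group survival comparison."""

    curves: dict[str, pd.DataFrame]  # per group: time, at_risk, survival
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float | None = None
    hazard_ratio_ci: tuple[float, float] | None = None
    threshold: float | None = None


def cn_features(
    neighbors: NeighborSets,
    cells: pd.DataFrame,
    vocab: tuple[str, ...],
    include_index: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell neighborhood composition for one region.

    Returns ``(features, isolated)``: fractions over the vocabulary per cell
    (rows sum to 1) and a boolean mask of cells with zero in-radius
    neighbors, which get no feature row and are excluded from clustering.
    """
    t = len(vocab)
    code = pd.Categorical(cells["cell_type"], categories=list(vocab)).codes.astype(np.intp)
    n = len(cells)
    feats = np.zeros((n, t))
    isolated = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = neighbors.neighbors[i]
        if len(nb) == 0:
            isolated[i] = True
            continue
        counts = np.bincount(code[nb], minlength=t).astype(float)
        if include_index:
            counts[code[i]] += 1
        feats[i] = counts / counts.sum()
    features = pd.DataFrame(feats[~isolated], index=cells.index[~isolated], columns=list(vocab))
    return features, isolated


def cohort_cn_features(
    cohort: Cohort,
    k: int = 10,
    radius_um: float = 40.0,
    include_index: bool = True,
) -> tuple[pd.DataFrame, pd.Index]:
    """Stacked neighborhood features for every region of a cohort.

    Returns the pooled feature matrix (indexed like ``cohort.cells``) and
    the index of isolated cells that were flagged and excluded.
    """
    frames = []
    isolated_idx = []
    for _, sub in cohort.cells.groupby("roi_id", sort=True):
        ns = knn_within_radius(sub, k=k, radius_um=radius_um)
        feats, iso = cn_features(ns, sub, cohort.type_vocab, include_index)
        frames.append(feats)
        isolated_idx.extend(sub.index[iso])
    features = pd.concat(frames).loc[lambda df: df.index.sort_values()]
    if isolated_idx:
        logger.warning("%d isolated cell(s) (no neighbor within %.0f um) excluded", len(isolated_idx), radius_um)
    return features, pd.Index(isolated_idx)


def cluster_cns(
    features: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_init: int = 10,
) -> CNModel:
    """K-means clustering of neighborhood compositions, pooled cohort-wide."""
    if k > len(features):
        raise ValueError(f"k = {k} exceeds the {len(features)} feature rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(features.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=features.columns)
    centroids = centroids.clip(lower=0.0)
    centroids = centroids.div(centroids.sum(axis=1), axis=0)
    return CNModel(
        k=k,
        centroids=centroids,
        labels=pd.Series(labels, index=features.index),
        seed=seed,
    )


_TUMOR_CN_NAME = {
    "epithelial tumor": "bulk tumor",
    "p53+ tumor": "p53+ tumor",
    "proliferative tumor": "proliferative tumor",
}
_IMMUNE_TYPES = ("proliferative immune", "macrophage", "B cell", "ILC/NK", "CD4+ T", "CD8+ T")


def annotate_cns(
    model: CNModel,
    rules: dict[int, str] | None = None,
    dominance: float = 0.4,
    immune_fraction: float = 0.25,
) -> CNModel:
    """Name each cluster from its centroid composition.

    Default rule: the dominant centroid type names the cluster — tumor
    subtypes map to "bulk tumor" / "p53+ tumor" / "proliferative tumor";
    stromal-dominant clusters with a summed immune fraction of at least
    ``immune_fraction`` become "immune-enriched stromal"; immune-dominant
    clusters become "<type> enriched"; clusters with no type reaching
    ``dominance`` become "mixed immune". A user rule table
    ``{cluster index: name}`` overrides individual clusters.
    """
    names: dict[int, str] = {}
    for ci in range(model.k):
        if rules and ci in rules:
            names[ci] = rules[ci]
            continue
        comp = model.centroids.iloc[ci]
        dom_type = comp.idxmax()
        dom_frac = float(comp.max())
        immune = float(comp[[t for t in _IMMUNE_TYPES if t in comp.index]].sum())
        if dom_frac < dominance:
            names[ci] = "mixed immune"
        elif dom_type in _TUMOR_CN_NAME:
            names[ci] = _TUMOR_CN_NAME[dom_type]
        elif dom_type == "stromal":
            names[ci] = "immune-enriched stromal" if immune >= immune_fraction else "stromal"
        else:
            names[ci] = f"{dom_type} enriched"
    # Deduplicate deterministically by cluster index.
    seen: dict[str, int] = {}
    for ci in sorted(names):
        base = names[ci]
        if base in seen:
            seen[base] += 1
            names[ci] = f"{base} ({seen[base]})"
        else:
            seen[base] = 1
    model.names = names
    return model


def cn_proportion_analyses(
    cohort: Cohort,
    model: CNModel,
    contrast: tuple[str, str, str],
    level: str = "roi",
    purity_covariate: bool = True,
    offset: float = 0.5,
):
    """CN proportions + moderated group test + patient-level correlogram.

    Delegates to :mod:`spatialtme.composition` with CN names as categories.
    Returns ``(ProportionMatrix, ModeratedTestResult | None,
    CorrelogramResult | None)``; tests are skipped with a warning when the
    CN labels are degenerate (a single class).
    """
    cn_labels = model.cn_of_cell
    pm = composition.proportions(cohort, level=level, labels=cn_labels)
    if pm.fractions.shape[1] < 2:
        logger.warning("only one CN class present; tests skipped")
        return pm, None, None
    y = composition.empirical_logit(pm, offset=offset)
    X, units, ci = composition.make_design(pm.meta, contrast, purity_covariate)
    y = y.loc[units]
    blocks = pm.meta.loc[units, "patient_id"].to_numpy()
    rho = composition.estimate_block_correlation(y, X, blocks)
    test = composition.moderated_group_test(y, X, ci, blocks, rho)
    pm_pat = composition.proportions(cohort, level="patient", labels=cn_labels)
    corr = (
        composition.spearman_correlogram(pm_pat.fractions)
        if len(pm_pat.fractions) >= 3
        else None
    )
    return pm, test, corr


def classify_tils(
    cells: pd.DataFrame,
    model: CNModel,
    tumor_cns: tuple[str, ...] = DEFAULT_TUMOR_CNS,
    stromal_cns: tuple[str, ...] = DEFAULT_STROMAL_CNS,
) -> TILTable:
    """Spatially classify lymphocytes into iTIL / sTIL by their CN.

    Lymphocytes in a tumor CN become iTILs; in a stromal CN, sTILs; every
    other cell — including lymphocytes in other CNs and all
    non-lymphocytes — is "none".
    """
    cn = model.cn_of_cell
    available = set(cn.dropna().unique())
    missing = (set(tumor_cns) | set(stromal_cns)) - available
    if missing == set(tumor_cns) | set(stromal_cns):
        raise ValueError(
            f"none of the configured CN names {sorted(missing)} exist; "
            f"available: {sorted(available)}"
        )
    cn_full = cn.reindex(cells.index)
    compartment = pd.Series("other", index=cells.index, dtype=object)
    compartment[cn_full.isin(tumor_cns)] = "tumor"
    compartment[cn_full.isin(stromal_cns)] = "stromal"
    compartment[cn_full.isna()] = np.nan  # isolated cells, outside every CN

    is_lymph = cells["cell_type"].isin(LYMPHOCYTE_TYPES)
    til = pd.Series("none", index=cells.index, dtype=object)
    til[is_lymph & (compartment == "tumor")] = "iTIL"
    til[is_lymph & (compartment == "stromal")] = "sTIL"
    return TILTable(til_class=til, compartment=compartment)


def til_proportions(
    tils: TILTable,
    cells: pd.DataFrame,
    level: str = "roi",
    denominator: str = "cells_in_compartment_cns",
) -> pd.DataFrame:
    """Per-unit iTIL and sTIL proportions.

    ``denominator`` conventions:

    * ``cells_in_compartment_cns`` (default) — iTILs over all cells in tumor
      CNs; sTILs over all cells in stromal CNs.
    * ``tumor_cells_in_tumor_cns`` — iTILs over tumor-type cells in tumor
      CNs; sTILs over stromal-type cells in stromal CNs.

    Units with an empty denominator get a missing value.
    """
    if denominator not in ("cells_in_compartment_cns", "tumor_cells_in_tumor_cns"):
        raise ValueError(f"unknown denominator convention: {denominator}")
    unit = cells["roi_id"] if level == "roi" else cells["patient_id"]
    df = pd.DataFrame(
        {
            "unit": unit,
            "til": tils.til_class,
            "compartment": tils.compartment,
            "cell_type": cells["cell_type"],
        }
    )
    rows = []
    for u, sub in df.groupby("unit", sort=True):
        rec: dict = {"unit": u}
        for comp, til_label, ref_types in (
            ("tumor", "iTIL", TUMOR_CELL_TYPES),
            ("stromal", "sTIL", ("stromal",)),
        ):
            in_comp = sub[sub["compartment"] == comp]
            n_til = int((in_comp["til"] == til_label).sum())
            if denominator == "cells_in_compartment_cns":
                denom = len(in_comp)
            else:
                denom = int(in_comp["cell_type"].isin(ref_types).sum())
            rec[f"{til_label}_proportion"] = n_til / denom if denom else np.nan
            rec[f"n_{til_label}"] = n_til
            rec[f"denom_{til_label}"] = denom
        rows.append(rec)
    return pd.DataFrame(rows).set_index("unit")


def otsu_split(
    values: pd.Series | np.ndarray, n_bins: int = 256
) -> tuple[float, pd.Series]:
    """Dichotomize values at the Otsu threshold (max between-class variance).

    The threshold is chosen on an ``n_bins`` equal-width histogram over the
    observed range; values strictly above it are labeled "high". Constant
    input has no valid split and raises.
    """
    s = pd.Series(values).astype(float).dropna()
    if s.nunique() < 2:
        raise ValueError("otsu_split requires >= 2 distinct values")
    thr = float(threshold_otsu(s.to_numpy(), nbins=n_bins))
    labels = pd.Series(np.where(s > thr, "high", "low"), index=s.index)
    return thr, labels


def survival_compare(
    clinical: pd.DataFrame,
    groups: pd.Series,
    fit_cox: bool = True,
    threshold: float | None = None,
) -> SurvivalResult:
    """Kaplan-Meier curves and log-rank test between two patient groups.

    ``groups`` maps patient_id to "high"/"low" (any two labels work). A
    proportional-hazards fit for the group indicator is attached when
    estimable; with zero events in a group the Cox fit is skipped with a
    warning but the log-rank test still runs.
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    joined = clin.loc[groups.index.intersection(clin.index)]
    g = groups.loc[joined.index]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"survival_compare needs exactly 2 groups, got {labels}")
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 patients")

    t = joined["os_time"].astype(float)
    e = joined["os_event"].astype(int)
    curves = {}
    for lab in labels:
        m = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=str(lab))
        ev = kmf.event_table
        curves[str(lab)] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(),
                "at_risk": ev["at_risk"].to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )

    m0 = g == labels[0]
    lr = logrank_test(t[m0], t[~m0], event_observed_A=e[m0], event_observed_B=e[~m0])

    hr = hr_ci = None
    if fit_cox:
        if (e[m0].sum() == 0) or (e[~m0].sum() == 0):
            logger.warning("a group has zero events; Cox fit skipped")
        else:
            try:
                cph = CoxPHFitter()
                frame = pd.DataFrame(
                    {"os_time": t, "os_event": e, "group": (g == labels[1]).astype(float)}
                )
                cph.fit(frame, duration_col="os_time", event_col="os_event")
                hr = float(np.exp(cph.params_["group"]))
                ci = cph.confidence_intervals_.loc["group"]
                hr_ci = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
            except Exception as exc:  # degenerate separation etc.
                logger.warning("Cox fit failed: %s", exc)

    return SurvivalResult(
        curves=curves,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hazard_ratio_ci=hr_ci,
        threshold=threshold,
    )
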