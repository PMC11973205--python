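"""Tier 1 — composition statistics on cell-type (or neighborhood) proportions.

Proportions are compared between patient groups on the empirical-logit scale
(a variance-stabilizing transform for count-derived fractions). Because the
unit of replication is the tissue region while the unit of inference is the
patient, the linear model treats patient as an exchangeable random block: a
common intra-patient correlation rho is estimated by REML and the group
contrast is fitted by generalized least squares under the block-exchangeable
covariance. Per-category residual variances are then shrunk toward a pooled
prior by the standard empirical-Bayes squeeze (a scaled inverse-chi-square
prior fitted by moment matching on log variances), giving moderated t
statistics with augmented degrees of freedom. Tumor purity enters as a fixed
covariate to absorb sampling-location bias. P values are Benjamini-Hochberg
adjusted within each comparison.

The same machinery is reused verbatim for cellular-neighborhood proportions
and (after a count-logit transform) for interaction scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from spatialtme.core_io import Cohort, TUMOR_CELL_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionMatrix",
    "ModeratedTestResult",
    "CorrelogramResult",
    "proportions",
    "empirical_logit",
    "make_design",
    "estimate_block_correlation",
    "moderated_group_test",
    "spearman_correlogram",
    "bh_adjust",
]

RHO_CAP = 0.99


@dataclass
class ProportionMatrix:
    """Units x categories fractions with parallel counts and unit metadata.

    ``fractions`` rows sum to 1; ``counts`` are the raw cell counts they were
    derived from; ``meta`` is indexed like the matrices and carries
    ``patient_id``, ``tumor_purity`` (if available) and condition labels.
    """

    fractions: pd.DataFrame
    counts: pd.DataFrame
    meta: pd.DataFrame
    level: str = "roi"

    def __post_init__(self) -> None:
        rowsum = self.fractions.sum(axis=1).to_numpy()
        if len(rowsum) and not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("ProportionMatrix rows must sum to 1")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass
class ModeratedTestResult:
    """Per-category moderated-t results plus the shared correlation estimate."""

    table: pd.DataFrame  # effect, t, df_residual, df_prior, p, p_adj per category
    rho: float
    df_prior: float
    s2_prior: float


@dataclass
class CorrelogramResult:
    """All pairwise Spearman correlations among categories."""

    rho: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at adjusted p <= 0.05


def proportions(
    cohort: Cohort,
    level: str = "roi",
    labels: pd.Series | None = None,
    categories: tuple[str, ...] | None = None,
) -> ProportionMatrix:
    """Per-unit category fractions at the region or patient level.

    Parameters
    ----------
    level : {"roi", "patient"}
        Patient level pools a patient's cells across all their regions before
        dividing (so regions with more cells weigh more).
    labels
        Per-cell category labels aligned with ``cohort.cells``; defaults to
        the ``cell_type`` column. Pass CN labels here for neighborhood
        proportions.
    categories
        Column order; defaults to the cohort vocabulary (for cell types) or
        the sorted label set.
    """
    if level not in ("roi", "patient"):
        raise ValueError("level must be 'roi' or 'patient'")
    cells = cohort.cells
    if labels is None:
        lab = cells["cell_type"]
        cats = tuple(categories) if categories is not None else cohort.type_vocab
    else:
        lab = labels.reindex(cells.index)
        cats = (
            tuple(categories)
            if categories is not None
            else tuple(sorted(lab.dropna().unique()))
        )
    unit_col = "roi_id" if level == "roi" else "patient_id"
    keep = lab.notna()
    counts = (
        pd.crosstab(cells.loc[keep, unit_col], lab[keep])
        .reindex(columns=list(cats), fill_value=0)
    )
    counts.index.name = unit_col
    counts.columns.name = None

    if level == "roi":
        all_units = cohort.rois["roi_id"]
    else:
        all_units = cohort.clinical["patient_id"]
    empty = sorted(set(all_units) - set(counts.index))
    if empty:
        logger.warning("%d empty unit(s) excluded from proportions: %s", len(empty), empty)
    totals = counts.sum(axis=1)
    zero_rows = totals == 0
    if zero_rows.any():
        logger.warning("%d unit(s) with no labeled cells excluded", int(zero_rows.sum()))
        counts = counts.loc[~zero_rows]
        totals = totals.loc[~zero_rows]
    fractions = counts.div(totals, axis=0)

    meta = _unit_meta(cohort, counts.index, level)
    return ProportionMatrix(fractions=fractions, counts=counts, meta=meta, level=level)


def _unit_meta(cohort: Cohort, units: pd.Index, level: str) -> pd.DataFrame:
    clin_cols = [c for c in ("msi_status", "recurrence", "sidedness") if c in cohort.clinical.columns]
    clin = cohort.clinical.set_index("patient_id")[clin_cols]
    if level == "roi":
        rois = cohort.rois.set_index("roi_id")
        meta = rois.reindex(units)[
            [c for c in ("patient_id", "tumor_purity") if c in rois.columns]
        ].copy()
        meta = meta.join(clin, on="patient_id")
    else:
        meta = pd.DataFrame(index=pd.Index(units, name=None))
        meta["patient_id"] = list(units)
        if "tumor_purity" in cohort.rois.columns:
            purity = cohort.rois.groupby("patient_id")["tumor_purity"].mean()
            meta["tumor_purity"] = purity.reindex(units).to_numpy()
        for c in clin.columns:
            meta[c] = clin[c].reindex(units).to_numpy()
    meta.index = units
    return meta


def tumor_purity_from_cells(cohort: Cohort) -> pd.Series:
    """Estimate per-ROI tumor purity as the fraction of tumor-compartment cells."""
    is_tumor = cohort.cells["cell_type"].isin(TUMOR_CELL_TYPES)
    return is_tumor.groupby(cohort.cells["roi_id"]).mean()


def empirical_logit(pm: ProportionMatrix, offset: float = 0.5) -> pd.DataFrame:
    """Variance-stabilized empirical logit of the count matrix.

    y = log((n + offset) / (N - n + offset)) with n the category count and N
    the unit total. The half-count offset keeps every value finite at the
    boundaries n = 0 and n = N.
    """
    counts = pm.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if offset <= 0 and ((counts == 0).any() or (counts == totals).any()):
        raise ValueError("offset must be positive when any count hits 0 or the unit total")
    y = np.log((counts + offset) / (totals - counts + offset))
    return pd.DataFrame(y, index=pm.counts.index, columns=pm.counts.columns)


def make_design(
    meta: pd.DataFrame,
    contrast: tuple[str, str, str],
    purity_covariate: bool = True,
) -> tuple[np.ndarray, pd.Index, int]:
    """Two-condition design matrix with optional tumor-purity covariate.

    ``contrast`` is ``(column, level_a, level_b)``; the returned coefficient
    of interest (index 1) is the mean difference level_a - level_b on the
    transformed scale. Units in neither level are excluded. Returns
    ``(X, kept_units, contrast_index)``.
    """
    col, a, b = contrast
    mask = meta[col].isin([a, b])
    sub = meta.loc[mask]
    ind = (sub[col] == a).astype(float).to_numpy()
    cols = [np.ones(len(sub)), ind]
    if purity_covariate and "tumor_purity" in sub.columns:
        purity = sub["tumor_purity"].astype(float)
        if purity.isna().any():
            logger.warning(
                "%d unit(s) missing tumor purity; mean-imputed for the covariate",
                int(purity.isna().sum()),
            )
            purity = purity.fillna(purity.mean())
        if purity.isna().all() or purity.nunique() <= 1:
            logger.warning("tumor purity constant or absent; covariate dropped")
        else:
            cols.append(purity.to_numpy() - purity.to_numpy().mean())
    X = np.column_stack(cols)
    return X, sub.index, 1


def _block_indices(blocks: np.ndarray) -> list[np.ndarray]:
    codes, _ = pd.factorize(blocks)
    return [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]


def _whiten(M: np.ndarray, block_idx: list[np.ndarray], rho: float) -> np.ndarray:
    """Multiply by C^{-1/2} for block-exchangeable correlation C(rho).

    Within a block of size m, C has eigenvalue 1+(m-1)rho on the mean
    direction and 1-rho on deviations, so whitening scales those components
    separately.
    """
    out = np.array(M, dtype=float, copy=True)
    two_d = out.ndim == 2
    for idx in block_idx:
        m = len(idx)
        if m == 1:
            continue
        sub = out[idx]
        mean = sub.mean(axis=0, keepdims=True) if two_d else sub.mean()
        dev = sub - mean
        out[idx] = dev / np.sqrt(1.0 - rho) + mean / np.sqrt(1.0 + (m - 1) * rho)
    return out


def _logdet_c(block_idx: list[np.ndarray], rho: float) -> float:
    ld = 0.0
    for idx in block_idx:
        m = len(idx)
        ld += np.log1p((m - 1) * rho) + (m - 1) * np.log1p(-rho)
    return ld


def _reml_neg_loglik(rho: float, y: np.ndarray, X: np.ndarray, block_idx) -> float:
    n, p = X.shape
    Xw = _whiten(X, block_idx, rho)
    yw = _whiten(y, block_idx, rho)
    xtx = Xw.T @ Xw
    sign, ld_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtx, Xw.T @ yw)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    if rss <= 0:
        rss = 1e-300
    return 0.5 * (_logdet_c(block_idx, rho) + ld_xtx + (n - p) * np.log(rss))


def estimate_block_correlation(
    y: pd.DataFrame,
    design: np.ndarray,
    blocks: np.ndarray | pd.Series,
) -> float:
    """Common intra-block (intra-patient) correlation of model residuals.

    For each category the exchangeable-block correlation is estimated by
    restricted maximum likelihood under a one-way random-block model on the
    residuals of the fixed-effects fit; per-category estimates are combined
    by averaging on the atanh scale. Returns a single rho in (-1, 1), capped
    at +/-0.99. With no block of size >= 2 there is no replicate information
    and rho = 0 is returned with a warning.
    """
    blocks = np.asarray(blocks)
    block_idx = _block_indices(blocks)
    sizes = np.array([len(i) for i in block_idx])
    if (sizes < 2).all():
        logger.warning("all blocks are singletons; returning rho = 0")
        return 0.0
    m_max = int(sizes.max())
    lo = max(-1.0 / (m_max - 1) + 1e-3, -RHO_CAP)
    Y = y.to_numpy(dtype=float)
    rhos = []
    for g in range(Y.shape[1]):
        yg = Y[:, g]
        if np.allclose(yg, yg[0]):
            continue  # constant category carries no correlation information
        res = minimize_scalar(
            _reml_neg_loglik,
            bounds=(lo, RHO_CAP),
            args=(yg, design, block_idx),
            method="bounded",
            options={"xatol": 1e-4},
        )
        rhos.append(float(np.clip(res.x, -RHO_CAP, RHO_CAP)))
    if not rhos:
        logger.warning("no informative categories; returning rho = 0")
        return 0.0
    return float(np.tanh(np.mean(np.arctanh(rhos))))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton iteration on the log scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_variances(
    s2: np.ndarray, df: np.ndarray, d0_cap: float = 500.0
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-category variances.

    Fits a scaled inverse-chi-square prior (d0, s0^2) by moment matching on
    log variances (mean/variance of log s^2 against their theoretical values
    under the hierarchical model) and returns posterior variances
    (d0 s0^2 + df s^2) / (d0 + df), d0, and s0^2. d0 is capped to avoid a
    degenerate fully-pooled fit.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = float(np.mean(e))
    ev = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df[ok] / 2.0)))
    if ev <= 0:
        d0 = d0_cap
    else:
        d0 = min(2.0 * _trigamma_inverse(ev), d0_cap)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, float(d0), s0_sq


def moderated_group_test(
    y: pd.DataFrame,
    design: np.ndarray,
    contrast_index: int = 1,
    blocks: np.ndarray | pd.Series | None = None,
    rho: float = 0.0,
    d0_cap: float = 500.0,
) -> ModeratedTestResult:
    """Moderated t-test of a group contrast per category.

    Each category is fitted by generalized least squares under the
    block-exchangeable correlation ``rho`` (plain least squares when rho = 0
    or blocks are singletons); residual variances are shrunk by
    :func:`squeeze_variances`; the moderated t uses df = prior + residual.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more units than design columns")
    if blocks is None or rho == 0.0:
        block_idx: list[np.ndarray] = []
    else:
        block_idx = _block_indices(np.asarray(blocks))
    Xw = _whiten(X, block_idx, rho) if block_idx else X

    # Guard against a singular design (e.g. constant purity): drop trailing
    # covariates until full rank, keeping intercept + contrast.
    while np.linalg.matrix_rank(Xw) < Xw.shape[1] and Xw.shape[1] > 2:
        logger.warning("singular design; dropping last covariate column")
        Xw = Xw[:, :-1]
        X = X[:, :-1]
    p = Xw.shape[1]

    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    hat = xtx_inv @ Xw.T
    u2 = float(xtx_inv[contrast_index, contrast_index])  # unscaled contrast variance

    Y = y.to_numpy(dtype=float)
    Yw = _whiten(Y, block_idx, rho) if block_idx else Y
    betas = hat @ Yw  # (p, G)
    resid = Yw - Xw @ betas
    df_res = float(n - p)
    s2 = (resid**2).sum(axis=0) / df_res
    post_s2, d0, s0_sq = squeeze_variances(s2, np.full(Y.shape[1], df_res), d0_cap)

    eff = betas[contrast_index]
    se = np.sqrt(u2 * post_s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, eff / np.where(se > 0, se, 1.0), np.where(eff == 0, 0.0, np.inf))
    df_total = df_res + d0
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.where(np.isfinite(t), pvals, 0.0)
    pvals = np.where((se == 0) & (eff == 0), 1.0, pvals)
    table = pd.DataFrame(
        {
            "effect": eff,
            "t": t,
            "df_residual": df_res,
            "df_prior": d0,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
        },
        index=y.columns,
    )
    return ModeratedTestResult(table=table, rho=float(rho), df_prior=d0, s2_prior=s0_sq)


def spearman_correlogram(
    fractions: pd.DataFrame,
    subset: np.ndarray | pd.Series | None = None,
    alpha: float = 0.05,
) -> CorrelogramResult:
    """All pairwise Spearman correlations between category columns.

    Constant columns have undefined correlations; their pairs are reported as
    missing and excluded from the BH family. Requires >= 3 units after
    subsetting.
    """
    F = fractions.loc[subset] if subset is not None else fractions
    if len(F) < 3:
        raise ValueError("spearman_correlogram requires >= 3 units")
    cats = list(F.columns)
    k = len(cats)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(rho, 1.0)
    const = F.nunique().to_numpy() <= 1
    flat_p, flat_ij = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if const[i] or const[j]:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, pv = stats.spearmanr(F.iloc[:, i], F.iloc[:, j])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
            flat_p.append(pv)
            flat_ij.append((i, j))
    p_adj = np.full((k, k), np.nan)
    if flat_p:
        adj = bh_adjust(np.array(flat_p))
        for (i, j), a in zip(flat_ij, adj):
            p_adj[i, j] = p_adj[j, i] = a
    sig = pd.DataFrame(
        np.where(np.isnan(p_adj), False, p_adj <= alpha), index=cats, columns=cats
    )
    return CorrelogramResult(
        rho=pd.DataFrame(rho, index=cats, columns=cats),
        p=pd.DataFrame(p, index=cats, columns=cats),
        p_adj=pd.DataFrame(p_adj, index=cats, columns=cats),
        significant=sig,
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
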