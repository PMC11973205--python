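"""Tier 2 — cell-cell interaction testing on contact graphs.

Two complementary statistics are computed per tissue region from the 6 um
contact graph:

* **Directed mean interactions** (histoCAT-style). For an ordered type pair
  (A, B), the number of A-side contact incidences with B divided by the
  number of A cells — "how many B neighbors does a typical A cell have". A
  homotypic contact is counted from both endpoints. Observed values are
  compared to a null built by shuffling type labels over the fixed contact
  graph (type counts preserved), with two one-tailed permutation tests:
  significantly more contact than expected = *interaction*, significantly
  less = *avoidance*. Cohort-level results are summarized as
  logFC = log2((regions with interaction + 1) / (regions with avoidance + 1)).

* **Interaction score**. For an unordered pair, the fraction of the region's
  contacts that join the two types. Being a proportion, scores from multiple
  regions of one patient can be tested between conditions with the same
  moderated GLS framework used for composition, treating regions as
  correlated replicates. Regions where either member type has fewer than 20
  cells are excluded for that pair to suppress small-count noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from spatialtme import composition
from spatialtme.spatial import AdjacencyList

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedInteractionMatrix",
    "InteractionClassification",
    "directed_matrix",
    "permutation_interaction_test",
    "cohort_logfc",
    "interaction_score",
    "interaction_score_table",
    "interaction_score_test",
]


@dataclass
class DirectedInteractionMatrix:
    """Per-region directed mean-interaction matrix M[A][B].

    ``mean`` is NaN on rows whose type is absent from the region; ``counts``
    holds raw contact incidences (homotypic contacts counted twice);
    ``type_counts`` the per-type cell counts.
    """

    roi_id: object
    mean: pd.DataFrame
    counts: pd.DataFrame
    type_counts: pd.Series


@dataclass
class InteractionClassification:
    """Permutation-test outcome for every ordered type pair in one region.

    ``label`` in {"interaction", "avoidance", "none"} (NaN for pairs with an
    absent type); ``p_high`` / ``p_low`` are the add-one one-tailed
    permutation p values for the more/less-contact alternatives.
    """

    roi_id: object
    label: pd.DataFrame
    p_high: pd.DataFrame
    p_low: pd.DataFrame
    observed: pd.DataFrame
    n_perm: int
    alpha: float

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a in self.label.index:
            for b in self.label.columns:
                rows.append(
                    {
                        "roi_id": self.roi_id,
                        "type_a": a,
                        "type_b": b,
                        "label": self.label.loc[a, b],
                        "p_high": self.p_high.loc[a, b],
                        "p_low": self.p_low.loc[a, b],
                        "mean_interaction": self.observed.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _codes(cell_types: pd.Series, vocab: tuple[str, ...]) -> np.ndarray:
    cat = pd.Categorical(cell_types, categories=list(vocab))
    if (cat.codes < 0).any():
        bad = set(cell_types) - set(vocab)
        raise ValueError(f"cell types outside vocabulary: {sorted(bad)}")
    return cat.codes.astype(np.intp)


def _incidence_counts(lab: np.ndarray, ei: np.ndarray, ej: np.ndarray, t: int) -> np.ndarray:
    """count[A, B] = contact incidences seen from A's side (homotypic twice)."""
    c = np.bincount(lab[ei] * t + lab[ej], minlength=t * t)
    c += np.bincount(lab[ej] * t + lab[ei], minlength=t * t)
    return c.reshape(t, t)


def directed_matrix(
    adj: AdjacencyList, cells: pd.DataFrame, vocab: tuple[str, ...]
) -> DirectedInteractionMatrix:
    """Directed mean-interaction matrix for one region.

    M[A][B] = (A-side incidences of A-B contacts) / (#A cells); rows of
    absent types are NaN.
    """
    t = len(vocab)
    lab = _codes(cells["cell_type"], vocab)
    if len(lab) != adj.n_cells:
        raise ValueError("adjacency and cell table disagree on region size")
    ei, ej = (adj.pairs[:, 0], adj.pairs[:, 1]) if adj.n_contacts else (np.empty(0, np.intp),) * 2
    counts = _incidence_counts(lab, ei, ej, t)
    n_type = np.bincount(lab, minlength=t).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = counts / n_type[:, None]
    mean[n_type == 0, :] = np.nan
    return DirectedInteractionMatrix(
        roi_id=adj.roi_id,
        mean=pd.DataFrame(mean, index=list(vocab), columns=list(vocab)),
        counts=pd.DataFrame(counts, index=list(vocab), columns=list(vocab)),
        type_counts=pd.Series(n_type.astype(int), index=list(vocab)),
    )


def permutation_interaction_test(
    cells: pd.DataFrame,
    adj: AdjacencyList,
    vocab: tuple[str, ...],
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
    batch: int = 250,
) -> InteractionClassification:
    """Label-shuffling interaction/avoidance test for one region.

    Type labels are permuted over the fixed contact graph (type counts
    preserved) ``n_perm`` times. For each ordered pair, add-one one-tailed
    p values are computed:

        p_high = (1 + #{perm: M_perm >= M_obs}) / (1 + n_perm)

    and analogously with <= for p_low. A pair is labeled *interaction* when
    p_high < alpha, *avoidance* when p_low < alpha; if both tails pass, the
    smaller p wins (a tie means no label). Pairs involving an absent type
    are left unlabeled (NaN).
    """
    if n_perm < 100:
        logger.warning("n_perm = %d is low; p values are coarse", n_perm)
    t = len(vocab)
    lab = _codes(cells["cell_type"], vocab)
    n = len(lab)
    rng = np.random.default_rng(seed)
    ei, ej = (adj.pairs[:, 0], adj.pairs[:, 1]) if adj.n_contacts else (np.empty(0, np.intp),) * 2
    obs = _incidence_counts(lab, ei, ej, t)
    n_type = np.bincount(lab, minlength=t)

    # Type counts are invariant under shuffling, so comparing raw incidence
    # counts is equivalent to comparing the per-cell means.
    ge = np.zeros((t, t), dtype=np.int64)
    le = np.zeros((t, t), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # b independent uniform permutations of the label vector.
        perm = np.argsort(rng.random((b, n)), axis=1)
        L = lab[perm]
        li, lj = L[:, ei], L[:, ej]
        offs = (np.arange(b) * (t * t))[:, None]
        flat = np.concatenate([(li * t + lj + offs).ravel(), (lj * t + li + offs).ravel()])
        cnt = np.bincount(flat, minlength=b * t * t).reshape(b, t, t)
        ge += (cnt >= obs).sum(axis=0)
        le += (cnt <= obs).sum(axis=0)
        done += b

    p_high = (1.0 + ge) / (1.0 + n_perm)
    p_low = (1.0 + le) / (1.0 + n_perm)
    present = n_type > 0
    defined = present[:, None] & present[None, :]

    label = np.full((t, t), "none", dtype=object)
    hi = p_high < alpha
    lo = p_low < alpha
    label[hi & ~lo] = "interaction"
    label[lo & ~hi] = "avoidance"
    both = hi & lo
    label[both & (p_high < p_low)] = "interaction"
    label[both & (p_low < p_high)] = "avoidance"
    label[~defined] = np.nan
    ph = np.where(defined, p_high, np.nan)
    pl = np.where(defined, p_low, np.nan)
    with np.errstate(invalid="ignore"):
        mean_obs = np.where(defined, obs / np.maximum(n_type[:, None], 1), np.nan)

    idx = list(vocab)
    return InteractionClassification(
        roi_id=adj.roi_id,
        label=pd.DataFrame(label, index=idx, columns=idx),
        p_high=pd.DataFrame(ph, index=idx, columns=idx),
        p_low=pd.DataFrame(pl, index=idx, columns=idx),
        observed=pd.DataFrame(mean_obs, index=idx, columns=idx),
        n_perm=n_perm,
        alpha=alpha,
    )


def cohort_logfc(classifications: list[InteractionClassification]) -> pd.DataFrame:
    """Cohort summary: per ordered pair, interacting vs avoiding region counts.

    logFC = log2((n_interaction + 1) / (n_avoidance + 1)); the add-one
    smoothing keeps the summary finite and maps equal counts — including the
    empty case — to exactly 0.
    """
    if not classifications:
        raise ValueError("cohort_logfc requires >= 1 region classification")
    vocab = list(classifications[0].label.index)
    n_int = np.zeros((len(vocab), len(vocab)), dtype=int)
    n_avoid = np.zeros_like(n_int)
    for cl in classifications:
        lab = cl.label.to_numpy()
        n_int += lab == "interaction"
        n_avoid += lab == "avoidance"
    rows = []
    for i, a in enumerate(vocab):
        for j, b in enumerate(vocab):
            rows.append(
                {
                    "type_a": a,
                    "type_b": b,
                    "n_interaction": n_int[i, j],
                    "n_avoidance": n_avoid[i, j],
                    "logfc": np.log2((n_int[i, j] + 1.0) / (n_avoid[i, j] + 1.0)),
                }
            )
    return pd.DataFrame(rows)


def _pair_contact_counts(
    adj: AdjacencyList, lab: np.ndarray, t: int
) -> np.ndarray:
    """Unordered pair contact counts: symmetric matrix, each contact once."""
    c = np.zeros((t, t), dtype=np.int64)
    if adj.n_contacts:
        a = lab[adj.pairs[:, 0]]
        b = lab[adj.pairs[:, 1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        np.add.at(c, (lo, hi), 1)
    return c


def interaction_score(
    adj: AdjacencyList,
    cells: pd.DataFrame,
    pair: tuple[str, str],
    vocab: tuple[str, ...],
    min_cells: int = 20,
) -> float | None:
    """Interaction score for one unordered pair in one region.

    score = (#contacts joining the two types) / (#all contacts). Returns
    ``None`` (region excluded) when either member type has fewer than
    ``min_cells`` cells or the region has no contacts at all.
    """
    table = interaction_score_table([(adj, cells)], vocab, min_cells=min_cells)
    a, b = sorted(pair)
    row = table[(table["type_a"] == a) & (table["type_b"] == b)]
    if row.empty or not bool(row["included"].iloc[0]):
        return None
    return float(row["score"].iloc[0])


def interaction_score_table(
    regions: list[tuple[AdjacencyList, pd.DataFrame]],
    vocab: tuple[str, ...],
    min_cells: int = 20,
) -> pd.DataFrame:
    """Per-region interaction scores for every unordered type pair.

    Columns: roi_id, type_a, type_b (sorted), n_pair_contacts,
    n_total_contacts, score, included. Within an included region the scores
    over all pairs (homotypic included) sum to 1. A region is excluded for a
    pair when either member type has fewer than ``min_cells`` cells, and for
    all pairs when it has no contacts.
    """
    t = len(vocab)
    rows = []
    for adj, cells in regions:
        lab = _codes(cells["cell_type"], vocab)
        n_type = np.bincount(lab, minlength=t)
        c = _pair_contact_counts(adj, lab, t)
        total = int(c.sum())
        for i in range(t):
            for j in range(i, t):
                n_pair = int(c[i, j])
                included = (
                    total > 0 and n_type[i] >= min_cells and n_type[j] >= min_cells
                )
                if total > 0 and not included:
                    logger.debug(
                        "region %s excluded for pair (%s, %s): type counts %d, %d",
                        adj.roi_id, vocab[i], vocab[j], n_type[i], n_type[j],
                    )
                a_name, b_name = sorted((vocab[i], vocab[j]))
                rows.append(
                    {
                        "roi_id": adj.roi_id,
                        "type_a": a_name,
                        "type_b": b_name,
                        "n_pair_contacts": n_pair,
                        "n_total_contacts": total,
                        "score": n_pair / total if total else np.nan,
                        "included": included,
                    }
                )
    return pd.DataFrame(rows)


def interaction_score_test(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str, str],
    pairs: list[tuple[str, str]] | None = None,
    purity_covariate: bool = False,
    offset: float = 0.5,
) -> composition.ModeratedTestResult:
    """Condition test of interaction scores across regions.

    Scores are logit-transformed on the contact counts,
    y = log((n_pair + offset) / (n_total - n_pair + offset)), then fitted
    with the moderated GLS framework of :mod:`spatialtme.composition`
    (patient as random block, empirical-Bayes variance squeeze), BH-adjusted
    across the tested pair set.

    Parameters
    ----------
    scores
        Long table from :func:`interaction_score_table`.
    meta
        Region metadata indexed by roi_id with ``patient_id``, condition
        columns, and optionally ``tumor_purity``.
    pairs
        Unordered type pairs to test; defaults to all pairs that survive
        inclusion in >= 2 regions per arm.
    """
    inc = scores[scores["included"]].copy()
    inc["pair"] = inc["type_a"] + " | " + inc["type_b"]
    if pairs is not None:
        keys = {" | ".join(sorted(p)) for p in pairs}
        inc = inc[inc["pair"].isin(keys)]
    if inc.empty:
        raise ValueError("no included region/pair observations to test")
    y_long = np.log(
        (inc["n_pair_contacts"] + offset)
        / (inc["n_total_contacts"] - inc["n_pair_contacts"] + offset)
    )
    wide = inc.assign(y=y_long).pivot_table(index="roi_id", columns="pair", values="y")

    col, a, b = contrast
    meta_w = meta.reindex(wide.index)
    cond = meta_w[col]
    # Drop pairs lacking >= 2 included regions in either arm.
    keep_cols = []
    for pair_name in wide.columns:
        have = wide[pair_name].notna()
        n_a = int((have & (cond == a)).sum())
        n_b = int((have & (cond == b)).sum())
        if n_a >= 2 and n_b >= 2:
            keep_cols.append(pair_name)
        else:
            logger.warning("pair %r dropped: %d/%d included regions per arm", pair_name, n_a, n_b)
    if not keep_cols:
        raise ValueError("no pair has >= 2 included regions in both arms")
    wide = wide[keep_cols]

    # Exclusions are pair-specific, so each pair is fitted on its own
    # included-region subset; the intra-patient correlation is pooled across
    # pairs (atanh average) and the variance squeeze is shared.
    X_all, units, ci = composition.make_design(meta_w, contrast, purity_covariate)
    wide = wide.loc[units]
    blocks_all = meta.reindex(units)["patient_id"]
    pos = {u: i for i, u in enumerate(units)}

    rhos = []
    fits = []  # (pair, beta, u2, s2, df)
    for pair_name in wide.columns:
        sub = wide[pair_name].dropna()
        rows = np.array([pos[u] for u in sub.index])
        Xp = X_all[rows]
        bp = blocks_all.iloc[rows].to_numpy()
        if len(sub) <= Xp.shape[1]:
            logger.warning("pair %r dropped: too few regions for the design", pair_name)
            continue
        rho_p = composition.estimate_block_correlation(sub.to_frame(), Xp, bp)
        rhos.append(rho_p)
        fits.append((pair_name, sub, rows, bp))
    if not fits:
        raise ValueError("no pair has enough included regions to fit")
    rho = float(np.tanh(np.mean(np.arctanh(np.clip(rhos, -0.99, 0.99)))))

    names, effs, u2s, s2s, dfs = [], [], [], [], []
    for pair_name, sub, rows, bp in fits:
        Xp = X_all[rows]
        bidx = composition._block_indices(bp)
        Xw = composition._whiten(Xp, bidx, rho)
        yw = composition._whiten(sub.to_numpy(), bidx, rho)
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        beta = xtx_inv @ Xw.T @ yw
        resid = yw - Xw @ beta
        df = len(sub) - Xp.shape[1]
        names.append(pair_name)
        effs.append(float(beta[ci]))
        u2s.append(float(xtx_inv[ci, ci]))
        s2s.append(float((resid**2).sum() / df))
        dfs.append(float(df))
    s2 = np.array(s2s)
    df = np.array(dfs)
    post_s2, d0, s0_sq = composition.squeeze_variances(s2, df)
    eff = np.array(effs)
    se = np.sqrt(np.array(u2s) * post_s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, eff / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df + d0)
    table = pd.DataFrame(
        {
            "effect": eff,
            "t": t,
            "df_residual": df,
            "df_prior": d0,
            "p": pvals,
            "p_adj": composition.bh_adjust(pvals),
        },
        index=pd.Index(names, name="pair"),
    )
    return composition.ModeratedTestResult(table=table, rho=rho, df_prior=d0, s2_prior=s0_sq)
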