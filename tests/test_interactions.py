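import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from spatialtme import interactions as ia
from spatialtme.simulate import ArmSpec, AttractionSpec, SimulationConfig, simulate_cohort
from spatialtme.spatial import AdjacencyList, contact_pairs

from conftest import csr_cells, make_cells

logging.getLogger("spatialtme").setLevel(logging.ERROR)

VOCAB = ("A", "B")


def adj_from_edges(edges, n, roi_id="R1"):
    pairs = np.array(sorted(tuple(sorted(e)) for e in edges), dtype=np.intp)
    if len(pairs) == 0:
        pairs = np.empty((0, 2), dtype=np.intp)
    return AdjacencyList(
        roi_id=roi_id,
        pairs=pairs,
        border_um=np.zeros(len(pairs)),
        cell_ids=np.arange(n),
        threshold_um=6.0,
    )


def cells_with_types(types, roi_id="R1"):
    return make_cells(
        [(i, float(i), 0.0, t) for i, t in enumerate(types)], roi_id=roi_id
    )


# ------------------------------------------------------- directed matrix
def test_directed_matrix_heterotypic_convention():
    # one A (cell 0) contacting two B (cells 1, 2)
    cells = cells_with_types(["A", "B", "B"])
    adj = adj_from_edges([(0, 1), (0, 2)], 3)
    m = ia.directed_matrix(adj, cells, VOCAB)
    assert m.mean.loc["A", "B"] == pytest.approx(2.0)  # 2 incidences / 1 A
    assert m.mean.loc["B", "A"] == pytest.approx(1.0)  # 2 incidences / 2 B


def test_directed_matrix_homotypic_double_count():
    cells = cells_with_types(["B", "B"])
    adj = adj_from_edges([(0, 1)], 2)
    m = ia.directed_matrix(adj, cells, VOCAB)
    assert m.mean.loc["B", "B"] == pytest.approx(1.0)  # 2 incidences / 2 B
    assert np.isnan(m.mean.loc["A", "B"])  # absent type row


def test_directed_matrix_no_contacts():
    cells = cells_with_types(["A", "B"])
    adj = adj_from_edges([], 2)
    m = ia.directed_matrix(adj, cells, VOCAB)
    assert m.mean.loc["A", "B"] == 0.0


# ---------------------------------------------------- permutation test
def exhaustive_pvalues(types, edges, vocab):
    """Oracle: exact permutation tails by enumerating all label orderings."""
    n = len(types)
    t = len(vocab)
    code = {v: i for i, v in enumerate(vocab)}
    lab0 = np.array([code[x] for x in types])

    def counts(lab):
        c = np.zeros((t, t), dtype=int)
        for i, j in edges:
            c[lab[i], lab[j]] += 1
            c[lab[j], lab[i]] += 1
        return c

    obs = counts(lab0)
    ge = np.zeros((t, t))
    le = np.zeros((t, t))
    total = 0
    for perm in itertools.permutations(range(n)):
        c = counts(lab0[list(perm)])
        ge += c >= obs
        le += c <= obs
        total += 1
    return ge / total, le / total


def test_permutation_p_matches_exhaustive_enumeration():
    """Sampled add-one p values converge to the exact permutation tails."""
    types = ["A", "A", "B", "B"]
    edges = [(0, 1), (1, 2), (2, 3)]  # fixed path graph
    cells = cells_with_types(types)
    adj = adj_from_edges(edges, 4)
    n_perm = 20000
    cl = ia.permutation_interaction_test(cells, adj, VOCAB, n_perm=n_perm, seed=3)
    ge_exact, le_exact = exhaustive_pvalues(types, edges, VOCAB)
    for i, a in enumerate(VOCAB):
        for b_i, b in enumerate(VOCAB):
            # add-one estimate vs exact tail: 4 MC standard errors
            se = np.sqrt(ge_exact[i, b_i] * (1 - ge_exact[i, b_i]) / n_perm) + 1e-4
            assert abs(cl.p_high.loc[a, b] - ge_exact[i, b_i]) < 4 * se + 1 / n_perm
            se = np.sqrt(le_exact[i, b_i] * (1 - le_exact[i, b_i]) / n_perm) + 1e-4
            assert abs(cl.p_low.loc[a, b] - le_exact[i, b_i]) < 4 * se + 1 / n_perm


def test_single_type_region_unlabeled():
    cells = cells_with_types(["A", "A", "A"])
    adj = adj_from_edges([(0, 1), (1, 2)], 3)
    cl = ia.permutation_interaction_test(cells, adj, VOCAB, n_perm=200, seed=0)
    assert pd.isna(cl.label.loc["A", "B"])  # heterotypic undefined
    # homotypic statistic is shuffle-invariant -> p = 1, label none
    assert cl.p_high.loc["A", "A"] == pytest.approx(1.0)
    assert cl.label.loc["A", "A"] == "none"


def test_permutation_statistic_depends_only_on_label_multiset():
    """Shuffled labels on a fixed graph leave the null distribution intact:
    the observed count for the shuffled data is itself a draw from the null."""
    rng = np.random.default_rng(8)
    cells = csr_cells(rng, n=60, width=80.0, types=VOCAB, probs=(0.6, 0.4))
    adj = contact_pairs(cells)
    from spatialtme.simulate import simulate_null_labels

    shuffled = simulate_null_labels(cells, seed=4)
    cl = ia.permutation_interaction_test(shuffled, adj, VOCAB, n_perm=500, seed=5)
    # p values for shuffled data should be unremarkable (not extreme)
    assert cl.p_high.loc["A", "B"] > 0.01
    assert cl.p_low.loc["A", "B"] > 0.01


# --------------------------------------------------------------- logFC
def _classification_with(labels_ab, roi_ids):
    out = []
    for lab, roi in zip(labels_ab, roi_ids):
        m = pd.DataFrame(
            [["none", lab], [lab, "none"]], index=list(VOCAB), columns=list(VOCAB)
        )
        nan = pd.DataFrame(np.nan, index=list(VOCAB), columns=list(VOCAB))
        out.append(
            ia.InteractionClassification(
                roi_id=roi, label=m, p_high=nan, p_low=nan,
                observed=nan, n_perm=1000, alpha=0.01,
            )
        )
    return out


def test_logfc_equal_counts_is_zero():
    labels = ["interaction"] * 5 + ["avoidance"] * 5
    lf = ia.cohort_logfc(_classification_with(labels, range(10)))
    row = lf[(lf.type_a == "A") & (lf.type_b == "B")].iloc[0]
    assert row["logfc"] == 0.0


def test_logfc_smoothing():
    labels = ["interaction"] * 10
    lf = ia.cohort_logfc(_classification_with(labels, range(10)))
    row = lf[(lf.type_a == "A") & (lf.type_b == "B")].iloc[0]
    assert row["logfc"] == pytest.approx(np.log2(11.0))
    empty = ia.cohort_logfc(_classification_with(["none"], ["r"]))
    assert (empty["logfc"] == 0.0).all()


# --------------------------------------------------------------- scores
def test_interaction_score_formula():
    # contacts: A-B x2, B-B x1
    cells = cells_with_types(["A", "B", "B", "B"])
    adj = adj_from_edges([(0, 1), (0, 2), (1, 2)], 4)
    score = ia.interaction_score(adj, cells, ("A", "B"), VOCAB, min_cells=1)
    assert score == pytest.approx(2 / 3)
    assert ia.interaction_score(adj, cells, ("B", "B"), VOCAB, min_cells=1) == pytest.approx(1 / 3)


def test_interaction_score_min_cell_filter():
    cells = cells_with_types(["A"] * 19 + ["B"] * 25)
    adj = adj_from_edges([(0, 20), (1, 21)], 44)
    assert ia.interaction_score(adj, cells, ("A", "B"), VOCAB, min_cells=20) is None
    assert ia.interaction_score(adj, cells, ("A", "B"), VOCAB, min_cells=19) == 1.0


def test_scores_sum_to_one_per_region():
    rng = np.random.default_rng(11)
    cells = csr_cells(rng, n=150, width=120.0)
    adj = contact_pairs(cells)
    table = ia.interaction_score_table([(adj, cells)], ("A", "B", "C"), min_cells=1)
    assert table["score"].sum() == pytest.approx(1.0)


def test_score_monotone_in_attraction_strength():
    """Imposed attraction strength gives a monotone median interaction score."""
    props = {
        "epithelial tumor": 0.25, "p53+ tumor": 0.02, "proliferative tumor": 0.02,
        "stromal": 0.35, "proliferative immune": 0.01, "macrophage": 0.08,
        "B cell": 0.04, "ILC/NK": 0.03, "CD4+ T": 0.12, "CD8+ T": 0.08,
    }
    medians = []
    for s in (0.0, 1.0, 3.0):
        scores = []
        for rep in range(10):
            cfg = SimulationConfig(
                arms=[ArmSpec("MSS", 1, proportions=props)],
                rois_per_patient=(1, 1), roi_width_um=300.0, roi_height_um=300.0,
                cells_per_roi=(400, 400), dirichlet_concentration=None,
                attractions=[AttractionSpec("stromal", "CD4+ T", s)],
                seed=1000 + rep,
            )
            cohort, _ = simulate_cohort(cfg)
            sub = cohort.cells.reset_index(drop=True)
            adj = contact_pairs(sub)
            scores.append(
                ia.interaction_score(adj, sub, ("CD4+ T", "stromal"), cohort.type_vocab)
            )
        medians.append(np.median(scores))
    assert medians[0] <= medians[1] <= medians[2]
    assert medians[2] > medians[0]


def test_score_test_null_contract(sim_cohort):
    """With both arms from the same generator, no pair should be strongly
    flagged beyond the nominal rate."""
    cohort, _ = sim_cohort
    regions = []
    for _, sub in cohort.iter_rois():
        sub = sub.reset_index(drop=True)
        regions.append((contact_pairs(sub), sub))
    table = ia.interaction_score_table(regions, cohort.type_vocab)
    meta = cohort.rois.set_index("roi_id").join(
        cohort.clinical.set_index("patient_id")[["msi_status"]], on="patient_id"
    )
    # assign arms at random within the same generator output
    rng = np.random.default_rng(0)
    pats = cohort.clinical["patient_id"].to_numpy()
    fake = dict(zip(pats, rng.permutation(["X"] * 4 + ["Y"] * 4)))
    meta["arm"] = meta["patient_id"].map(fake)
    res = ia.interaction_score_test(table, meta, ("arm", "X", "Y"))
    assert (res.table["p_adj"] <= 0.05).mean() <= 0.1


def test_score_test_single_pair_bh_identity(sim_cohort):
    cohort, _ = sim_cohort
    regions = []
    for _, sub in cohort.iter_rois():
        sub = sub.reset_index(drop=True)
        regions.append((contact_pairs(sub), sub))
    table = ia.interaction_score_table(regions, cohort.type_vocab)
    meta = cohort.rois.set_index("roi_id").join(
        cohort.clinical.set_index("patient_id")[["msi_status"]], on="patient_id"
    )
    res = ia.interaction_score_test(
        table, meta, ("msi_status", "MSI-H", "MSS"),
        pairs=[("stromal", "CD4+ T")],
    )
    assert len(res.table) == 1
    assert res.table["p_adj"].iloc[0] == pytest.approx(res.table["p"].iloc[0])
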