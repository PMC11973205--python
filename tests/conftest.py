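import logging

import numpy as np
import pandas as pd
import pytest

from spatialtme.core_io import Cohort
from spatialtme.simulate import ArmSpec, SimulationConfig, simulate_cohort

logging.getLogger("spatialtme").setLevel(logging.ERROR)

VOCAB3 = ("A", "B", "C")


def make_cells(rows, roi_id="R1", patient_id="P1"):
    """Build a cell table from (cell_id, x, y, type[, radius]) tuples."""
    recs = []
    for r in rows:
        rec = {
            "cell_id": r[0],
            "roi_id": roi_id,
            "patient_id": patient_id,
            "x_um": float(r[1]),
            "y_um": float(r[2]),
            "cell_type": r[3],
        }
        if len(r) > 4:
            rec["radius_um"] = float(r[4])
        recs.append(rec)
    return pd.DataFrame(recs)


def make_cohort(cells, vocab=VOCAB3, purity=None):
    """Wrap a cell table in a minimal validated Cohort."""
    rois = (
        cells.groupby("roi_id")
        .agg(patient_id=("patient_id", "first"))
        .reset_index()
        .assign(width_um=1000.0, height_um=1000.0)
    )
    if purity is not None:
        rois["tumor_purity"] = purity
    clinical = pd.DataFrame(
        {
            "patient_id": sorted(cells["patient_id"].unique()),
            "msi_status": "unknown",
            "recurrence": "unknown",
            "os_time": 10.0,
            "os_event": 0,
        }
    )
    return Cohort(cells=cells, rois=rois, clinical=clinical, type_vocab=vocab)


def csr_cells(rng, n=200, width=160.0, types=VOCAB3, probs=(0.5, 0.3, 0.2), roi_id="R1"):
    """Completely-spatially-random region: uniform coordinates, random labels."""
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "roi_id": roi_id,
            "patient_id": "P1",
            "x_um": rng.uniform(0, width, n),
            "y_um": rng.uniform(0, width, n),
            "cell_type": rng.choice(list(types), n, p=list(probs)),
        }
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """A small two-arm niche-structured cohort reused across tests."""
    cfg = SimulationConfig(seed=7)
    cfg.arms[0].n_patients = 4
    cfg.arms[1].n_patients = 4
    cfg.rois_per_patient = (2, 2)
    # keep the default ~0.008 cells/um^2 density at a smaller region size
    cfg.roi_width_um = cfg.roi_height_um = 250.0
    cfg.cells_per_roi = (450, 550)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth
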