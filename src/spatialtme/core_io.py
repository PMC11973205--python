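"""Shared data model, tabular I/O, and cohort validation.

The pipeline's universal input is a *cell table*: one row per segmented cell
with planar coordinates in micrometres, a region-of-interest (ROI) identifier,
a patient identifier, and a cell-type label from a fixed vocabulary. Region
metadata (extent, tumor purity) and per-patient clinical annotations (MSI
status, recurrence, overall survival) ride alongside in two smaller tables.

Coordinate convention: micrometres, origin at the region's top-left corner,
y increasing downward (image convention).

Cell geometry: contact rules downstream are defined between cell *borders*.
When per-cell boundaries are unavailable each cell is modeled as a disc of its
stated radius; absent a radius column, a configured default radius is used
(5 um, about the size of a tightly packed epithelial cell section).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default cell-type vocabulary: three tumor compartment classes, a stromal
#: (fibroblast) class, and six immune classes.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "epithelial tumor",
    "p53+ tumor",
    "proliferative tumor",
    "stromal",
    "proliferative immune",
    "macrophage",
    "B cell",
    "ILC/NK",
    "CD4+ T",
    "CD8+ T",
)

#: Lymphocyte classes eligible for TIL (tumor-infiltrating lymphocyte) labels.
LYMPHOCYTE_TYPES: tuple[str, ...] = ("CD4+ T", "CD8+ T", "B cell")

#: Tumor-compartment cell types (used for tumor purity and TIL denominators).
TUMOR_CELL_TYPES: tuple[str, ...] = (
    "epithelial tumor",
    "p53+ tumor",
    "proliferative tumor",
)

#: Fallback equivalent-disc radius in um when no radius column is provided.
DEFAULT_CELL_RADIUS_UM: float = 5.0

CELL_COLUMNS = ("cell_id", "roi_id", "patient_id", "x_um", "y_um", "cell_type")
ROI_COLUMNS = ("roi_id", "patient_id", "width_um", "height_um")
CLINICAL_COLUMNS = ("patient_id", "msi_status", "recurrence", "os_time", "os_event")


class FormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class IntegrityError(ValueError):
    """Cross-table references or uniqueness constraints are violated."""


@dataclass
class Cohort:
    """A validated bundle of cell, ROI, and clinical tables.

    Attributes
    ----------
    cells : pandas.DataFrame
        Columns ``cell_id, roi_id, patient_id, x_um, y_um, cell_type`` plus
        optional ``radius_um`` and ``marker_*`` intensity columns.
    rois : pandas.DataFrame
        Columns ``roi_id, patient_id, width_um, height_um`` plus optional
        ``tumor_purity``.
    clinical : pandas.DataFrame
        Columns ``patient_id, msi_status, recurrence, os_time, os_event``
        plus optional ``sidedness``.
    type_vocab : tuple of str
        The cell-type vocabulary every ``cell_type`` value is drawn from.
    """

    cells: pd.DataFrame
    rois: pd.DataFrame
    clinical: pd.DataFrame
    type_vocab: tuple[str, ...] = DEFAULT_CELL_TYPES

    def __post_init__(self) -> None:
        self.type_vocab = tuple(self.type_vocab)
        validate_cohort(self)

    def radii(self, default: float = DEFAULT_CELL_RADIUS_UM) -> pd.Series:
        """Per-cell disc radius in um, filling in the default where absent."""
        if "radius_um" in self.cells.columns:
            r = self.cells["radius_um"].astype(float)
            return r.fillna(default)
        return pd.Series(default, index=self.cells.index, dtype=float)

    def iter_rois(self):
        """Yield ``(roi_id, cell sub-table)`` pairs in stable ROI order."""
        for roi_id, sub in self.cells.groupby("roi_id", sort=True):
            yield roi_id, sub


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{table} table is missing required column(s): {', '.join(missing)}")


def validate_cohort(cohort: Cohort) -> None:
    """Enforce every structural invariant of the data model.

    Raises :class:`FormatError` for malformed fields and
    :class:`IntegrityError` for broken cross-references or duplicates.
    """
    cells, rois, clinical = cohort.cells, cohort.rois, cohort.clinical
    _require_columns(cells, CELL_COLUMNS, "cell")
    _require_columns(rois, ROI_COLUMNS, "ROI")
    _require_columns(clinical, CLINICAL_COLUMNS, "clinical")

    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
        raise FormatError(f"non-finite coordinate in cell table at row {bad + 2}")
    if "radius_um" in cells.columns:
        r = cells["radius_um"].astype(float)
        if (r.dropna() <= 0).any():
            raise FormatError("radius_um must be > 0 where present")

    unknown = set(cells["cell_type"].unique()) - set(cohort.type_vocab)
    if unknown:
        raise FormatError(
            f"cell_type value(s) outside the configured vocabulary: {sorted(unknown)}"
        )

    dup = cells.duplicated(subset=["roi_id", "cell_id"])
    if dup.any():
        row = cells.loc[dup, ["roi_id", "cell_id"]].iloc[0]
        raise IntegrityError(
            f"duplicate (roi_id, cell_id) = ({row['roi_id']}, {row['cell_id']})"
        )
    if rois["roi_id"].duplicated().any():
        raise IntegrityError("duplicate roi_id in ROI table")
    if clinical["patient_id"].duplicated().any():
        raise IntegrityError("duplicate patient_id in clinical table")

    if (rois["width_um"].astype(float) <= 0).any() or (
        rois["height_um"].astype(float) <= 0
    ).any():
        raise FormatError("ROI width_um and height_um must be > 0")
    if "tumor_purity" in rois.columns:
        purity = rois["tumor_purity"].astype(float).dropna()
        if ((purity < 0) | (purity > 1)).any():
            raise FormatError("tumor_purity must lie in [0, 1]")

    os_time = clinical["os_time"].astype(float)
    if (os_time < 0).any():
        raise FormatError("os_time must be nonnegative")
    if not clinical["os_event"].isin([0, 1]).all():
        raise FormatError("os_event must be 0 (censored) or 1 (death)")

    orphan_cells = set(cells["roi_id"]) - set(rois["roi_id"])
    if orphan_cells:
        raise IntegrityError(f"cell roi_id(s) absent from ROI table: {sorted(orphan_cells)}")
    orphan_rois = set(rois["patient_id"]) - set(clinical["patient_id"])
    if orphan_rois:
        raise IntegrityError(
            f"ROI patient_id(s) absent from clinical table: {sorted(orphan_rois)}"
        )


def _read_csv(path: str | Path, table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"could not parse {table} table {path}: {exc}") from exc


def load_cohort(
    cell_path: str | Path,
    roi_path: str | Path,
    clinical_path: str | Path,
    type_vocab: Sequence[str] = DEFAULT_CELL_TYPES,
    type_remap: Mapping[str, str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read and validate a cohort from three CSV files.

    Parameters
    ----------
    cell_path, roi_path, clinical_path
        CSV files with the columns documented on :class:`Cohort`.
    type_vocab
        Allowed cell-type labels. Rows whose label is outside the vocabulary
        are rejected unless ``type_remap`` maps them onto it.
    type_remap
        Optional mapping from source labels to canonical vocabulary labels,
        e.g. ``{"Tcell": "CD4+ T"}``.
    column_map
        Optional mapping from source column names to the canonical names
        (deposited tables rarely agree on headers), e.g.
        ``{"X_position": "x_um"}``. Applied to all three tables.
    """
    cells = _read_csv(cell_path, "cell")
    rois = _read_csv(roi_path, "ROI")
    clinical = _read_csv(clinical_path, "clinical")
    if column_map:
        cells = cells.rename(columns=dict(column_map))
        rois = rois.rename(columns=dict(column_map))
        clinical = clinical.rename(columns=dict(column_map))

    _require_columns(cells, CELL_COLUMNS, "cell")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(cells[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise FormatError(f"cell table: missing or non-numeric {col} at row {bad[0] + 2}")
        cells[col] = vals

    if type_remap:
        cells["cell_type"] = cells["cell_type"].replace(dict(type_remap))

    # Unknown clinical fields become the literal category "unknown"; rows are
    # never dropped here — comparisons subset explicitly later.
    for col in ("msi_status", "recurrence"):
        if col in clinical.columns:
            clinical[col] = clinical[col].fillna("unknown")

    return Cohort(cells=cells, rois=rois, clinical=clinical, type_vocab=tuple(type_vocab))


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping (stamps output tables)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    bundle: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
) -> pd.DataFrame:
    """Write each named table as a CSV plus a manifest of what was written.

    Returns the manifest: one row per table with file name, row count, and the
    configuration hash shared by the whole bundle.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory not writable: {out_dir}") from exc

    chash = config_hash(config or {})
    rows = []
    for name, table in bundle.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False)
        rows.append({"file": fname, "n_rows": len(table), "config_hash": chash})
    manifest = pd.DataFrame(rows, columns=["file", "n_rows", "config_hash"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(
            {
                "written_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
                "config_hash": chash,
                "files": rows,
            },
            indent=2,
        )
    )
    return manifest
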