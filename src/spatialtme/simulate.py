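"""Synthetic multi-patient, multi-region tissue cohorts with known truth.

The generator emulates the structure a multiplexed-imaging study of solid
tumors produces: tens of patients split into molecular arms (e.g. MSI-H vs
MSS), a handful of rectangular tissue regions per patient, and on the order
of a thousand segmented cells per region drawn from a 10-type vocabulary.
Spatial structure is composed from:

* **niches** — Gaussian clouds of cells around uniformly placed centers,
  each with its own type mixture (e.g. a tumor-dominated niche, a stromal
  niche, an immune-enriched stromal niche), emulating the patchwork of
  tumor nests and stroma in sections;
* **pairwise attraction** — for an attraction (A, B, s), a fraction
  s / (1 + s) of B cells is re-placed within contact range of a random A
  cell, giving a monotone dose-response for interaction statistics;
* **a hard core** — no two cell centroids closer than 0.8 (r_i + r_j),
  mimicking the fact that segmented cells cannot overlap;
* **clinical arms** — per-arm type proportions (Dirichlet-perturbed per
  patient), exponential survival whose hazard decreases with the patient's
  realized stromal-TIL fraction, administrative censoring, and a logistic
  recurrence model.

Every downstream stage therefore has a recoverable ground truth: planted
niche labels for neighborhood clustering, imposed attraction strengths for
interaction tests, arm-specific composition shifts for proportion tests,
and a known hazard structure for survival analysis.

Reproducibility: one global seed; every region, patient, and cohort-level
draw uses its own counter-based substream, so regions are independently
reproducible and byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spatialtme.core_io import (
    DEFAULT_CELL_TYPES,
    LYMPHOCYTE_TYPES,
    TUMOR_CELL_TYPES,
    Cohort,
)

__all__ = [
    "NicheSpec",
    "AttractionSpec",
    "ArmSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulationError",
    "simulate_cohort",
    "simulate_null_labels",
    "config_from_yaml",
]


class SimulationError(RuntimeError):
    """Raised when a region cannot be realized (e.g. infeasible density)."""


@dataclass
class NicheSpec:
    """A planted niche: Gaussian clouds with a fixed type mixture."""

    name: str
    mixture: dict[str, float]
    n_centers: int = 3
    sigma_um: float = 70.0
    compartment: str = "other"  # {"tumor", "stromal", "other"}
    weight: float = 1.0
    centers_um: list[tuple[float, float]] | None = None  # fixed centers; else uniform


@dataclass
class AttractionSpec:
    """Imposed spatial attraction: B cells co-placed next to A cells."""

    type_a: str
    type_b: str
    strength: float = 0.0  # fraction s/(1+s) of B cells re-placed


@dataclass
class ArmSpec:
    """One clinical arm: patient count plus composition/niche structure.

    Either ``proportions`` (cells placed uniformly, no niches) or ``niches``
    must be given. ``msi_status`` defaults to the arm name when that name is
    a recognized MSI label.
    """

    name: str
    n_patients: int
    proportions: dict[str, float] | None = None
    niches: list[NicheSpec] | None = None
    attractions: list[AttractionSpec] | None = None  # overrides the global list

    @property
    def msi_status(self) -> str:
        return self.name if self.name in ("MSI-H", "MSS") else "unknown"


def _default_niches(
    bulk_w: float, stromal_w: float, immune_stromal_w: float
) -> list[NicheSpec]:
    return [
        NicheSpec(
            name="bulk tumor",
            mixture={
                "epithelial tumor": 0.62, "p53+ tumor": 0.08,
                "proliferative tumor": 0.08, "stromal": 0.08, "macrophage": 0.05,
                "CD8+ T": 0.04, "CD4+ T": 0.02, "B cell": 0.01, "ILC/NK": 0.01,
                "proliferative immune": 0.01,
            },
            n_centers=4, sigma_um=80.0, compartment="tumor", weight=bulk_w,
        ),
        NicheSpec(
            name="stromal",
            mixture={
                "stromal": 0.65, "epithelial tumor": 0.08, "p53+ tumor": 0.01,
                "proliferative tumor": 0.01, "proliferative immune": 0.01,
                "macrophage": 0.09, "B cell": 0.03, "ILC/NK": 0.02,
                "CD4+ T": 0.05, "CD8+ T": 0.05,
            },
            n_centers=3, sigma_um=80.0, compartment="stromal", weight=stromal_w,
        ),
        NicheSpec(
            name="immune-enriched stromal",
            mixture={
                "stromal": 0.35, "macrophage": 0.15, "CD8+ T": 0.15,
                "CD4+ T": 0.12, "B cell": 0.08, "ILC/NK": 0.05,
                "proliferative immune": 0.03, "epithelial tumor": 0.05,
                "p53+ tumor": 0.01, "proliferative tumor": 0.01,
            },
            n_centers=2, sigma_um=60.0, compartment="stromal",
            weight=immune_stromal_w,
        ),
    ]


def _default_arms() -> list[ArmSpec]:
    # Cohort split and niche balance emulate a stage III colorectal study
    # arm structure: a small MSI-H arm with a richer immune-stromal
    # compartment and a larger MSS arm dominated by bulk tumor.
    return [
        ArmSpec(name="MSS", n_patients=33, niches=_default_niches(0.55, 0.30, 0.15)),
        ArmSpec(name="MSI-H", n_patients=9, niches=_default_niches(0.45, 0.25, 0.30)),
    ]


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort.

    Defaults emulate a ~40-patient imaging-mass-cytometry study: 2-8 regions
    of 500 x 500 um per patient, 1600-2400 cells per region (about
    0.008 cells/um^2, which reproduces a ~10 um modal nearest-neighbor
    spacing), cell radii around 4 um, and survival over a scale of months
    with hazard decreasing in the stromal-TIL fraction.
    """

    arms: list[ArmSpec] = field(default_factory=_default_arms)
    rois_per_patient: tuple[int, int] = (2, 8)
    roi_width_um: float = 500.0
    roi_height_um: float = 500.0
    cells_per_roi: tuple[int, int] = (1600, 2400)
    dirichlet_concentration: float | None = 150.0
    attractions: list[AttractionSpec] = field(default_factory=list)
    radius_mean_um: float = 4.0
    radius_sd_um: float = 0.6
    radius_bounds_um: tuple[float, float] = (2.0, 8.0)
    hardcore_factor: float = 0.8
    contact_range_um: float = 6.0
    baseline_hazard: float = 0.012  # events per month at sTIL fraction 0
    hazard_multiplier_per_stil: float = 0.05  # hazard = base * mult ** sTIL
    recurrence_intercept: float = 0.2
    recurrence_stil_coef: float = -8.0
    censor_quantile: float = 0.9
    type_vocab: tuple[str, ...] = DEFAULT_CELL_TYPES
    max_place_tries: int = 80
    seed: int = 0

    def validate(self) -> None:
        for arm in self.arms:
            if arm.proportions is None and not arm.niches:
                raise ValueError(f"arm {arm.name!r}: provide proportions or niches")
            if arm.proportions is not None:
                s = sum(arm.proportions.values())
                if not math.isclose(s, 1.0, abs_tol=1e-6):
                    raise ValueError(f"arm {arm.name!r}: proportions sum to {s}, not 1")
                unknown = set(arm.proportions) - set(self.type_vocab)
                if unknown:
                    raise ValueError(f"arm {arm.name!r}: unknown types {sorted(unknown)}")
            for niche in arm.niches or []:
                s = sum(niche.mixture.values())
                if not math.isclose(s, 1.0, abs_tol=1e-6):
                    raise ValueError(f"niche {niche.name!r}: mixture sums to {s}")
                if niche.sigma_um < 0 or niche.weight < 0:
                    raise ValueError(f"niche {niche.name!r}: sigma and weight must be >= 0")
        arm_atts = [a for arm in self.arms for a in (arm.attractions or [])]
        for att in list(self.attractions) + arm_atts:
            if att.strength < 0:
                raise ValueError("attraction strength must be >= 0")
        if self.baseline_hazard < 0 or self.hazard_multiplier_per_stil <= 0:
            raise ValueError("hazards must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream validation."""

    cell_niche: pd.DataFrame  # roi_id, cell_id, niche, compartment
    attractions: list[AttractionSpec]
    patients: pd.DataFrame  # patient_id, arm, true_stil_fraction, hazard


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


class _HardCoreGrid:
    """Uniform bucket grid for the minimum-centroid-distance constraint."""

    def __init__(self, width: float, height: float, cell_size: float):
        self.cs = max(cell_size, 1.0)
        self.buckets: dict[tuple[int, int], list[int]] = {}
        self.xy = []  # parallel to indices
        self.r = []

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cs), int(y // self.cs))

    def ok(self, x: float, y: float, r: float, factor: float) -> bool:
        kx, ky = self._key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in self.buckets.get((kx + dx, ky + dy), ()):
                    ox, oy = self.xy[idx]
                    mind = factor * (r + self.r[idx])
                    if (x - ox) ** 2 + (y - oy) ** 2 < mind * mind:
                        return False
        return True

    def add(self, x: float, y: float, r: float) -> int:
        idx = len(self.xy)
        self.xy.append((x, y))
        self.r.append(r)
        self.buckets.setdefault(self._key(x, y), []).append(idx)
        return idx

    def move(self, idx: int, x: float, y: float) -> None:
        ox, oy = self.xy[idx]
        self.buckets[self._key(ox, oy)].remove(idx)
        self.xy[idx] = (x, y)
        self.buckets.setdefault(self._key(x, y), []).append(idx)


def _perturb(mixture: dict[str, float], conc: float | None, rng) -> dict[str, float]:
    if conc is None:
        return mixture
    keys = list(mixture)
    alpha = np.array([mixture[k] for k in keys]) * conc + 1e-6
    draw = rng.dirichlet(alpha)
    return dict(zip(keys, draw))


def _simulate_region(
    cfg: SimulationConfig,
    niches: list[NicheSpec],
    rng: np.random.Generator,
    n_cells: int,
    attractions: list[AttractionSpec] | None = None,
) -> pd.DataFrame:
    """Place one region's cells; returns x, y, radius, cell_type, niche, compartment."""
    w, h = cfg.roi_width_um, cfg.roi_height_um
    vocab = list(cfg.type_vocab)

    weights = np.array([n.weight for n in niches], dtype=float)
    weights = weights / weights.sum()
    niche_of_cell = rng.choice(len(niches), size=n_cells, p=weights)

    centers = [
        np.asarray(n.centers_um, dtype=float)
        if n.centers_um is not None
        else (
            np.column_stack([rng.uniform(0, w, n.n_centers), rng.uniform(0, h, n.n_centers)])
            if n.n_centers > 0
            else np.empty((0, 2))
        )
        for n in niches
    ]
    radii = np.clip(
        rng.normal(cfg.radius_mean_um, cfg.radius_sd_um, n_cells),
        *cfg.radius_bounds_um,
    )
    types = np.empty(n_cells, dtype=object)
    for ni, niche in enumerate(niches):
        mask = niche_of_cell == ni
        probs = np.array([niche.mixture.get(t, 0.0) for t in vocab])
        types[mask] = rng.choice(vocab, size=int(mask.sum()), p=probs / probs.sum())

    grid = _HardCoreGrid(w, h, 2.0 * cfg.radius_bounds_um[1] * cfg.hardcore_factor)
    xs = np.empty(n_cells)
    ys = np.empty(n_cells)

    def draw_position(ni: int) -> tuple[float, float]:
        niche = niches[ni]
        if niche.sigma_um == 0.0 or len(centers[ni]) == 0:
            return rng.uniform(0, w), rng.uniform(0, h)
        cx, cy = centers[ni][rng.integers(len(centers[ni]))]
        for _ in range(20):
            x = rng.normal(cx, niche.sigma_um)
            y = rng.normal(cy, niche.sigma_um)
            if 0 <= x <= w and 0 <= y <= h:
                return x, y
        return float(np.clip(x, 0, w)), float(np.clip(y, 0, h))

    for i in range(n_cells):
        placed = False
        for _ in range(cfg.max_place_tries):
            x, y = draw_position(int(niche_of_cell[i]))
            if grid.ok(x, y, radii[i], cfg.hardcore_factor):
                grid.add(x, y, radii[i])
                xs[i], ys[i] = x, y
                placed = True
                break
        if not placed:
            raise SimulationError(
                "could not satisfy the hard-core constraint after "
                f"{cfg.max_place_tries} tries at cell {i}/{n_cells}; "
                "lower the density (fewer cells or a larger region)"
            )

    # Conditional re-placement: a fraction s/(1+s) of B cells moves next to
    # a random A cell, within contact range and outside the hard core.
    for att in cfg.attractions if attractions is None else attractions:
        frac = att.strength / (1.0 + att.strength)
        if frac <= 0:
            continue
        a_idx = np.flatnonzero(types == att.type_a)
        b_idx = np.flatnonzero(types == att.type_b)
        if len(a_idx) == 0 or len(b_idx) == 0:
            continue
        chosen = b_idx[rng.random(len(b_idx)) < frac]
        for bi in chosen:
            for _ in range(30):
                ai = a_idx[rng.integers(len(a_idx))]
                rr = radii[ai] + radii[int(bi)]
                dist = rng.uniform(cfg.hardcore_factor * rr + 0.05, rr + cfg.contact_range_um)
                theta = rng.uniform(0, 2 * np.pi)
                x = xs[ai] + dist * np.cos(theta)
                y = ys[ai] + dist * np.sin(theta)
                if 0 <= x <= w and 0 <= y <= h and grid.ok(x, y, radii[int(bi)], cfg.hardcore_factor):
                    grid.move(int(bi), x, y)
                    xs[bi], ys[bi] = x, y
                    break
            # on failure the B cell keeps its original position

    return pd.DataFrame(
        {
            "x_um": xs,
            "y_um": ys,
            "radius_um": radii,
            "cell_type": types,
            "niche": [niches[i].name for i in niche_of_cell],
            "compartment": [niches[i].compartment for i in niche_of_cell],
        }
    )


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full cohort (cells + ROI metadata + clinical) with truth.

    Deterministic given ``config.seed``; every region uses an independent
    counter-based substream.
    """
    cfg = config
    cfg.validate()
    vocab = list(cfg.type_vocab)

    cell_frames: list[pd.DataFrame] = []
    roi_rows: list[dict] = []
    patient_rows: list[dict] = []
    region_counter = 0
    patient_counter = 0

    for arm in cfg.arms:
        for _ in range(arm.n_patients):
            patient_id = f"P{patient_counter:03d}"
            prng = _rng(cfg.seed, 1, patient_counter)
            if arm.niches:
                niches = [
                    NicheSpec(
                        name=n.name,
                        mixture=_perturb(n.mixture, cfg.dirichlet_concentration, prng),
                        n_centers=n.n_centers,
                        sigma_um=n.sigma_um,
                        compartment=n.compartment,
                        weight=n.weight,
                        centers_um=n.centers_um,
                    )
                    for n in arm.niches
                ]
            else:
                props = _perturb(arm.proportions, cfg.dirichlet_concentration, prng)
                niches = [
                    NicheSpec(
                        name="uniform", mixture=props, n_centers=0, sigma_um=0.0,
                        compartment="other", weight=1.0,
                    )
                ]
            lo, hi = cfg.rois_per_patient
            n_rois = int(prng.integers(lo, hi + 1))
            for _ in range(n_rois):
                roi_id = f"R{region_counter:04d}"
                rrng = _rng(cfg.seed, 2, region_counter)
                clo, chi = cfg.cells_per_roi
                n_cells = int(rrng.integers(clo, chi + 1))
                region = _simulate_region(cfg, niches, rrng, n_cells, arm.attractions)
                region.insert(0, "cell_id", [f"{roi_id}_c{i}" for i in range(len(region))])
                region.insert(1, "roi_id", roi_id)
                region.insert(2, "patient_id", patient_id)
                cell_frames.append(region)
                purity = float(region["cell_type"].isin(TUMOR_CELL_TYPES).mean())
                roi_rows.append(
                    {
                        "roi_id": roi_id,
                        "patient_id": patient_id,
                        "width_um": cfg.roi_width_um,
                        "height_um": cfg.roi_height_um,
                        "tumor_purity": purity,
                    }
                )
                region_counter += 1
            patient_rows.append({"patient_id": patient_id, "arm": arm.name, "msi_status": arm.msi_status})
            patient_counter += 1

    cells = pd.concat(cell_frames, ignore_index=True)
    rois = pd.DataFrame(roi_rows)
    patients = pd.DataFrame(patient_rows)

    # Realized stromal-TIL fraction per patient: lymphocytes in
    # stromal-compartment niches over all cells in those niches.
    stromal = cells[cells["compartment"] == "stromal"]
    stil_map = {
        pid: float(s.isin(LYMPHOCYTE_TYPES).mean())
        for pid, s in stromal.groupby("patient_id")["cell_type"]
    }
    stil = np.array([stil_map.get(pid, 0.0) for pid in patients["patient_id"]])
    hazard = cfg.baseline_hazard * cfg.hazard_multiplier_per_stil**stil

    srng = _rng(cfg.seed, 3, 0)
    raw_times = srng.exponential(1.0 / hazard)
    horizon = float(np.quantile(raw_times, cfg.censor_quantile))
    os_time = np.minimum(raw_times, horizon)
    os_event = (raw_times <= horizon).astype(int)

    logit = cfg.recurrence_intercept + cfg.recurrence_stil_coef * stil
    p_rec = 1.0 / (1.0 + np.exp(-logit))
    recurrence = np.where(srng.random(len(p_rec)) < p_rec, "yes", "no")

    clinical = patients.assign(
        recurrence=recurrence, os_time=os_time, os_event=os_event
    )[["patient_id", "msi_status", "recurrence", "os_time", "os_event", "arm"]]

    truth = GroundTruth(
        cell_niche=cells[["roi_id", "cell_id", "niche", "compartment"]].copy(),
        attractions=list(cfg.attractions),
        patients=pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "arm": patients["arm"],
                "true_stil_fraction": stil,
                "hazard": hazard,
            }
        ),
    )
    cohort = Cohort(
        cells=cells.drop(columns=["niche", "compartment"]),
        rois=rois,
        clinical=clinical,
        type_vocab=tuple(vocab),
    )
    return cohort, truth


def simulate_null_labels(cells: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Shuffle cell-type labels within each region, preserving type counts.

    Coordinates are untouched; this is the permutation null used by the
    interaction test, exposed for simulation studies.
    """
    if len(cells) == 0:
        raise ValueError("simulate_null_labels requires a nonempty table")
    out = cells.copy()
    rng = np.random.default_rng(seed)
    for _, idx in cells.groupby("roi_id", sort=True).indices.items():
        labels = out.iloc[idx, out.columns.get_loc("cell_type")].to_numpy()
        out.iloc[idx, out.columns.get_loc("cell_type")] = labels[rng.permutation(len(labels))]
    return out


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML key/value tree."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "arms" in raw:
        raw["arms"] = [
            ArmSpec(
                name=a["name"],
                n_patients=a["n_patients"],
                proportions=a.get("proportions"),
                niches=[NicheSpec(**n) for n in a.get("niches", [])] or None,
                attractions=[AttractionSpec(**t) for t in a.get("attractions", [])] or None,
            )
            for a in raw["arms"]
        ]
    if "attractions" in raw:
        raw["attractions"] = [AttractionSpec(**a) for a in raw["attractions"]]
    for key in ("rois_per_patient", "cells_per_roi", "radius_bounds_um", "type_vocab"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
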