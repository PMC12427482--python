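"""M2-macrophage-centric spatial statistics within a fixed radius.

All statistics are computed per tissue core from cell centroids (µm) inside
a query radius, 250 µm by default — the reported maximum distance for
meaningful hematopoietic cell–cell communication:

* **pair distances** — Euclidean centroid distances for every
  (center, target) pair closer than the radius; same-label pairs are
  unordered and self-pairs excluded.
* **median pair distance** — median over the pooled pairs of a core; an
  empty neighborhood is handled by a configurable policy (treat as missing,
  code as 0, or cap at the radius).
* **M2–IMSC composite distance** — mean of the per-core median M2–M2,
  M2–MDSC and M2–Treg distances.
* **density** — for each M2 cell, the count of target cells within the
  radius; the per-core median count divided by the neighborhood area in mm²
  (πr² by default; optionally the mean disc∩core intersection, correcting
  for the fact that a 250 µm neighborhood often overhangs a 1 mm core).
* **IMSC count sum** — the summed median per-M2 counts of M2, MDSC and Treg.

Neighbor queries use a KD-tree; tests cross-check every statistic against a
brute-force all-pairs scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .abundance import MDSC_LABELS

IMSC_TARGETS = ("M2", "MDSC", "Treg")


def core_area_mm2(diameter_um: float = 1000.0) -> float:
    """Analyzable area of a circular core of the given diameter, in mm²."""
    r_mm = diameter_um / 2.0 / 1000.0
    return math.pi * r_mm**2


def disc_intersection_area_um2(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two discs with radii r1, r2 at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r**2
    a1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    tri = 0.5 * math.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return a1 + a2 - tri


@dataclass
class SpatialParams:
    """Parameters of the M2-centric neighborhood statistics.

    radius
        Query radius in µm.
    center_label
        Phenotype at the neighborhood centers.
    missing_policy
        What a core with no qualifying pairs reports: ``"missing"`` (NaN,
        excluded from downstream dichotomization), ``"zero"`` or
        ``"radius_cap"`` (the radius itself).
    clip_area
        If true, density uses the mean intersection area of the query disc
        with the core disc instead of the full πr².
    """

    radius: float = 250.0
    center_label: str = "M2"
    missing_policy: str = "missing"
    clip_area: bool = False

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.missing_policy not in ("missing", "zero", "radius_cap"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def _coords(core: pd.DataFrame, labels: Iterable[str] | str, label_col: str) -> np.ndarray:
    if isinstance(labels, str):
        labels = (labels,)
    mask = core[label_col].isin(tuple(labels))
    return core.loc[mask, ["x_um", "y_um"]].to_numpy(dtype=float)


def _target_labels(target_label: str) -> tuple[str, ...]:
    # "MDSC" is the pooled monocytic + polymorphonuclear compartment.
    return MDSC_LABELS if target_label == "MDSC" else (target_label,)


def pair_distances(
    core: pd.DataFrame,
    center_label: str,
    target_label: str,
    radius: float = 250.0,
    label_col: str = "phenotype",
) -> np.ndarray:
    """All qualifying (center, target) centroid distances of one core, in µm.

    For ``center_label == target_label`` unordered pairs are counted once and
    self-pairs are excluded.  May be empty.
    """
    centers = _coords(core, center_label, label_col)
    if center_label == target_label:
        if len(centers) < 2:
            return np.empty(0)
        tree = cKDTree(centers)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty(0)
        d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
        return np.sort(d)
    targets = _coords(core, _target_labels(target_label), label_col)
    if len(centers) == 0 or len(targets) == 0:
        return np.empty(0)
    tree = cKDTree(targets)
    out: list[np.ndarray] = []
    for c, idx in zip(centers, tree.query_ball_point(centers, radius)):
        if idx:
            out.append(np.linalg.norm(targets[np.asarray(idx)] - c, axis=1))
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def _apply_missing(params: SpatialParams) -> float:
    if params.missing_policy == "zero":
        return 0.0
    if params.missing_policy == "radius_cap":
        return float(params.radius)
    return float("nan")


def median_pair_distance(
    core: pd.DataFrame,
    center_label: str,
    target_label: str,
    params: SpatialParams | None = None,
    label_col: str = "phenotype",
) -> float:
    """Median of the pooled qualifying pair distances of one core."""
    params = params or SpatialParams()
    d = pair_distances(core, center_label, target_label, params.radius, label_col)
    if len(d) == 0:
        return _apply_missing(params)
    return float(np.median(d))


def composite_m2_imsc_distance(medians: Mapping[str, float]) -> float:
    """Mean of the median M2–M2, M2–MDSC and M2–Treg distances of a core.

    Missing components (NaN under the ``missing`` policy) propagate: the
    composite is NaN if any component is.
    """
    vals = [float(medians[t]) for t in IMSC_TARGETS]
    return float(np.mean(vals))


def neighbor_counts(
    core: pd.DataFrame,
    target_label: str,
    params: SpatialParams | None = None,
    label_col: str = "phenotype",
) -> np.ndarray:
    """Per-center counts of target cells within the radius (self excluded)."""
    params = params or SpatialParams()
    centers_mask = core[label_col] == params.center_label
    centers = core.loc[centers_mask, ["x_um", "y_um"]].to_numpy(dtype=float)
    if len(centers) == 0:
        return np.empty(0, dtype=int)
    tlabels = _target_labels(target_label)
    targets = _coords(core, tlabels, label_col)
    if len(targets) == 0:
        return np.zeros(len(centers), dtype=int)
    tree = cKDTree(targets)
    counts = np.array([len(ix) for ix in tree.query_ball_point(centers, params.radius)])
    if params.center_label in tlabels:
        counts = counts - 1  # each center finds itself at distance 0
    return counts


def _mean_clip_area_mm2(
    centers: np.ndarray,
    params: SpatialParams,
    core_center: Sequence[float],
    core_diameter: float,
) -> float:
    cc = np.asarray(core_center, dtype=float)
    r_core = core_diameter / 2.0
    areas = [
        disc_intersection_area_um2(float(np.linalg.norm(c - cc)), params.radius, r_core)
        for c in centers
    ]
    return float(np.mean(areas)) / 1e6


def density_around(
    core: pd.DataFrame,
    target_label: str,
    params: SpatialParams | None = None,
    label_col: str = "phenotype",
    core_center: Sequence[float] | None = None,
    core_diameter: float | None = None,
) -> float:
    """Median per-M2 target count divided by the neighborhood area (cells/mm²).

    Returns NaN (metric missing) for cores without any center-label cell.
    With ``clip_area`` the divisor is the mean intersection area of the
    query disc with the core disc, which requires the core geometry.
    """
    params = params or SpatialParams()
    counts = neighbor_counts(core, target_label, params, label_col)
    if len(counts) == 0:
        return float("nan")
    med = float(np.median(counts))
    if params.clip_area:
        if core_center is None or core_diameter is None:
            raise ValueError("clip_area=True requires core_center and core_diameter")
        centers = core.loc[core[label_col] == params.center_label, ["x_um", "y_um"]]
        area = _mean_clip_area_mm2(
            centers.to_numpy(dtype=float), params, core_center, core_diameter
        )
    else:
        area = math.pi * (params.radius / 1000.0) ** 2
    return med / area


def imsc_count_sum(
    core: pd.DataFrame,
    params: SpatialParams | None = None,
    label_col: str = "phenotype",
) -> float:
    """Summed median per-M2 counts of the IMSC constituents (M2, MDSC, Treg)."""
    params = params or SpatialParams()
    total = 0.0
    any_center = False
    for target in IMSC_TARGETS:
        counts = neighbor_counts(core, target, params, label_col)
        if len(counts) == 0:
            return float("nan")
        any_center = True
        total += float(np.median(counts))
    return total if any_center else float("nan")


def spatial_metrics(
    cells: pd.DataFrame,
    params: SpatialParams | None = None,
    label_col: str = "phenotype",
    density_targets: Iterable[str] = IMSC_TARGETS,
    core_geometry: Mapping[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Per-core table of all M2-centric spatial statistics.

    Columns: ``dist_M2_M2``, ``dist_M2_MDSC``, ``dist_M2_Treg``,
    ``dist_M2_IMSC`` (the composite), ``density_<target>`` for each density
    target, and ``imsc_count_sum``.  ``core_geometry`` maps core_id to
    (cx, cy, diameter) and is only needed with ``clip_area``.
    """
    params = params or SpatialParams()
    rows = []
    for core_id, core in cells.groupby("core_id", sort=True):
        med = {
            t: median_pair_distance(core, params.center_label, t, params, label_col)
            for t in IMSC_TARGETS
        }
        row: dict[str, float | str] = {"core_id": core_id}
        row["dist_M2_M2"] = med["M2"]
        row["dist_M2_MDSC"] = med["MDSC"]
        row["dist_M2_Treg"] = med["Treg"]
        row["dist_M2_IMSC"] = composite_m2_imsc_distance(med)
        geo = (core_geometry or {}).get(core_id)
        for t in density_targets:
            row[f"density_{t}"] = density_around(
                core,
                t,
                params,
                label_col,
                core_center=None if geo is None else geo[:2],
                core_diameter=None if geo is None else geo[2],
            )
        row["imsc_count_sum"] = imsc_count_sum(core, params, label_col)
        rows.append(row)
    return pd.DataFrame(rows).set_index("core_id")
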