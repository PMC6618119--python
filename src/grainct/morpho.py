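"""Per-grain trait operators and the percentile outlier filter.

Five traits are measured per labelled grain, all in physical units:

- **length** — extent along the grain's first principal axis;
- **width / depth** — the larger / smaller extent of the one-voxel-thick
  cross-section slab taken at the midpoint of the length extent;
- **volume** — voxel count × voxel_size³;
- **surface area** — count of voxel faces (6-connectivity) adjacent to
  non-grain voxels, × voxel_size².

Axis extents treat voxels as unit cubes rather than points: the peak-to-peak
projection of voxel centres plus one voxel size, so a single voxel has
length equal to the voxel size.

The face-count surface area is a "Manhattan" estimate: for smooth shapes it
converges to ~1.5× the true area (e.g. 6πr² for a sphere, not 4πr²).  It is
kept because it is exactly reproducible and monotone in shape changes; do
not compare it against marching-cubes areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from grainct.volio import TRAIT_COLUMNS, LabelVolume

logger = logging.getLogger(__name__)


class DegenerateGrainError(ValueError):
    """Raised when a voxel set is too small or too flat to measure."""


@dataclass(frozen=True)
class GrainLimitBounds:
    """Plausibility window per linear trait, μm — the 'expected grain limits'.

    Components failing these bounds are treated as non-grain material.
    Defaults are deliberately wide for small-grain cereals.
    """

    length: tuple[float, float] = (1_000.0, 15_000.0)
    width: tuple[float, float] = (500.0, 6_000.0)
    depth: tuple[float, float] = (500.0, 6_000.0)

    def __post_init__(self) -> None:
        for name in ("length", "width", "depth"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds must satisfy min < max, got {lo}, {hi}")

    def check(self, length: float, width: float, depth: float) -> bool:
        return (
            self.length[0] <= length <= self.length[1]
            and self.width[0] <= width <= self.width[1]
            and self.depth[0] <= depth <= self.depth[1]
        )


def _coords(grain_voxels: np.ndarray) -> np.ndarray:
    """(n, 3) float array of voxel centre coordinates in (z, y, x) order."""
    grain_voxels = np.asarray(grain_voxels)
    if grain_voxels.ndim == 2 and grain_voxels.shape[1] == 3:
        return grain_voxels.astype(float)
    if grain_voxels.ndim == 3:  # boolean mask
        return np.argwhere(grain_voxels).astype(float)
    raise ValueError("grain_voxels must be an (n,3) coordinate array or 3D mask")


def principal_axes(grain_voxels) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes and extents of a grain's voxel set.

    Returns ``(axes, extents)`` where ``axes`` rows are the orthonormal
    eigenvectors of the voxel-coordinate covariance in descending
    eigenvalue order, and ``extents`` are peak-to-peak projections of voxel
    centres onto each axis plus one voxel (units: voxels; multiply by
    voxel_size for μm).

    Raises
    ------
    DegenerateGrainError
        For fewer than 4 voxels or coplanar/collinear voxel sets.
    """
    pts = _coords(grain_voxels)
    if len(pts) < 4:
        raise DegenerateGrainError(f"need >= 4 voxels for principal axes, got {len(pts)}")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12 * max(evals[0], 1.0):
        raise DegenerateGrainError("degenerate (coplanar or collinear) voxel set")
    axes = evecs.T
    proj = centred @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0
    return axes, extents


def measure_length(grain_voxels, voxel_size: float) -> float:
    """Grain length: extent along the major principal axis, μm.

    A single voxel has length ``voxel_size`` by the unit-cube convention.
    """
    pts = _coords(grain_voxels)
    if len(pts) < 4:
        if len(pts) == 0:
            raise DegenerateGrainError("empty voxel set")
        # tiny voxel sets: longest peak-to-peak span over coordinate axes
        return float((np.ptp(pts, axis=0).max() + 1.0) * voxel_size)
    _, extents = principal_axes(pts)
    return float(extents[0] * voxel_size)


def measure_cross_section(grain_voxels, voxel_size: float) -> tuple[float, float]:
    """Width and depth from the grain's midpoint cross-section, μm.

    The slab is the set of voxels whose projection onto the major axis lies
    within half a voxel of the midpoint of the length extent.  Within the
    slab, 2D principal axes are computed in the plane spanned by the two
    minor axes; width is the larger extent, depth the smaller (equal for
    circular sections).
    """
    pts = _coords(grain_voxels)
    axes, extents = principal_axes(pts)
    centred = pts - pts.mean(axis=0)
    proj = centred @ axes.T
    mid = (proj[:, 0].max() + proj[:, 0].min()) / 2.0
    slab = np.abs(proj[:, 0] - mid) <= 0.5
    section = proj[slab][:, 1:]
    if len(section) < 3:
        raise DegenerateGrainError(
            f"degenerate midpoint section ({len(section)} voxels)"
        )
    centred2 = section - section.mean(axis=0)
    cov2 = centred2.T @ centred2 / len(section)
    evals2, evecs2 = np.linalg.eigh(cov2)
    order = np.argsort(evals2)[::-1]
    proj2 = centred2 @ evecs2[:, order]
    ext2 = proj2.max(axis=0) - proj2.min(axis=0) + 1.0
    width, depth = float(max(ext2)), float(min(ext2))
    return width * voxel_size, depth * voxel_size


def measure_volume(grain_voxels, voxel_size: float) -> float:
    """Grain volume: voxel count × voxel_size³, μm³."""
    pts = _coords(grain_voxels)
    return float(len(pts) * voxel_size**3)


def measure_surface_area(grain_voxels, voxel_size: float) -> float:
    """Surface area: exposed voxel faces (6-connectivity) × voxel_size², μm²."""
    pts = _coords(grain_voxels).astype(int)
    if len(pts) == 0:
        return 0.0
    lo = pts.min(axis=0)
    shape = pts.max(axis=0) - lo + 3  # one-voxel pad on every side
    mask = np.zeros(shape, dtype=bool)
    mask[tuple((pts - lo + 1).T)] = True
    faces = 0
    for axis in range(3):
        diff = np.diff(mask.astype(np.int8), axis=axis)
        faces += int(np.abs(diff).sum())
    return float(faces * voxel_size**2)


def measure_grain(grain_voxels, voxel_size: float) -> dict:
    """All five trait operators on one voxel set, as a dict in μm units."""
    pts = _coords(grain_voxels)
    length = measure_length(pts, voxel_size)
    width, depth = measure_cross_section(pts, voxel_size)
    volume = measure_volume(pts, voxel_size)
    area = measure_surface_area(pts, voxel_size)
    centroid = pts.mean(axis=0) * voxel_size
    return {
        "length_um": length,
        "width_um": width,
        "depth_um": depth,
        "volume_um3": volume,
        "surface_area_um2": area,
        "sa_v_ratio_per_um": area / volume,
        "centroid_z_um": float(centroid[0]),
        "centroid_y_um": float(centroid[1]),
        "centroid_x_um": float(centroid[2]),
    }


def extract_traits(
    labels: LabelVolume,
    *,
    status: str = "unknown",
    taxon: str = "unknown",
) -> pd.DataFrame:
    """Measure every grain in a label volume; one record per label.

    Records are ordered by label.  A grain whose measurement fails (e.g. a
    degenerate voxel set) is kept as a flagged record with NaN traits and
    the failure reason in ``flag`` — records are never silently dropped.
    """
    voxel_size = labels.voxel_size
    rows = []
    objects = ndimage.find_objects(labels.data)
    reserved = labels.metadata.get("non_grain_label")
    for label, box in enumerate(objects, start=1):
        if box is None or label == reserved:
            continue
        pts = np.argwhere(labels.data[box] == label).astype(float)
        pts += [s.start for s in box]
        row = {"grain_id": label, "status": status, "taxon": taxon, "flag": ""}
        try:
            row.update(measure_grain(pts, voxel_size))
        except DegenerateGrainError as err:
            row.update({c: np.nan for c in TRAIT_COLUMNS})
            row["sa_v_ratio_per_um"] = np.nan
            row["flag"] = str(err)
        rows.append(row)
    columns = [
        "grain_id", "status", "taxon",
        *TRAIT_COLUMNS, "sa_v_ratio_per_um",
        "centroid_z_um", "centroid_y_um", "centroid_x_um", "flag",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows).reindex(columns=columns)


def filter_outliers(
    table: pd.DataFrame,
    grain_limit_bounds: GrainLimitBounds | None = None,
    *,
    lower: float = 0.025,
    upper: float = 0.975,
) -> pd.DataFrame:
    """Remove trait outliers by tail percentiles, then by grain limits.

    For each of the five traits, records strictly below that trait's
    ``lower`` quantile or strictly above its ``upper`` quantile are removed
    (union over traits).  Quantiles use linear interpolation of order
    statistics (type 7).  Traits that are constant across the table are
    exempt — a degenerate distribution has no tails.  Records violating the
    length/width/depth plausibility bounds are then removed.  Removal
    reasons are logged per record at INFO.
    """
    if len(table) == 0:
        return table.copy()
    keep = np.ones(len(table), dtype=bool)
    reasons: dict[int, list[str]] = {}
    for trait in TRAIT_COLUMNS:
        values = table[trait].to_numpy(dtype=float)
        if np.nanmax(values) == np.nanmin(values):
            continue
        lo = np.nanquantile(values, lower)
        hi = np.nanquantile(values, upper)
        bad = (values < lo) | (values > hi)
        for i in np.flatnonzero(bad):
            reasons.setdefault(i, []).append(f"{trait} outside [{lo:.6g}, {hi:.6g}]")
        keep &= ~bad
    if grain_limit_bounds is not None:
        for i, (length, width, depth) in enumerate(
            zip(table["length_um"], table["width_um"], table["depth_um"])
        ):
            if not grain_limit_bounds.check(length, width, depth):
                reasons.setdefault(i, []).append("grain limit bounds violated")
                keep[i] = False
    for i, why in sorted(reasons.items()):
        logger.info(
            "dropping grain_id=%s: %s", table.iloc[i].get("grain_id", i), "; ".join(why)
        )
    return table.iloc[np.flatnonzero(keep)].reset_index(drop=True)
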