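"""Grain segmentation: binarize, clean, watershed-split, discard non-grain.

The stages mirror a standard μCT spike-analysis pipeline: threshold the
volume at the endosperm intensity class (the lower-density hull and rachis
fall below the threshold and are thereby excluded from measurement), remove
speckle and fill cavities, split touching grains by a watershed on the
negated Euclidean distance transform seeded from h-maxima, and finally drop
any surviving component that does not look like a grain (size window,
trait plausibility bounds, endosperm mean-intensity test).

All stages are deterministic: identical inputs yield identical labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from grainct import morpho
from grainct.volio import LabelVolume, VoxelVolume

logger = logging.getLogger(__name__)

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation pipeline.

    threshold_mode:
        ``"otsu"`` (between-class-variance maximization on a 256-bin
        histogram) or a fixed numeric threshold.  A fixed threshold placed
        between the hull and endosperm intensity classes selects endosperm
        only, which is how hull material is excluded.
    min_grain_voxels / max_grain_voxels:
        Component-size window; components outside it are dropped.
    h_maxima_depth:
        Merging depth (in distance-transform units, i.e. voxels) for
        watershed seed suppression; larger values merge more seeds and
        split less.
    connectivity:
        Foreground connectivity for component analysis: 6, 18 or 26.
    grain_limit_bounds:
        Per-trait plausibility window applied in :func:`remove_non_grain`.
    """

    threshold_mode: str | float = "otsu"
    min_grain_voxels: int = 200
    max_grain_voxels: int = 2_000_000
    h_maxima_depth: float = 2.0
    connectivity: int = 26
    grain_limit_bounds: morpho.GrainLimitBounds = field(
        default_factory=morpho.GrainLimitBounds
    )

    def __post_init__(self) -> None:
        if not 0 < self.min_grain_voxels < self.max_grain_voxels:
            raise ValueError("need 0 < min_grain_voxels < max_grain_voxels")
        if self.connectivity not in _CONNECTIVITY_STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")
        if isinstance(self.threshold_mode, str) and self.threshold_mode != "otsu":
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    @property
    def structure(self) -> np.ndarray:
        return _CONNECTIVITY_STRUCTS[self.connectivity]


def binarize(volume: VoxelVolume, params: SegmentationParams) -> np.ndarray:
    """Threshold the intensity volume to a boolean foreground mask.

    With ``threshold_mode="otsu"`` the threshold maximizes between-class
    intensity variance over a 256-bin histogram; a numeric
    ``threshold_mode`` is used as-is.  Foreground is strictly above the
    threshold.
    """
    data = volume.data
    if data.size == 0:
        raise ValueError("empty volume")
    if params.threshold_mode == "otsu":
        if np.all(data == data.flat[0]):
            raise ValueError("degenerate histogram: constant-intensity volume")
        thresh = float(threshold_otsu(data, nbins=256))
    else:
        thresh = float(params.threshold_mode)
    logger.info("binarize: threshold=%.6g", thresh)
    return data > thresh


def clean(binary: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Drop components below the size floor and fill internal cavities.

    Components are taken at ``params.connectivity``; cavities are filled
    both in 3D and slice-wise along z (a cavity open to the top/bottom face
    of the volume is still closed in its slice).  Idempotent.
    """
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(binary, structure=params.structure)
    if n:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < params.min_grain_voxels)
        small = small[small != 0]
        if small.size:
            binary = binary & ~np.isin(labels, small)
    binary = ndimage.binary_fill_holes(binary)
    for z in range(binary.shape[0]):
        binary[z] = ndimage.binary_fill_holes(binary[z])
    return binary


def split_touching(binary: np.ndarray, params: SegmentationParams) -> LabelVolume:
    """Split touching grains by seeded watershed on the distance transform.

    Seeds are the h-maxima of the exact Euclidean distance transform at
    merging depth ``h_maxima_depth`` (shallow secondary maxima on a grain's
    medial ridge are suppressed, so a lone convex grain yields one seed);
    the watershed floods the negated distance map from those seeds within
    the foreground.  Output labels are compacted to {1..K} and ordered by
    centroid position along the spike (z) axis.

    Note: voxel_size is attached by the caller via :func:`segment_volume`;
    this function works in voxel units and returns voxel_size 1.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return LabelVolume(np.zeros(binary.shape, dtype=np.int32), 1.0, {})
    # Work per connected component (padded bounding boxes): the distance
    # transform and greyscale reconstruction are local to a component, and
    # most of a spike volume is background.
    components, n_comp = ndimage.label(binary, structure=params.structure)
    distance = np.zeros(binary.shape, dtype=np.float64)
    peaks = np.zeros(binary.shape, dtype=bool)
    for comp, box in enumerate(ndimage.find_objects(components), start=1):
        if box is None:
            continue
        box = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(box, binary.shape)
        )
        mask = components[box] == comp
        dist = ndimage.distance_transform_edt(mask)
        distance[box][mask] = dist[mask]
        # h-maxima seed suppression via reconstruction: regional maxima of
        # the reconstruction of (d - h) under d.  Taking maxima of the
        # reconstructed map (not the raw h-maxima mask) keeps equal-height
        # plateaus connected through a shallow saddle as a single seed.
        rec = reconstruction(dist - params.h_maxima_depth, dist, method="dilation")
        peaks[box] |= local_maxima(rec, connectivity=3) & mask
    markers, n_seeds = ndimage.label(peaks, structure=params.structure)
    if n_seeds == 0:  # pathological; fall back to plain components
        markers = components
    labels = watershed(-distance, markers=markers, mask=binary)
    return _compact_by_z(labels)


def _compact_by_z(labels: np.ndarray) -> LabelVolume:
    """Relabel to {1..K} ordered by centroid z (ties: y then x)."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return LabelVolume(labels.astype(np.int32), 1.0, {})
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=np.uint8), labels, ids)
    order = sorted(range(len(ids)), key=lambda i: centroids[i])
    mapping = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    for new, i in enumerate(order, start=1):
        mapping[ids[i]] = new
    return LabelVolume(mapping[labels], 1.0, {})


def remove_non_grain(
    labels: LabelVolume,
    volume: VoxelVolume,
    params: SegmentationParams,
    *,
    endosperm_threshold: float | None = None,
) -> LabelVolume:
    """Drop labelled components that are not grains; compact the rest.

    A component is removed if it fails any of: the voxel-count window, the
    per-trait plausibility bounds (length/width/depth measured on the
    candidate itself), or the endosperm-intensity test (mean intensity at
    or below ``endosperm_threshold``; defaults to the binarization
    threshold that produced the labels, if numeric).  Idempotent.
    """
    if endosperm_threshold is None and not isinstance(params.threshold_mode, str):
        endosperm_threshold = float(params.threshold_mode)
    data = labels.data
    keep = []
    for label, box in enumerate(ndimage.find_objects(data), start=1):
        if box is None:
            continue
        mask = data[box] == label
        count = int(mask.sum())
        if not params.min_grain_voxels <= count <= params.max_grain_voxels:
            logger.info("dropping label %d: voxel count %d outside window", label, count)
            continue
        if endosperm_threshold is not None:
            mean_int = float(volume.data[box][mask].mean())
            if mean_int <= endosperm_threshold:
                logger.info(
                    "dropping label %d: mean intensity %.3g below endosperm class",
                    label, mean_int,
                )
                continue
        pts = np.argwhere(mask).astype(float) + [s.start for s in box]
        try:
            length = morpho.measure_length(pts, labels.voxel_size)
            width, depth = morpho.measure_cross_section(pts, labels.voxel_size)
        except morpho.DegenerateGrainError as err:
            logger.info("dropping label %d: %s", label, err)
            continue
        if not params.grain_limit_bounds.check(length, width, depth):
            logger.info(
                "dropping label %d: traits (%.0f, %.0f, %.0f) μm outside grain limits",
                label, length, width, depth,
            )
            continue
        keep.append(label)

    out = np.where(np.isin(data, keep), data, 0)
    compacted = _compact_by_z(out)
    return LabelVolume(compacted.data, labels.voxel_size, dict(labels.metadata))


def segment_volume(
    volume: VoxelVolume, params: SegmentationParams | None = None
) -> LabelVolume:
    """Full segmentation pipeline: binarize → clean → split → remove non-grain."""
    params = params or SegmentationParams()
    binary = binarize(volume, params)
    binary = clean(binary, params)
    split = split_touching(binary, params)
    split = LabelVolume(split.data, volume.voxel_size, split.metadata)
    result = remove_non_grain(split, volume, params)
    logger.info("segment_volume: %d grains", len(result.grain_labels()))
    return result
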