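"""Volume and trait-table I/O with explicit units and axis conventions.

Interchange formats are deliberately plain: TIFF slice stacks (or a single
multi-page TIFF) with a JSON sidecar carrying the physical voxel size, and
RFC-4180 CSV for trait tables.  The proprietary scanner format (Scanco ISQ)
is intentionally not supported.

Conventions, used everywhere in the package:

- volumes are indexed ``(z, y, x)``, 0-based, voxel centres at integer
  coordinates;
- the voxel size is isotropic and given in μm/voxel;
- all physical quantities are micrometres (μm, μm², μm³) internally.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Required columns of a trait-table CSV, in canonical order.
TRAIT_TABLE_COLUMNS = [
    "grain_id",
    "status",
    "taxon",
    "length_um",
    "width_um",
    "depth_um",
    "volume_um3",
    "surface_area_um2",
]

#: Names of the five measured traits as they appear in trait tables.
TRAIT_COLUMNS = ["length_um", "width_um", "depth_um", "volume_um3", "surface_area_um2"]

SIDECAR_NAME = "volume.json"


@dataclass
class VoxelVolume:
    """A 3D scalar intensity field with physical voxel size.

    Attributes
    ----------
    data:
        3D array indexed ``(z, y, x)``.
    voxel_size:
        Isotropic voxel edge length in μm/voxel.  Must be positive.
    provenance:
        Free-text metadata (e.g. generator settings, source path).
    """

    data: np.ndarray
    voxel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """An integer field assigning each voxel to background or a grain.

    Label 0 is background.  Grain labels are the contiguous set ``{1..K}``.
    A reserved label above K may mark non-grain material (hull, rachis); its
    value is recorded in ``metadata['non_grain_label']``.
    """

    data: np.ndarray
    voxel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def grain_labels(self) -> np.ndarray:
        """Labels present, excluding background and the reserved label."""
        labels = np.unique(self.data)
        labels = labels[labels > 0]
        reserved = self.metadata.get("non_grain_label")
        if reserved is not None:
            labels = labels[labels != reserved]
        return labels


def _numeric_stem_key(path: Path) -> tuple:
    """Sort key ordering file stems by embedded integer, then lexically.

    ``slice_2`` sorts before ``slice_10`` (numeric, not lexicographic).
    """
    m = re.search(r"(\d+)", path.stem)
    return (0, int(m.group(1)), path.stem) if m else (1, 0, path.stem)


def write_volume(volume: VoxelVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF plus JSON sidecar.

    ``path`` is created as a directory containing ``volume.tif`` and
    ``volume.json``.  Integer and floating data round-trip losslessly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if np.issubdtype(data.dtype, np.integer):
        # choose the narrowest unsigned/signed width that preserves values
        data = np.ascontiguousarray(data.astype(np.min_scalar_type(int(data.max(initial=0)))))
        if volume.data.size and volume.data.min() < 0:
            data = volume.data.astype(np.int64)
    tifffile.imwrite(path / "volume.tif", data)
    meta = {
        "voxel_size_um": volume.voxel_size,
        "axis_order": "zyx",
        "dtype": str(data.dtype),
    }
    extra = getattr(volume, "provenance", None) or getattr(volume, "metadata", None)
    if extra:
        meta["provenance"] = extra
    with open(path / SIDECAR_NAME, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a volume from a TIFF stack directory or a single multi-page TIFF.

    A directory may hold one multi-page TIFF or many single-slice TIFFs;
    slices are stacked along z in ascending numeric order of their file
    stems.  The voxel size must be present in the JSON sidecar — there is
    no silent default.
    """
    path = Path(path)
    if path.is_dir():
        sidecar = path / SIDECAR_NAME
        tiffs = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=_numeric_stem_key,
        )
        if not tiffs:
            raise FileNotFoundError(f"no TIFF files in {path}")
    else:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            sidecar = path.parent / SIDECAR_NAME
        tiffs = [path]

    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar with voxel_size for {path} (no silent default)"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "voxel_size_um" not in meta:
        raise KeyError(f"sidecar {sidecar} lacks required key 'voxel_size_um'")

    slabs = [tifffile.imread(p) for p in tiffs]
    slabs = [s[np.newaxis] if s.ndim == 2 else s for s in slabs]
    shapes = {s.shape[1:] for s in slabs}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    data = np.concatenate(slabs, axis=0)
    return VoxelVolume(
        data=data,
        voxel_size=float(meta["voxel_size_um"]),
        provenance=meta.get("provenance", {}),
    )


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trait table as UTF-8 CSV with the canonical header.

    Extra columns beyond the required set are preserved after them.
    Values are written at full float precision (round-trip exact).
    """
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing required columns: {missing}")
    extra = [c for c in table.columns if c not in TRAIT_TABLE_COLUMNS]
    table[TRAIT_TABLE_COLUMNS + extra].to_csv(
        path, index=False, float_format="%.17g", encoding="utf-8"
    )


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a trait-table CSV, validating the required header.

    An empty table (header only) is valid and yields zero records.
    """
    table = pd.read_csv(path)
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table {path} missing required columns: {missing}")
    return table
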