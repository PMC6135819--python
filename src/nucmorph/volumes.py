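"""3D binary mask volumes: TIFF I/O, connected-component splitting, nucleolus assignment.

Volumes are stored as ``(z, y, x)`` integer arrays — TIFF pages are the z
axis — with a per-axis physical voxel ``spacing`` in the same order.  All
physical coordinates are ``index * spacing``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

log = logging.getLogger(__name__)

#: 26-connected foreground / 6-connected background is the default
#: well-composed connectivity pairing used throughout the package.
DEFAULT_CONNECTIVITY = 26

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D voxel grid (binary mask = discretized indicator function).

    Parameters
    ----------
    voxels
        ``(z, y, x)`` non-negative integer grid; 0 is background.
    spacing
        Physical voxel size per axis ``(dz, dy, dx)``, e.g. in µm.
    image_id
        Opaque identifier of the source microscopy image.
    channel
        ``"nuclear"`` or ``"nucleolar"``.
    condition
        Class label of the image (e.g. ``"SS"`` / ``"PROLIF"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    image_id: str = ""
    channel: str = "nuclear"
    condition: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"voxel grid must be 3D with all dims >= 1, got shape {vox.shape}")
        if not np.issubdtype(vox.dtype, np.integer) and vox.dtype != bool:
            raise ValueError(f"voxel grid must be integer-typed, got {vox.dtype}")
        if vox.min() < 0:
            raise ValueError("voxel labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        if self.channel not in ("nuclear", "nucleolar"):
            raise ValueError(f"channel must be 'nuclear' or 'nucleolar', got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_binary(self) -> bool:
        return bool(self.voxels.max(initial=0) <= 1)

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def binarized(self) -> "LabeledVolume":
        """Map all nonzero labels to 1."""
        return replace(self, voxels=(self.voxels > 0).astype(np.uint8))


@dataclass(frozen=True)
class ObjectMask:
    """One connected foreground component, stored on its bounding-box subgrid."""

    voxels: np.ndarray  # local binary subgrid, (z, y, x)
    offset: tuple[int, int, int]  # bounding-box minimum corner in the parent grid
    grid_shape: tuple[int, int, int]  # parent grid shape
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    object_id: int = 0
    image_id: str = ""
    channel: str = "nuclear"
    condition: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels).astype(bool)
        if vox.ndim != 3 or not vox.any():
            raise ValueError("object mask must be a non-empty 3D binary grid")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "offset", tuple(int(o) for o in self.offset))
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def bounding_box(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """Inclusive voxel index ranges ``(min_corner, max_corner)`` in the parent grid."""
        hi = tuple(o + s - 1 for o, s in zip(self.offset, self.voxels.shape))
        return self.offset, hi

    @property
    def centroid(self) -> np.ndarray:
        """Physical centroid ``(z, y, x)``."""
        com = np.array(ndimage.center_of_mass(self.voxels))
        return (com + np.array(self.offset)) * np.array(self.spacing)

    @property
    def centroid_voxel(self) -> tuple[int, int, int]:
        """Nearest voxel index of the centroid in the parent grid."""
        com = np.array(ndimage.center_of_mass(self.voxels)) + np.array(self.offset)
        idx = np.clip(np.round(com).astype(int), 0, np.array(self.grid_shape) - 1)
        return tuple(int(i) for i in idx)

    @property
    def voxel_volume(self) -> float:
        """Foreground volume in physical units (count × voxel volume)."""
        return self.n_voxels * float(np.prod(self.spacing))

    def to_global(self) -> np.ndarray:
        """Render the object back onto a full-size parent grid."""
        full = np.zeros(self.grid_shape, dtype=np.uint8)
        sl = tuple(slice(o, o + s) for o, s in zip(self.offset, self.voxels.shape))
        full[sl] = self.voxels
        return full

    def with_voxels(self, voxels: np.ndarray) -> "ObjectMask":
        return replace(self, voxels=voxels)


def read_mask_volume(
    path: str | Path,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    image_id: str = "",
    channel: str = "nuclear",
    condition: str = "",
) -> LabeledVolume:
    """Read a multi-page TIFF stack as a binary :class:`LabeledVolume`.

    Nonzero pixel values (e.g. 65535 in 16-bit masks) are mapped to 1.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read TIFF mask volume {path}: {exc}") from exc
    if data.size == 0:
        raise OSError(f"cannot read TIFF mask volume {path}: no image data found")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D multi-page TIFF, got ndim={data.ndim}")
    vox = (data > 0).astype(np.uint8)
    return LabeledVolume(vox, tuple(spacing), image_id=image_id, channel=channel, condition=condition)


def write_mask_volume(volume: LabeledVolume, path: str | Path) -> Path:
    """Write a volume as an 8-bit multi-page TIFF (foreground = 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.where(volume.voxels > 0, 255, 0).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def split_objects(
    volume: LabeledVolume,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_voxels: int = 50,
) -> list[ObjectMask]:
    """Split a binary volume into maximal connected components.

    Components smaller than ``min_voxels`` are discarded (logged).  Returns
    objects ordered by decreasing voxel count, ids starting at 1.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    if not volume.is_binary:
        raise ValueError("split_objects requires a binary volume")
    labels, n = ndimage.label(volume.voxels, structure=_STRUCTS[connectivity])
    if n == 0:
        return []
    slices = ndimage.find_objects(labels)
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(-counts, kind="stable")
    objects: list[ObjectMask] = []
    next_id = 1
    for lab in order:
        if counts[lab] < min_voxels:
            log.info(
                "image %s/%s: discarding component of %d voxels (< %d)",
                volume.image_id, volume.channel, counts[lab], min_voxels,
            )
            continue
        sl = slices[lab]
        local = labels[sl] == (lab + 1)
        objects.append(
            ObjectMask(
                voxels=local,
                offset=tuple(s.start for s in sl),
                grid_shape=volume.shape,
                spacing=volume.spacing,
                object_id=next_id,
                image_id=volume.image_id,
                channel=volume.channel,
                condition=volume.condition,
            )
        )
        next_id += 1
    return objects


def assign_nucleoli(
    nuclei: Sequence[ObjectMask],
    nucleoli: Sequence[ObjectMask],
) -> dict[int, list[ObjectMask]]:
    """Assign nucleoli to the nucleus containing their centroid voxel.

    Nucleoli whose centroid lies inside no nucleus are dropped; nuclei with
    zero assigned nucleoli are excluded from the mapping (both logged), so
    every key of the returned ``{nucleus_id: [nucleoli]}`` mapping has at
    least one nucleolus.
    """
    if not nuclei:
        return {}
    grid_shape = nuclei[0].grid_shape
    for obj in list(nuclei) + list(nucleoli):
        if obj.grid_shape != grid_shape:
            raise ValueError(
                f"grid shape mismatch: {obj.grid_shape} vs {grid_shape} "
                f"(image {obj.image_id}, channel {obj.channel})"
            )
    mapping: dict[int, list[ObjectMask]] = {}
    for ncl in nucleoli:
        z, y, x = ncl.centroid_voxel
        parent = None
        for nuc in nuclei:
            (z0, y0, x0), (z1, y1, x1) = nuc.bounding_box
            if z0 <= z <= z1 and y0 <= y <= y1 and x0 <= x <= x1:
                if nuc.voxels[z - z0, y - y0, x - x0]:
                    parent = nuc
                    break
        if parent is None:
            log.info("image %s: nucleolus %d centered outside every nucleus, dropped",
                     ncl.image_id, ncl.object_id)
            continue
        mapping.setdefault(parent.object_id, []).append(ncl)
    for nuc in nuclei:
        if nuc.object_id not in mapping:
            log.info("image %s: nucleus %d has no internal nucleoli, excluded",
                     nuc.image_id, nuc.object_id)
    return mapping


# ---------------------------------------------------------------------------
# Manifest handling

MANIFEST_COLUMNS = ["path", "image_id", "channel", "condition", "dz", "dy", "dx"]


def write_manifest(rows: Iterable[Mapping], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(list(rows))
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing and len(df):
        raise ValueError(f"manifest rows missing columns: {sorted(missing)}")
    df = df[MANIFEST_COLUMNS] if len(df) else pd.DataFrame(columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "channel": str, "condition": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def load_manifest_volumes(path: str | Path) -> list[LabeledVolume]:
    """Read every volume listed in a manifest CSV (paths relative to it)."""
    path = Path(path)
    df = read_manifest(path)
    vols = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        vols.append(
            read_mask_volume(p, spacing=(row.dz, row.dy, row.dx),
                             image_id=row.image_id, channel=row.channel,
                             condition=row.condition)
        )
    return vols
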