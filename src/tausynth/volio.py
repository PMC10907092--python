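"""Template-space volume and atlas containers plus NIfTI / JSON / CSV I/O.

Every stage of the pipeline operates on 3D scalar grids that share one
voxel grid. The containers here enforce that contract: finite values,
matching shapes, a declared coordinate convention. Axis order is fixed as
(x: left-right, y: posterior-anterior, z: inferior-superior) with 0-based
voxel indices; crops and pads elsewhere refer to this convention.

No resampling or reorientation happens here — volumes must already live on
a common template grid, and orientation metadata (the NIfTI affine) is
carried through verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "ROIAtlas",
    "AlignmentError",
    "VolumeValidationError",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "check_aligned",
]

#: spaces a Volume may live in: the anatomical template grid, or the
#: power-of-two grid the network consumes.
SPACES = ("template", "network")


class VolumeValidationError(ValueError):
    """A volume or atlas violates the data model (NaNs, wrong rank, ...)."""


class AlignmentError(ValueError):
    """Two grids that must share a shape do not."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel size (mm) and a space tag.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite scalar intensities.
    voxel_size : tuple of 3 floats
        Voxel edge lengths in millimetres.
    space : {"template", "network"}
        Which grid convention the volume lives on.
    affine : ndarray (4, 4), optional
        NIfTI affine, preserved verbatim on I/O. Defaults to a scaled
        identity built from ``voxel_size``.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space: str = "template"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeValidationError(
                f"expected a 3D grid, got {self.values.ndim} dimensions"
            )
        bad = np.size(self.values) - np.isfinite(self.values).sum()
        if bad:
            raise VolumeValidationError(
                f"volume contains {int(bad)} non-finite voxel(s)"
            )
        if self.space not in SPACES:
            raise VolumeValidationError(f"unknown space {self.space!r}")
        if any(v <= 0 for v in self.voxel_size):
            raise VolumeValidationError("voxel_size entries must be positive")
        if self.affine is None:
            self.affine = np.diag((*self.voxel_size, 1.0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, space: str | None = None) -> "Volume":
        """Copy of this volume with new voxel data (and optionally a new space)."""
        return Volume(
            values=values,
            voxel_size=self.voxel_size,
            space=space if space is not None else self.space,
            affine=None if space not in (None, self.space) else self.affine,
        )


@dataclass
class ROIAtlas:
    """Integer-labelled parcellation aligned to a template-space Volume.

    Label 0 is reserved for background. ``meta_members`` names the composite
    temporal meta-ROI (in the real study: amygdala, entorhinal, fusiform,
    parahippocampal, inferior and middle temporal); ``reference_label`` is
    the SUVR normalization region (pons / cerebellar crus surrogate).
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    meta_members: frozenset[int] = frozenset()
    reference_label: int = 0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeValidationError("atlas labels must form a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeValidationError("atlas labels must be integers")
        self.meta_members = frozenset(int(m) for m in self.meta_members)
        if not self.meta_members:
            raise VolumeValidationError("meta_members must be non-empty")
        if 0 in self.meta_members:
            raise VolumeValidationError("background (0) cannot be a meta-ROI member")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def roi_labels(self) -> list[int]:
        """Sorted non-background labels present in the grid."""
        present = np.unique(self.labels)
        return [int(v) for v in present if v != 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def check_aligned(volume: Volume, atlas: ROIAtlas) -> None:
    """Assert that a volume and an atlas share one voxel grid.

    Raises
    ------
    AlignmentError
        If the shapes differ (both shapes are named in the message).
    VolumeValidationError
        If the atlas carries no non-background labels.
    """
    if volume.shape != atlas.shape:
        raise AlignmentError(
            f"volume shape {volume.shape} != atlas shape {atlas.shape}"
        )
    if not np.any(atlas.labels):
        raise VolumeValidationError("atlas labels are all background (0)")


def read_volume(path: str | Path, space: str = "template") -> Volume:
    """Read a single-frame 3D NIfTI volume.

    Raises an explicit error for 4D files, non-finite voxels, or a missing
    file; never silently reorients.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeValidationError(
            f"{path.name}: expected a 3D single-frame volume, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return Volume(
        values=data.astype(np.float64),
        voxel_size=tuple(float(z) for z in zooms),
        space=space,
        affine=np.asarray(img.affine),
    )


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a Volume as NIfTI-1, preserving the affine verbatim."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))
    return path


def write_atlas(atlas: ROIAtlas, nifti_path: str | Path, json_path: str | Path) -> None:
    """Write an atlas as a NIfTI label grid plus a JSON sidecar.

    The sidecar records label names, meta-ROI membership and the reference
    label so the atlas round-trips without loss.
    """
    img = nib.Nifti1Image(np.asarray(atlas.labels, dtype=np.int16), atlas.affine)
    nib.save(img, str(nifti_path))
    sidecar = {
        "names": {str(k): v for k, v in atlas.names.items()},
        "meta_members": sorted(atlas.meta_members),
        "reference_label": int(atlas.reference_label),
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2))


def read_atlas(nifti_path: str | Path, json_path: str | Path) -> ROIAtlas:
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    sidecar = json.loads(Path(json_path).read_text())
    return ROIAtlas(
        labels=labels,
        names={int(k): v for k, v in sidecar["names"].items()},
        meta_members=frozenset(sidecar["meta_members"]),
        reference_label=int(sidecar["reference_label"]),
        affine=np.asarray(img.affine),
    )
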