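"""Intensity normalization and the template <-> network-space crop/pad.

Two deterministic geometry ops move volumes between the anatomical
template grid (121 x 145 x 121 in the full-size configuration) and the
power-of-two grid the network needs (128^3): along the posterior-anterior
axis (axis 1) 8 anterior and 9 posterior slices are cropped, and the two
121-length axes (0 and 2) are zero-padded with 7 slices at their low-index
("left" / "bottom") ends. The inverse restores the template shape exactly,
with the cropped slices re-created as zeros.

Two intensity normalizations mirror PET and structural MRI conventions:
SUVR (divide by the *median* uptake in a reference region) and T1w
white-matter normalization (divide by the *mean* within a mask). Both are
scale-equivariant: normalize(k*v) == normalize(v) for any k > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import ROIAtlas, Volume, check_aligned

__all__ = [
    "CropPadSpec",
    "NormalizationError",
    "template_128_spec",
    "identity_spec",
    "crop_pad",
    "invert_crop_pad",
    "normalize_suvr",
    "normalize_t1w",
]

AP_AXIS = 1  # posterior-anterior axis in the fixed (x, y, z) convention


class NormalizationError(ValueError):
    """Reference region empty or with non-positive central value."""


@dataclass(frozen=True)
class CropPadSpec:
    """Deterministic crop/pad between template and network shapes.

    ``crop_low_ap`` slices are removed at the anterior (high-index) end of
    axis 1 and ``crop_high_ap`` at the posterior (low-index) end; axes 0 and
    2 are zero-padded at their low ends. The arithmetic must close exactly:
    template minus crops / plus pads equals the network shape.
    """

    crop_low_ap: int
    crop_high_ap: int
    pad_low_axis1: int
    pad_low_axis3: int
    template_shape: tuple[int, int, int]
    network_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if min(self.crop_low_ap, self.crop_high_ap, self.pad_low_axis1, self.pad_low_axis3) < 0:
            raise ValueError("crop/pad amounts must be non-negative")
        t, n = self.template_shape, self.network_shape
        if t[AP_AXIS] - self.crop_low_ap - self.crop_high_ap != n[AP_AXIS]:
            raise ValueError(
                f"AP arithmetic does not close: {t[AP_AXIS]} - {self.crop_low_ap} "
                f"- {self.crop_high_ap} != {n[AP_AXIS]}"
            )
        if t[0] + self.pad_low_axis1 != n[0] or t[2] + self.pad_low_axis3 != n[2]:
            raise ValueError("lateral/axial pad arithmetic does not close")


def template_128_spec() -> CropPadSpec:
    """The full-size 121x145x121 -> 128^3 specification.

    8 anterior and 9 posterior slices cropped on the AP axis
    (145 - 17 = 128) and 7 zero slices padded at the low end of each
    121-length axis (121 + 7 = 128).
    """
    return CropPadSpec(
        crop_low_ap=8,
        crop_high_ap=9,
        pad_low_axis1=7,
        pad_low_axis3=7,
        template_shape=(121, 145, 121),
        network_shape=(128, 128, 128),
    )


def identity_spec(shape: tuple[int, int, int]) -> CropPadSpec:
    """A no-op spec for volumes already on a network-compatible grid."""
    return CropPadSpec(0, 0, 0, 0, tuple(shape), tuple(shape))


def _check_shape(vol: Volume, expected: tuple[int, int, int], what: str) -> None:
    if vol.shape != tuple(expected):
        raise ValueError(f"{what}: expected shape {tuple(expected)}, got {vol.shape}")


def crop_pad(volume: Volume, spec: CropPadSpec) -> Volume:
    """Template -> network space: crop the AP axis, zero-pad axes 0 and 2.

    Retained voxels are copied unchanged; padded voxels are exactly 0.
    """
    _check_shape(volume, spec.template_shape, "crop_pad input")
    v = volume.values
    ap_len = v.shape[AP_AXIS]
    # anterior = high-index end of the posterior->anterior axis
    v = v[:, spec.crop_high_ap : ap_len - spec.crop_low_ap, :]
    v = np.pad(v, ((spec.pad_low_axis1, 0), (0, 0), (spec.pad_low_axis3, 0)))
    out = Volume(values=v, voxel_size=volume.voxel_size, space="network")
    _check_shape(out, spec.network_shape, "crop_pad output")
    return out


def invert_crop_pad(volume: Volume, spec: CropPadSpec) -> Volume:
    """Network -> template space; cropped slices come back as zeros.

    Exact inverse on the retained region: for any template-space ``v``,
    ``invert_crop_pad(crop_pad(v))`` equals ``v`` wherever voxels were kept.
    """
    _check_shape(volume, spec.network_shape, "invert_crop_pad input")
    v = volume.values[spec.pad_low_axis1 :, :, spec.pad_low_axis3 :]
    v = np.pad(v, ((0, 0), (spec.crop_high_ap, spec.crop_low_ap), (0, 0)))
    out = Volume(values=v, voxel_size=volume.voxel_size, space="template")
    _check_shape(out, spec.template_shape, "invert_crop_pad output")
    return out


def normalize_suvr(volume: Volume, atlas: ROIAtlas) -> Volume:
    """Divide by the median uptake in the atlas's reference region.

    After normalization the median over the reference region equals 1.
    """
    check_aligned(volume, atlas)
    ref = volume.values[atlas.mask(atlas.reference_label)]
    if ref.size == 0:
        raise NormalizationError(
            f"reference region (label {atlas.reference_label}) is empty"
        )
    med = float(np.median(ref))
    if med <= 0:
        raise NormalizationError(
            f"reference-region median is {med}; SUVR undefined"
        )
    return volume.with_values(volume.values / med)


def normalize_t1w(volume: Volume, wm_mask: Volume) -> Volume:
    """Divide by the mean intensity within a white-matter mask volume.

    The mask is any volume whose non-zero voxels define the region; after
    normalization the in-mask mean equals 1.
    """
    if volume.shape != wm_mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {wm_mask.shape}"
        )
    m = wm_mask.values > 0
    if not m.any():
        raise NormalizationError("white-matter mask is empty")
    mean = float(volume.values[m].mean())
    if mean <= 0:
        raise NormalizationError(f"in-mask mean is {mean}; normalization undefined")
    return volume.with_values(volume.values / mean)
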