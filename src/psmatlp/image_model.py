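"""Data model and NIfTI I/O for SUV-calibrated PET volumes and aligned label masks.

A :class:`SuvImage` is a 3-D grid of body-weight standardized uptake values
(SUV, dimensionless) with millimetre voxel spacing taken from the NIfTI
header.  Masks (:class:`LabelMask`) must live on the exact same grid as their
companion image; no resampling is performed anywhere in this package — the
segmentation operates on one co-registered grid per scan.

Input volumes are expected to already be in SUV units.  Conversion from raw
activity concentration (which needs injected dose, decay and body-weight
bookkeeping) is outside the scope of this model.  Negative voxel values are
rejected at read time rather than clamped, so miscalibrated input fails
loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Timepoint",
    "MaskRole",
    "ValidationError",
    "AlignmentError",
    "SuvImage",
    "LabelMask",
    "read_suv_image",
    "write_suv_image",
    "read_mask",
    "write_mask",
    "voxel_volume_ml",
]


class Timepoint(str, Enum):
    """Scan timepoint relative to the therapy course."""

    BASELINE = "baseline"
    POST_CYCLE2 = "post_cycle2"


class MaskRole(str, Enum):
    """What a label mask marks on the SUV grid."""

    EXCLUSION = "exclusion"  # physiologic-uptake sites to remove from candidates
    LIVER = "liver"  # liver parenchyma (gets the elevated threshold)
    LIVER_REFERENCE_VOI = "liver_reference_voi"  # healthy-liver reference region


class ValidationError(ValueError):
    """Input data violates a model invariant (negative SUV, wrong dtype...)."""


class AlignmentError(ValueError):
    """A mask does not share the grid of its companion image."""


@dataclass
class SuvImage:
    """A 3-D SUV-valued voxel grid plus geometry metadata.

    Parameters
    ----------
    voxels
        3-D float array of SUV values; all finite and >= 0.
    spacing
        Voxel edge lengths in mm per axis, all > 0.
    affine
        4x4 voxel-to-world affine (NIfTI convention).  Carried through I/O;
        not used in any computation.
    patient_id, timepoint
        Provenance labels.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    patient_id: str = ""
    timepoint: Timepoint = Timepoint.BASELINE

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"SUV volume must be 3-D, got shape {self.voxels.shape}"
            )
        if self.voxels.size == 0:
            raise ValidationError("SUV volume is empty")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("SUV volume contains non-finite values")
        if np.any(self.voxels < 0):
            raise ValidationError(
                "SUV volume contains negative values; input is not SUV-calibrated"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.timepoint = Timepoint(self.timepoint)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMask:
    """An integer label grid aligned voxel-for-voxel with a :class:`SuvImage`.

    All roles used by the pipeline are binary: values must be 0 or 1.
    """

    voxels: np.ndarray
    role: MaskRole
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValidationError("mask contains non-integer values")
            arr = arr.astype(np.int16)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{self.role.value} mask must be binary (0/1)")
        self.voxels = arr
        self.role = MaskRole(self.role)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def check_aligned(self, reference: SuvImage) -> None:
        if self.shape != reference.shape:
            raise AlignmentError(
                f"mask shape {self.shape} does not match image shape {reference.shape}"
            )
        if not np.allclose(self.spacing, reference.spacing):
            raise AlignmentError(
                f"mask spacing {self.spacing} does not match image spacing "
                f"{reference.spacing}"
            )


def read_suv_image(
    path: str | Path,
    patient_id: str = "",
    timepoint: Timepoint | str = Timepoint.BASELINE,
) -> SuvImage:
    """Load a 3-D SUV volume from a NIfTI file (.nii or .nii.gz).

    Spacing comes from the header zooms.  4-D input is refused rather than
    silently squeezed or averaged: a dynamic series is not one SUV volume.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(
            f"expected a 3-D scalar volume, got {data.ndim}-D data in {path.name}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SuvImage(
        voxels=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        affine=np.asarray(img.affine, dtype=np.float64),
        patient_id=patient_id,
        timepoint=Timepoint(timepoint),
    )


def write_suv_image(image: SuvImage, path: str | Path) -> Path:
    """Write an :class:`SuvImage` to NIfTI; gzip chosen by file extension."""
    path = Path(path)
    nifti = nib.Nifti1Image(image.voxels, affine=image.affine)
    nifti.header.set_zooms(image.spacing)
    nib.save(nifti, str(path))
    return path


def read_mask(path: str | Path, reference: SuvImage, role: MaskRole | str) -> LabelMask:
    """Load a binary mask and validate its alignment against *reference*."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"mask must be 3-D, got {data.ndim}-D in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = LabelMask(voxels=data, role=MaskRole(role), spacing=spacing)
    mask.check_aligned(reference)
    return mask


def write_mask(mask: LabelMask, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    aff = affine if affine is not None else np.diag([*mask.spacing, 1.0])
    nifti = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine=aff)
    nifti.header.set_zooms(mask.spacing)
    nib.save(nifti, str(path))
    return path


def voxel_volume_ml(image: SuvImage) -> float:
    """Volume of one voxel in millilitres: product of mm spacings / 1000."""
    sx, sy, sz = image.spacing
    return sx * sy * sz / 1000.0
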