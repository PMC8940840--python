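"""Whole-body SUV-threshold tumor segmentation.

The procedure mirrors semiautomatic whole-body delineation of PSMA-avid
disease: every voxel with SUV at or above a fixed global threshold
(default 3.0) is a tumor candidate, except that voxels inside the liver must
instead exceed 1.5 x the mean SUV of a healthy-liver reference region (liver
parenchyma shows physiologic tracer uptake, so the global threshold would
flood it).  Physiologic-uptake organs other than the liver — salivary
glands, vocal cords, spleen, intestine, ureter, bladder — are removed with a
caller-supplied exclusion mask.  The surviving candidate voxels are grouped
into connected components (26-connectivity by default) and per-lesion
statistics (volume in mL, SUVmean, SUVmax) are computed; these feed the
total-lesion-PSMA biomarker downstream.

All threshold comparisons are inclusive (>=).  Lesion ids are assigned by
descending volume with centroid lexicographic order breaking ties, so the
output is independent of component traversal order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_model import (
    AlignmentError,
    LabelMask,
    SuvImage,
    voxel_volume_ml,
)

__all__ = [
    "SegmentationConfig",
    "Lesion",
    "LesionSet",
    "liver_reference_threshold",
    "build_threshold_map",
    "segment_whole_body",
    "lesion_stats",
]

#: scipy connectivity rank per face/edge/corner neighbourhood
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the threshold segmentation.

    Attributes
    ----------
    global_threshold_suv
        Inclusive SUV threshold applied outside the liver.  Default 3.0.
    liver_factor
        Multiplier on the healthy-liver reference SUVmean giving the liver
        threshold.  Default 1.5.
    connectivity
        Voxel neighbourhood for connected components: 6 (faces), 18
        (faces+edges) or 26 (faces+edges+corners).  Default 26.
    min_lesion_volume_ml
        Components smaller than this are dropped.  Default 0 (keep all).
    """

    global_threshold_suv: float = 3.0
    liver_factor: float = 1.5
    connectivity: int = 26
    min_lesion_volume_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.global_threshold_suv <= 0:
            raise ValueError("global_threshold_suv must be > 0")
        if self.liver_factor <= 0:
            raise ValueError("liver_factor must be > 0")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.min_lesion_volume_ml < 0:
            raise ValueError("min_lesion_volume_ml must be >= 0")


@dataclass
class Lesion:
    """One connected tumor component with its summary statistics."""

    lesion_id: int
    voxel_count: int
    volume_ml: float
    suv_mean: float
    suv_max: float
    centroid: tuple[float, float, float]
    in_liver: bool = False


@dataclass
class LesionSet:
    """All lesions segmented from one scan, plus provenance."""

    lesions: list[Lesion]
    source_image_id: str = ""
    config: SegmentationConfig = field(default_factory=SegmentationConfig)
    liver_threshold_used: float | None = None

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "lesion_id": l.lesion_id,
                "voxel_count": l.voxel_count,
                "volume_ml": l.volume_ml,
                "suv_mean": l.suv_mean,
                "suv_max": l.suv_max,
                "centroid_i": l.centroid[0],
                "centroid_j": l.centroid[1],
                "centroid_k": l.centroid[2],
                "in_liver": l.in_liver,
            }
            for l in self.lesions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "lesion_id",
                "voxel_count",
                "volume_ml",
                "suv_mean",
                "suv_max",
                "centroid_i",
                "centroid_j",
                "centroid_k",
                "in_liver",
            ],
        )

    def write_csv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        """Write the lesion table; optionally a JSON sidecar with config and
        the thresholds actually applied."""
        self.to_dataframe().to_csv(path, index=False)
        if provenance_path is not None:
            prov = {
                "source_image_id": self.source_image_id,
                "config": asdict(self.config),
                "liver_threshold_used": self.liver_threshold_used,
                "n_lesions": len(self.lesions),
            }
            Path(provenance_path).write_text(json.dumps(prov, indent=2))


def liver_reference_threshold(
    image: SuvImage,
    liver_ref_voi: LabelMask,
    config: SegmentationConfig | None = None,
) -> float:
    """Liver segmentation threshold: liver_factor x SUVmean of the healthy-liver
    reference region.

    An empty reference VOI is an error — there is no silent fallback to the
    global threshold, because applying SUV >= 3 inside a physiologically avid
    liver would segment healthy parenchyma as tumor.
    """
    config = config or SegmentationConfig()
    liver_ref_voi.check_aligned(image)
    sel = liver_ref_voi.as_bool()
    if not sel.any():
        raise ValueError("liver reference VOI selects no voxels")
    return float(config.liver_factor * image.voxels[sel].mean())


def build_threshold_map(
    image: SuvImage,
    liver_mask: LabelMask | None = None,
    liver_threshold: float | None = None,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Per-voxel SUV threshold: the global threshold everywhere, replaced by
    the liver threshold inside the liver mask."""
    config = config or SegmentationConfig()
    thr = np.full(image.shape, config.global_threshold_suv, dtype=np.float64)
    if liver_mask is not None:
        liver_mask.check_aligned(image)
        if liver_threshold is None:
            raise ValueError("liver_threshold required when a liver mask is supplied")
        thr[liver_mask.as_bool()] = liver_threshold
    return thr


def lesion_stats(
    image: SuvImage,
    component_voxels: np.ndarray,
    lesion_id: int = 0,
    liver_mask: LabelMask | None = None,
) -> Lesion:
    """Summary statistics for one voxel set.

    Parameters
    ----------
    component_voxels
        (n, 3) integer array of grid coordinates, n >= 1.
    """
    coords = np.atleast_2d(np.asarray(component_voxels, dtype=np.intp))
    if coords.size == 0:
        raise ValueError("empty voxel set")
    if coords.shape[1] != 3:
        raise ValueError("component_voxels must be an (n, 3) coordinate array")
    values = image.voxels[coords[:, 0], coords[:, 1], coords[:, 2]]
    centroid = tuple(float(c) for c in coords.mean(axis=0))
    in_liver = False
    if liver_mask is not None:
        idx = tuple(int(round(c)) for c in centroid)
        idx = tuple(min(max(i, 0), s - 1) for i, s in zip(idx, image.shape))
        in_liver = bool(liver_mask.voxels[idx])
    return Lesion(
        lesion_id=lesion_id,
        voxel_count=int(coords.shape[0]),
        volume_ml=float(coords.shape[0] * voxel_volume_ml(image)),
        suv_mean=float(values.mean()),
        suv_max=float(values.max()),
        centroid=centroid,
        in_liver=in_liver,
    )


def segment_whole_body(
    image: SuvImage,
    exclusion_mask: LabelMask | None = None,
    liver_mask: LabelMask | None = None,
    liver_ref_voi: LabelMask | None = None,
    config: SegmentationConfig | None = None,
) -> LesionSet:
    """Segment all tumor lesions of a whole-body SUV volume.

    Candidate voxels satisfy SUV >= per-voxel threshold (global outside the
    liver, ``liver_factor x reference SUVmean`` inside it) and lie outside the
    exclusion mask.  Candidates are grouped into connected components at the
    configured connectivity; components smaller than
    ``min_lesion_volume_ml`` are dropped.  ``in_liver`` flags lesions whose
    (rounded) centroid falls inside the liver mask; a lesion straddling the
    liver boundary is segmented with the threshold map as-is.
    """
    config = config or SegmentationConfig()

    liver_threshold: float | None = None
    if liver_mask is not None:
        liver_mask.check_aligned(image)
        if not liver_mask.as_bool().any():
            liver_mask = None  # no liver voxels: the liver rule is vacuous
    if liver_mask is not None:
        if liver_ref_voi is None:
            raise ValueError(
                "liver mask supplied without a healthy-liver reference VOI"
            )
        liver_threshold = liver_reference_threshold(image, liver_ref_voi, config)

    thr = build_threshold_map(image, liver_mask, liver_threshold, config)
    candidates = image.voxels >= thr
    if exclusion_mask is not None:
        exclusion_mask.check_aligned(image)
        candidates &= ~exclusion_mask.as_bool()

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[config.connectivity])
    labels, n_components = ndimage.label(candidates, structure=structure)

    lesions: list[Lesion] = []
    for comp in range(1, n_components + 1):
        coords = np.argwhere(labels == comp)
        lesion = lesion_stats(image, coords, lesion_id=0, liver_mask=liver_mask)
        if lesion.volume_ml < config.min_lesion_volume_ml:
            continue
        lesions.append(lesion)

    # deterministic ids: largest lesion first, centroid breaks ties
    lesions.sort(key=lambda l: (-l.volume_ml, l.centroid))
    for i, lesion in enumerate(lesions, start=1):
        lesion.lesion_id = i

    return LesionSet(
        lesions=lesions,
        source_image_id=image.patient_id,
        config=config,
        liver_threshold_used=liver_threshold,
    )
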