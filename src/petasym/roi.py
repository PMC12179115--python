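"""Region bookkeeping: probability-map thresholding, label grouping, and TAC /
volume extraction from already-aligned label images.

Alignment (registration, segmentation, atlas warping) is explicitly the
caller's responsibility: volumes are interpreted in plain voxel-index space.
ROI statistics use unweighted voxel means after binarisation, matching a
binarise-then-apply order of operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import FrameSchedule, TimeActivityCurve

__all__ = [
    "RegionDefinition",
    "binarize_probability_map",
    "combine_region_labels",
    "extract_region_tac",
    "save_nifti",
    "load_nifti",
]

_GMWM_REGIONS = {"thalamus", "putamen", "brain_gmwm"}
_VALID_NAMES = {
    "thalamus",
    "putamen",
    "temporal",
    "frontal",
    "occipital",
    "parietal",
    "grey_matter",
    "brain_gmwm",
    "cerebellum_gm",
}


@dataclass(frozen=True)
class RegionDefinition:
    """A composite region: named atlas labels on one side (or bilateral).

    Thalamus, putamen and the whole-brain composite are unsegmented (GM+WM);
    cortices, grey matter and cerebellum are grey matter only and are
    intersected with a thresholded GM mask when one is supplied.
    """

    name: str
    side: str
    member_labels: frozenset[int]
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.name not in _VALID_NAMES:
            raise ValueError(f"unknown region name {self.name!r}")
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError(f"side must be left/right/bilateral, got {self.side!r}")
        if not self.member_labels:
            raise ValueError("member_labels must be non-empty")
        tissue = "GMWM" if self.name in _GMWM_REGIONS else "GM"
        if self.tissue and self.tissue != tissue:
            raise ValueError(f"{self.name!r} must have tissue class {tissue}")
        object.__setattr__(self, "tissue", tissue)


def binarize_probability_map(pmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Inclusive threshold: voxel kept iff probability >= threshold.

    The inclusive rule keeps the threshold value itself inside the mask.  An
    all-below-threshold map yields an empty mask with a warning, not an error.
    """
    pmap = np.asarray(pmap, dtype=float)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if np.any(pmap < 0.0) or np.any(pmap > 1.0):
        raise ValueError("probability map values must lie in [0, 1]")
    mask = pmap >= threshold
    if not mask.any():
        warnings.warn("thresholded probability map is empty", stacklevel=2)
    return mask


def combine_region_labels(
    labels: np.ndarray,
    definition: RegionDefinition,
    legend: dict[int, tuple[str, str]] | set[int] | None = None,
    gm_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Union of a region's member labels, GM-restricted for GM-tissue regions."""
    labels = np.asarray(labels)
    if legend is not None:
        known = set(legend) if not isinstance(legend, dict) else set(legend.keys())
        unknown = set(definition.member_labels) - known
        if unknown:
            raise ValueError(
                f"region {definition.name!r} references unknown label ids {sorted(unknown)}"
            )
    mask = np.isin(labels, list(definition.member_labels))
    if definition.tissue == "GM" and gm_mask is not None:
        if gm_mask.shape != labels.shape:
            raise ValueError("GM mask and label volume shapes differ")
        mask &= gm_mask.astype(bool)
    return mask


def extract_region_tac(
    image4d: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float,
    schedule: FrameSchedule,
    label: str = "",
) -> tuple[TimeActivityCurve, float]:
    """Unweighted voxel-mean TAC over a mask plus its volume in mL."""
    image4d = np.asarray(image4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image4d.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, frame) image")
    if image4d.shape[:3] != mask.shape:
        raise ValueError("image and mask grids differ")
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("cannot extract a TAC from an empty mask")
    values = image4d[mask].mean(axis=0)
    volume_ml = n_vox * voxel_size_mm**3 / 1000.0
    return TimeActivityCurve(schedule, values, label=label), volume_ml


def save_nifti(path, array: np.ndarray, voxel_size_mm: float) -> None:
    """Write an array as NIfTI-1 with isotropic voxel size in the header."""
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI-1 file; returns (array, isotropic voxel size in mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-6:
        raise ValueError("expected isotropic voxels")
    return np.asarray(img.dataobj), float(zooms[0])
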