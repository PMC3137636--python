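"""Cell detection in correlated volumes via the soft maximum filter.

Cell peaks in a correlated volume vary in height, so a plain global
threshold cannot separate them from the background.  The detector instead
keeps every voxel whose intensity comes within ``soft_thresh`` of the
maximum over an anisotropic neighborhood around it (the "soft" local-maximum
mask), restores the original intensities inside that mask, and finally
discards the low background maxima with ``noise_thresh``.  Connected
foreground components (26-connectivity) are the detected objects: isolated
cells, or conjoined cells merged into one object when closer than the
neighborhood extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Volume
from .correlation import CorrelatedVolume

__all__ = [
    "DetectionParams",
    "DetectedObject",
    "max_filter",
    "soft_max_mask",
    "segment",
    "label_objects",
    "detect_cells",
]

#: 26-connectivity structuring element for component labeling.
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DetectionParams:
    """Parameters of the soft-max detector.

    neighborhood : (nx, ny, nz) full window extents in voxels; the default
        20x20x10 matches one cell volume at the anisotropic acquisition
        resolution, so conjoined cells merge into a single object.
    soft_thresh : leniency with which a voxel counts as a local maximum
        (default 5 on the 8-bit scale).
    noise_thresh : minimal intensity of a cell peak (default 120 on the
        8-bit scale); lower local maxima are background texture.
    """

    neighborhood: tuple[int, int, int] = (20, 20, 10)
    soft_thresh: float = 5.0
    noise_thresh: float = 120.0

    def __post_init__(self) -> None:
        if any(int(n) < 1 for n in self.neighborhood):
            raise ValueError("neighborhood extents must be >= 1")
        if self.soft_thresh < 0:
            raise ValueError("soft_thresh must be >= 0")
        if not (0 < self.noise_thresh <= 255):
            raise ValueError("noise_thresh must lie in (0, 255]")


@dataclass
class DetectedObject:
    """A connected foreground component interpreted as one (or conjoined) cell(s)."""

    label: int
    voxels: frozenset  # of (z, y, x) index tuples
    centroid: tuple[float, float, float]  # continuous (x, y, z)
    peak_intensity: float

    def contains_position(self, position) -> bool:
        """True if the rounded (x, y, z) position indexes a member voxel."""
        x, y, z = position
        return (int(round(z)), int(round(y)), int(round(x))) in self.voxels


def max_filter(volume: Volume | np.ndarray, neighborhood=(20, 20, 10)) -> np.ndarray:
    """Anisotropic moving-maximum filter.

    ``neighborhood`` is given as (nx, ny, nz) full extents.  Windows are
    truncated at the volume faces (no padding is invented: replicate-edge
    padding is exactly the truncated-window maximum).  An even extent places
    its extra voxel toward lower indices.
    """
    data = np.asarray(volume.data if isinstance(volume, Volume) else volume)
    nx, ny, nz = (int(n) for n in neighborhood)
    if min(nx, ny, nz) < 1:
        raise ValueError("neighborhood extents must be >= 1")
    # scipy centers a size-n window at index n//2, i.e. the extra voxel of an
    # even window sits at lower indices, matching the stated tie rule.
    return ndimage.maximum_filter(data, size=(nz, ny, nx), mode="nearest")


def soft_max_mask(volume, maxvol: np.ndarray, soft_thresh: float = 5.0) -> np.ndarray:
    """Binary mask of voxels within ``soft_thresh`` of their local maximum."""
    data = np.asarray(volume.data if isinstance(volume, Volume) else volume)
    maxvol = np.asarray(maxvol)
    if data.shape != maxvol.shape:
        raise ValueError("volume and max-filtered volume must share a shape")
    return (maxvol - data) <= soft_thresh


def segment(volume: CorrelatedVolume | np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Binary segmentation of cell peaks.

    Composition of the soft-max detector: max filter, leniency mask, mask
    multiplication (softMax), noise threshold.  Returns a boolean array.
    """
    params = params or DetectionParams()
    data = np.asarray(volume.data if isinstance(volume, Volume) else volume)
    maxvol = max_filter(data, params.neighborhood)
    mask = soft_max_mask(data, maxvol, params.soft_thresh)
    soft_max = data * mask
    return soft_max >= params.noise_thresh


def label_objects(binary: np.ndarray) -> list[DetectedObject]:
    """Label 26-connected components of a binary volume.

    The centroid is the arithmetic mean of member voxel coordinates,
    reported as continuous (x, y, z); ``peak_intensity`` is filled by
    :func:`detect_cells`.
    """
    binary = np.asarray(binary).astype(bool)
    labeled, n = ndimage.label(binary, structure=_STRUCTURE_26)
    objects: list[DetectedObject] = []
    for lab in range(1, n + 1):
        zz, yy, xx = np.nonzero(labeled == lab)
        centroid = (float(xx.mean()), float(yy.mean()), float(zz.mean()))
        voxels = frozenset(zip(zz.tolist(), yy.tolist(), xx.tolist()))
        objects.append(
            DetectedObject(label=lab, voxels=voxels, centroid=centroid, peak_intensity=0.0)
        )
    return objects


def detect_cells(volume: CorrelatedVolume, params: DetectionParams | None = None) -> list[DetectedObject]:
    """Detect all distinguishable cell peaks in a correlated volume."""
    params = params or DetectionParams()
    data = np.asarray(volume.data if isinstance(volume, Volume) else volume)
    binary = segment(data, params)
    objects = label_objects(binary)
    for obj in objects:
        obj.peak_intensity = float(max(data[v] for v in obj.voxels))
    return objects
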