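"""Reading, writing and contrast preprocessing of 3D time-lapse volumes.

A time point is one 3D grayscale grid (a Z-stack of phase-contrast slices).
Arrays are indexed ``(z, y, x)`` with 0-based indices throughout the package,
while all user-facing positions are continuous ``(x, y, z)`` voxel
coordinates.  Physical voxel spacing is anisotropic (typically 0.78 µm in X/Y
and 8 µm in Z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "VolumeSequence",
    "read_stack",
    "write_stack",
    "read_sequence",
    "enhance_contrast",
]

#: Default physical voxel spacing (dx, dy, dz) in µm.
DEFAULT_SPACING = (0.78, 0.78, 8.0)

#: Default time between consecutive frames, in minutes.
DEFAULT_FRAME_INTERVAL = 4.0


@dataclass
class Volume:
    """One 3D intensity grid at a single time point.

    Parameters
    ----------
    data : ndarray
        3D array indexed ``(z, y, x)``.
    spacing : tuple of float
        Physical voxel size ``(dx, dy, dz)`` in µm/voxel.
    frame_index : int
        Position of this volume in its time-lapse sequence (0-based).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D (z, y, x); got shape {self.data.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values; got {self.spacing}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def contains_position(self, position: Sequence[float]) -> bool:
        """True if the continuous (x, y, z) position lies inside the grid."""
        x, y, z = position
        nz, ny, nx = self.data.shape
        return 0 <= x <= nx - 1 and 0 <= y <= ny - 1 and 0 <= z <= nz - 1


@dataclass
class VolumeSequence:
    """A time-ordered list of volumes sharing shape and spacing."""

    volumes: list[Volume]
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for i, vol in enumerate(self.volumes):
            if vol.frame_index != i:
                raise ValueError(
                    f"frame_index values must be consecutive from 0; volume {i} "
                    f"has frame_index {vol.frame_index}"
                )
        if self.volumes:
            shape = self.volumes[0].shape
            spacing = self.volumes[0].spacing
            for vol in self.volumes[1:]:
                if vol.shape != shape or vol.spacing != spacing:
                    raise ValueError("all volumes must share shape and spacing")

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self):
        return iter(self.volumes)

    def __getitem__(self, i: int) -> Volume:
        return self.volumes[i]


def read_stack(path, spacing=DEFAULT_SPACING, frame_index: int = 0) -> Volume:
    """Read a multi-page grayscale TIFF as a Volume.

    Page ``k`` of the TIFF becomes slice ``z = k``; a single-page TIFF yields
    a volume of depth 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF stack: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise ValueError(f"could not read {path} as a TIFF stack: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages (got array of shape {data.shape}); "
            "RGB or inconsistent pages are not supported"
        )
    return Volume(data=data, spacing=tuple(spacing), frame_index=frame_index)


def write_stack(volume: Volume, path) -> None:
    """Write a Volume as a multi-page TIFF readable by :func:`read_stack`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(volume.data))


def read_sequence(
    directory,
    spacing=DEFAULT_SPACING,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    manifest=None,
    pattern: str = "*.tif*",
) -> VolumeSequence:
    """Read a directory of one-TIFF-per-frame stacks as a VolumeSequence.

    Filenames sorted lexicographically define frame order unless a manifest
    (iterable of ``(frame_index, filename)`` or a CSV path with those two
    columns) overrides it.
    """
    directory = Path(directory)
    if manifest is None:
        paths = sorted(directory.glob(pattern))
    else:
        if isinstance(manifest, (str, Path)):
            import csv

            with open(manifest, newline="") as fh:
                rows = [(int(r[0]), r[1]) for r in csv.reader(fh) if r and r[0].strip().isdigit()]
        else:
            rows = [(int(i), str(name)) for i, name in manifest]
        rows.sort()
        paths = [directory / name for _, name in rows]
    if not paths:
        raise FileNotFoundError(f"no TIFF stacks found in {directory}")
    volumes = [read_stack(p, spacing=spacing, frame_index=i) for i, p in enumerate(paths)]
    return VolumeSequence(volumes=volumes, frame_interval=frame_interval)


def enhance_contrast(
    volume: Volume, low_percentile: float = 0.01, high_percentile: float = 0.99
) -> Volume:
    """Percentile-clip linear contrast stretch to the 8-bit range.

    Intensities are clipped at the ``low_percentile`` and ``high_percentile``
    quantiles of the whole volume and rescaled linearly to [0, 255].  This is
    the contrast boost that suppresses the collagen-gel background texture
    while saturating the bright cell bodies; it is order-preserving inside
    the clip window.

    A constant-intensity volume has no contrast to stretch: it is returned as
    all zeros with a warning.
    """
    if not (0 <= low_percentile < high_percentile <= 1):
        raise ValueError("percentiles must satisfy 0 <= low < high <= 1")
    data = np.asarray(volume.data, dtype=np.float64)
    lo = float(np.quantile(data, low_percentile))
    hi = float(np.quantile(data, high_percentile))
    if hi <= lo:
        warnings.warn(
            "volume has no contrast inside the percentile window; returning zeros",
            stacklevel=2,
        )
        out = np.zeros_like(data, dtype=np.uint8)
    else:
        out = np.clip(data, lo, hi)
        out = (out - lo) * (255.0 / (hi - lo))
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return replace(volume, data=out)
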