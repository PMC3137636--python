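"""Template-matching preprocessing of volumes.

Phase-contrast cells appear as a bright focal disk flanked by off-focus
cone-like halos.  Cross-correlating every volume with a small subvolume
cropped around one isolated cell (the template) turns each cell into a
single smooth correlation blob whose peak sits on the cell center, which is
what makes the downstream peak detection and mean-shift convergence robust.

The correlation is the raw product sum

    Ic(v) = sum_k I(v + k - c) * T(k)

where ``T`` is the template and ``c`` its center offset; no mean subtraction
and no local-energy normalization are applied.  It is evaluated with FFTs
(zero-padded linear correlation, cropped back to the input shape) and the
result is rescaled per volume to the 8-bit range so that the fixed
downstream thresholds apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .volume_io import Volume

__all__ = [
    "CellTemplate",
    "CorrelatedVolume",
    "extract_template",
    "correlate_raw",
    "correlate_volume",
]


@dataclass
class CellTemplate:
    """A small 3D matched-filter subvolume.

    ``data`` is indexed (z, y, x); ``center_offset`` is the (z, y, x) voxel
    treated as the template's center (default: the geometric middle,
    ``size // 2`` per axis).
    """

    data: np.ndarray
    center_offset: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("template must be 3D (z, y, x)")
        if np.any(self.data < 0):
            raise ValueError("template intensities must be nonnegative")
        if self.center_offset is None:
            self.center_offset = tuple(s // 2 for s in self.data.shape)
        c = self.center_offset
        if any(not (0 <= c[a] < self.data.shape[a]) for a in range(3)):
            raise ValueError("center_offset must index a voxel of the template")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CorrelatedVolume(Volume):
    """A volume of correlation blobs, same geometry as its source Volume."""

    provenance: dict | None = None


def extract_template(volume: Volume, center: Sequence[float], size: Sequence[int]) -> CellTemplate:
    """Crop a template box from a volume.

    ``center`` is an (x, y, z) voxel position and ``size`` an (sx, sy, sz)
    box extent.  The box must lie fully inside the volume; boxes crossing a
    face are rejected rather than padded.
    """
    size_xyz = tuple(int(s) for s in size)
    if any(s < 1 for s in size_xyz):
        raise ValueError("template size must be positive in every dimension")
    center_zyx = tuple(int(round(c)) for c in reversed(tuple(center)))
    size_zyx = tuple(reversed(size_xyz))
    shape = volume.data.shape
    start = tuple(c - s // 2 for c, s in zip(center_zyx, size_zyx))
    stop = tuple(a + s for a, s in zip(start, size_zyx))
    if any(a < 0 or b > n for a, b, n in zip(start, stop, shape)):
        raise ValueError(
            f"template box {size_xyz} centered at {tuple(center)} crosses the volume boundary"
        )
    crop = np.asarray(
        volume.data[start[0]:stop[0], start[1]:stop[1], start[2]:stop[2]], dtype=np.float64
    )
    return CellTemplate(data=crop)


def correlate_raw(data: np.ndarray, template: CellTemplate) -> np.ndarray:
    """Unnormalized linear cross-correlation, same shape as ``data``.

    Output voxel ``v`` holds ``sum_k data[v + k - c] * T[k]`` with zero
    padding outside the volume, so a blob peak coincides with the matched
    cell's center.
    """
    data = np.asarray(data, dtype=np.float64)
    t = template.data
    if any(ts >= ds for ts, ds in zip(t.shape, data.shape)):
        raise ValueError(
            f"template shape {t.shape} must be smaller than volume shape {data.shape}"
        )
    full = fftconvolve(data, t[::-1, ::-1, ::-1], mode="full")
    # full[j] = sum_k data[j - (M-1) + k] * T[k]; want j = v + (M-1) - c.
    start = tuple(m - 1 - c for m, c in zip(t.shape, template.center_offset))
    sl = tuple(slice(s, s + n) for s, n in zip(start, data.shape))
    return full[sl]


def correlate_volume(
    volume: Volume, template: CellTemplate, rescale: bool = True
) -> CorrelatedVolume:
    """Correlate a volume with a cell template.

    The raw correlation is linearly rescaled per volume to [0, 255] (kept as
    floats to preserve the smooth gradients the mean-shift kernels climb).
    """
    corr = correlate_raw(volume.data, template)
    if rescale:
        lo = corr.min()
        hi = corr.max()
        if hi > lo:
            corr = (corr - lo) * (255.0 / (hi - lo))
        else:
            corr = np.zeros_like(corr)
    return CorrelatedVolume(
        data=corr,
        spacing=volume.spacing,
        frame_index=volume.frame_index,
        provenance={"source_frame": volume.frame_index, "template_shape": template.shape},
    )
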