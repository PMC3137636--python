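"""Mean-shift convergence of flat-kernel cell trackers.

Each tracked cell carries a mean-shift kernel: a flat (uniform) cube of
voxels, 7 per side by default, that is repeatedly moved to the
intensity-weighted mean of the correlated volume under it until the shift
falls below a small tolerance (0.01 voxel).  In a correlated volume this
converges onto the nearest blob peak, i.e. the cell center.  Trackers whose
converged position comes within fixed margins of the volume faces (10
voxels in X/Y, 5 slices in Z) are stopped, since a cell partially outside
the field cannot be followed reliably.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np

from .volume_io import Volume

__all__ = [
    "MeanShiftParams",
    "Tracker",
    "kernel_mean",
    "mean_shift_converge",
    "near_boundary",
]

ACTIVE = "active"
STOPPED_COLLISION = "stopped_collision"
STOPPED_BOUNDARY = "stopped_boundary"
REMOVED_PARASITE = "removed_parasite"
STOPPED_END = "stopped_end"

TRACKER_STATES = (ACTIVE, STOPPED_COLLISION, STOPPED_BOUNDARY, REMOVED_PARASITE, STOPPED_END)


@dataclass
class MeanShiftParams:
    kernel_size: int = 7
    tolerance: float = 0.01
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Tracker:
    """A live mean-shift kernel with identity and continuous position."""

    id: int
    position: tuple[float, float, float]  # continuous (x, y, z)
    birth_frame: int
    state: str = ACTIVE

    def __post_init__(self) -> None:
        if self.state not in TRACKER_STATES:
            raise ValueError(f"unknown tracker state {self.state!r}")


def _axis_coverage(p: float, half: float, n: int):
    """Per-voxel coverage weights of a kernel interval [p-half, p+half].

    Returns ``(first_index, weights)`` where ``weights[k]`` is the length of
    the overlap between voxel ``first_index + k`` (which spans index ±0.5)
    and the kernel interval, truncated at the volume border.  Edge voxels
    get fractional weight, so the kernel support slides continuously with
    ``p`` instead of snapping to integer centers (snapping creates spurious
    fixed points that freeze a tracker short of its peak on wide blobs).
    """
    a, b = p - half, p + half
    lo = max(0, int(math.floor(a + 0.5)))
    hi = min(n - 1, int(math.ceil(b - 0.5)))
    if hi < lo:
        lo = hi = min(max(int(round(p)), 0), n - 1)
    idx = np.arange(lo, hi + 1)
    cov = np.minimum(b, idx + 0.5) - np.maximum(a, idx - 0.5)
    return lo, np.clip(cov, 0.0, 1.0)


def kernel_mean(volume, center, kernel_size: int = 7):
    """Intensity-weighted mean position under a flat kernel.

    The kernel is a cube of side ``kernel_size`` voxels centered on the
    continuous position: voxels fully inside count once, voxels straddling
    the kernel face count by their overlap fraction, and the window is
    truncated at the volume borders.  Each voxel is weighted by its
    correlated intensity times its coverage.

    Returns ``(mean_xyz, ok)`` where ``ok`` is False when every weight in
    the window is zero (the center is then returned unchanged).
    """
    data = np.asarray(volume.data if isinstance(volume, Volume) else volume, dtype=np.float64)
    x, y, z = (float(c) for c in center)
    half = kernel_size / 2.0
    z0, wz = _axis_coverage(z, half, data.shape[0])
    y0, wy = _axis_coverage(y, half, data.shape[1])
    x0, wx = _axis_coverage(x, half, data.shape[2])
    block = data[z0:z0 + len(wz), y0:y0 + len(wy), x0:x0 + len(wx)]
    w = block * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
    total = w.sum()
    if total <= 0:
        return (x, y, z), False
    zz = np.arange(z0, z0 + len(wz), dtype=np.float64)
    yy = np.arange(y0, y0 + len(wy), dtype=np.float64)
    xx = np.arange(x0, x0 + len(wx), dtype=np.float64)
    mz = float((w.sum(axis=(1, 2)) * zz).sum() / total)
    my = float((w.sum(axis=(0, 2)) * yy).sum() / total)
    mx = float((w.sum(axis=(0, 1)) * xx).sum() / total)
    return (mx, my, mz), True


def mean_shift_converge(volume, start, params: MeanShiftParams | None = None):
    """Iterate the kernel mean until the shift falls below tolerance.

    Returns ``(position, n_iterations, converged)``.  The returned position
    ``p*`` satisfies ``|kernel_mean(p*) - p*| < tolerance`` when converged
    (the loop stops at the position whose own kernel mean moved less than
    the tolerance, and returns that position).  Starts in a zero-intensity
    region return the start unconverged.
    """
    params = params or MeanShiftParams()
    p = tuple(float(c) for c in start)
    for it in range(1, params.max_iterations + 1):
        m, ok = kernel_mean(volume, p, params.kernel_size)
        if not ok:
            return p, it, False
        shift = float(np.sqrt(sum((a - b) ** 2 for a, b in zip(m, p))))
        if shift < params.tolerance:
            return p, it, True
        p = m
    return p, params.max_iterations, False


def near_boundary(position, shape, margins=(10.0, 5.0)) -> bool:
    """True if an (x, y, z) position is within the stop margins of a face.

    ``shape`` is the (nz, ny, nx) volume shape; ``margins`` is
    (xy_margin, z_margin) in voxels/slices, compared inclusively.
    """
    x, y, z = position
    nz, ny, nx = shape
    xy_margin, z_margin = margins
    return (
        x <= xy_margin
        or y <= xy_margin
        or x >= nx - 1 - xy_margin
        or y >= ny - 1 - xy_margin
        or z <= z_margin
        or z >= nz - 1 - z_margin
    )
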