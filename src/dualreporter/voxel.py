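"""Voxel-wise Pearson correlation maps of two-channel confocal stacks.

To ask where in a biofilm thin-section two reporters are expressed
together, the co-registered two-channel stack is tiled into cubic voxels
(default 10 pixels, about 0.80 µm per side at 0.08 µm/pixel) and the
sample Pearson correlation between the two channels' intensities is
computed over each voxel's pixels, then placed at the voxel centroid.
Voxels in no-fluorescence regions are excluded rather than reported as
spurious correlations: a voxel is retained only when at least a minimum
fraction of its pixels (default 10%) exceeds a background threshold in at
least one channel.  Voxels with zero variance in either channel are
likewise excluded (Pearson is undefined there).  Correlations are
computed on raw intensities — no background subtraction — and are
invariant to positive affine rescaling of either channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

DEFAULT_EDGE = 10
DEFAULT_PIXEL_SIZE_UM = 0.08
DEFAULT_MIN_FLUOR_FRACTION = 0.1

REASON_RETAINED = ""
REASON_NO_FLUORESCENCE = "no_fluorescence"
REASON_CONSTANT = "constant_channel"


class VoxelError(ValueError):
    """Invalid stack, grid or threshold input."""


@dataclass(frozen=True)
class ConfocalStack:
    """Two co-registered intensity arrays, (z, y, x) or single-plane (y, x).

    2D inputs are promoted to a single z-plane; ``is_planar`` records it so
    voxels become in-plane squares (edge 1 along z).
    """

    ch1: np.ndarray
    ch2: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    is_planar: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.ch1, dtype=float)
        b = np.asarray(self.ch2, dtype=float)
        if a.shape != b.shape:
            raise VoxelError(f"channel shapes differ: {a.shape} vs {b.shape}")
        if a.ndim == 2:
            object.__setattr__(self, "is_planar", True)
            a = a[None]
            b = b[None]
        elif a.ndim != 3:
            raise VoxelError(f"expected 2D or 3D arrays, got ndim={a.ndim}")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise VoxelError("intensities must be finite")
        if a.min() < 0 or b.min() < 0:
            raise VoxelError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise VoxelError("pixel size must be positive")
        object.__setattr__(self, "ch1", a)
        object.__setattr__(self, "ch2", b)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ch1.shape


@dataclass(frozen=True)
class VoxelGrid:
    """Partition of a stack into non-overlapping cubic voxels.

    ``edge`` is the per-axis voxel edge (z, y, x) in pixels; trailing
    pixels that do not fill a whole voxel are dropped, so the grid covers
    ``n_voxels * edge`` pixels along each axis.
    """

    stack_shape: tuple[int, int, int]
    edge: tuple[int, int, int]
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(s // e for s, e in zip(self.stack_shape, self.edge))

    @property
    def n_voxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    def centroids_px(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis centroid coordinates (pixels) of the voxel index ranges."""
        return tuple(
            np.arange(n) * e + (e - 1) / 2.0
            for n, e in zip(self.shape, self.edge)
        )

    def centroids_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(c * self.pixel_size_um for c in self.centroids_px())


@dataclass(frozen=True)
class CorrelationMap:
    """Per-voxel Pearson r placed at voxel centroids.

    ``r`` has the grid's voxel shape with NaN at excluded voxels; ``reason``
    is an equally shaped string array ('' for retained voxels,
    'no_fluorescence' or 'constant_channel' otherwise).  ``axis_labels``
    annotates the in-plane axes from colony center to periphery
    ('Center' -> 'End').
    """

    r: np.ndarray
    reason: np.ndarray
    grid: VoxelGrid
    background_threshold: float
    min_fluor_fraction: float
    axis_labels: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"x": ("Center", "End")}
    )

    @property
    def retained(self) -> np.ndarray:
        return self.reason == REASON_RETAINED

    def to_frame(self) -> pd.DataFrame:
        nz, ny, nx = self.grid.shape
        cz, cy, cx = self.grid.centroids_px()
        uz, uy, ux = self.grid.centroids_um()
        iz, iy, ix = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
        flat = lambda a: a.ravel()
        return pd.DataFrame({
            "voxel_id": np.arange(self.grid.n_voxels),
            "cz": flat(iz), "cy": flat(iy), "cx": flat(ix),
            "centroid_px_z": cz[flat(iz)], "centroid_px_y": cy[flat(iy)],
            "centroid_px_x": cx[flat(ix)],
            "centroid_um_z": uz[flat(iz)], "centroid_um_y": uy[flat(iy)],
            "centroid_um_x": ux[flat(ix)],
            "r": flat(self.r),
            "excluded": flat(~self.retained),
            "reason": flat(self.reason),
        })


def tile_voxels(stack: ConfocalStack, edge: int = DEFAULT_EDGE) -> VoxelGrid:
    """Partition the stack into cubic voxels of ``edge`` pixels per side.

    Trailing partial voxels are dropped (correlations over unequal pixel
    counts would not be comparable).  Planar (single z-plane) stacks use
    in-plane ``edge x edge`` squares.
    """
    if edge < 2:
        raise VoxelError(f"voxel edge must be >= 2 pixels, got {edge}")
    ez = 1 if stack.is_planar else edge
    edges = (ez, edge, edge)
    for dim, e, name in zip(stack.shape, edges, "zyx"):
        if e > dim:
            raise VoxelError(f"voxel edge {e} exceeds stack extent {dim} along {name}")
    return VoxelGrid(stack_shape=stack.shape, edge=edges,
                     pixel_size_um=stack.pixel_size_um)


def _voxel_view(arr: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Reshape to (nz, ny, nx, pixels_per_voxel), dropping trailing pixels."""
    nz, ny, nx = grid.shape
    ez, ey, ex = grid.edge
    cropped = arr[: nz * ez, : ny * ey, : nx * ex]
    blocks = cropped.reshape(nz, ez, ny, ey, nx, ex)
    return blocks.transpose(0, 2, 4, 1, 3, 5).reshape(nz, ny, nx, ez * ey * ex)


def voxel_pearson(
    stack: ConfocalStack,
    grid: VoxelGrid | None = None,
    background_threshold: float = 0.0,
    min_fluor_fraction: float = DEFAULT_MIN_FLUOR_FRACTION,
) -> CorrelationMap:
    """Compute the per-voxel Pearson correlation between the two channels.

    For each voxel, r is the sample correlation over its pixels' (ch1,
    ch2) pairs.  A voxel is excluded as ``no_fluorescence`` when fewer than
    ``min_fluor_fraction`` of its pixels exceed ``background_threshold`` in
    at least one channel, and as ``constant_channel`` when either channel
    has zero variance within it; excluded voxels carry NaN.
    """
    if background_threshold < 0:
        raise VoxelError("background threshold must be non-negative")
    if not 0.0 <= min_fluor_fraction <= 1.0:
        raise VoxelError("min_fluor_fraction must be in [0, 1]")
    if grid is None:
        grid = tile_voxels(stack)
    if grid.stack_shape != stack.shape:
        raise VoxelError("grid was derived from a stack of different shape")

    v1 = _voxel_view(stack.ch1, grid)
    v2 = _voxel_view(stack.ch2, grid)

    above = (v1 > background_threshold) | (v2 > background_threshold)
    fluor_frac = above.mean(axis=-1)

    m1 = v1.mean(axis=-1, keepdims=True)
    m2 = v2.mean(axis=-1, keepdims=True)
    d1 = v1 - m1
    d2 = v2 - m2
    var1 = (d1 * d1).sum(axis=-1)
    var2 = (d2 * d2).sum(axis=-1)
    cov = (d1 * d2).sum(axis=-1)

    constant = (var1 == 0) | (var2 == 0)
    no_fluor = fluor_frac < min_fluor_fraction

    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var1 * var2)
    r = np.clip(r, -1.0, 1.0)

    reason = np.full(grid.shape, REASON_RETAINED, dtype=object)
    reason[constant] = REASON_CONSTANT
    reason[no_fluor] = REASON_NO_FLUORESCENCE   # no-fluorescence takes precedence
    r = np.where(reason == REASON_RETAINED, r, np.nan)
    return CorrelationMap(r=r, reason=reason, grid=grid,
                          background_threshold=background_threshold,
                          min_fluor_fraction=min_fluor_fraction)


def cross_section(cmap: CorrelationMap, axis: str, index: int) -> np.ndarray:
    """Extract a 2D slice of the correlation map through one voxel plane.

    ``axis`` is one of 'z', 'y', 'x' (voxel indices); excluded voxels
    appear as NaN so renderers can leave them transparent.
    """
    axes = {"z": 0, "y": 1, "x": 2}
    if axis not in axes:
        raise VoxelError(f"axis must be one of {sorted(axes)}, got {axis!r}")
    ax = axes[axis]
    if not 0 <= index < cmap.grid.shape[ax]:
        raise VoxelError(
            f"index {index} out of range for axis {axis!r} with {cmap.grid.shape[ax]} voxels"
        )
    return np.take(cmap.r, index, axis=ax)


def estimate_background(
    stack: ConfocalStack,
    region: tuple[slice, slice, slice] | np.ndarray,
    n_sd: float = 2.0,
) -> float:
    """Background threshold = mean + ``n_sd`` * sd over a no-signal region.

    ``region`` is a (z, y, x) slice triple (corner box) or a boolean mask;
    intensities from both channels are pooled.
    """
    if isinstance(region, np.ndarray):
        if region.shape != stack.shape:
            raise VoxelError("background mask shape must match stack")
        vals = np.concatenate([stack.ch1[region], stack.ch2[region]])
    else:
        vals = np.concatenate([stack.ch1[region].ravel(), stack.ch2[region].ravel()])
    if vals.size == 0:
        raise VoxelError("background region is empty")
    return float(vals.mean() + n_sd * vals.std())


def load_stack_tiff(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel_axis: int = 1,
) -> ConfocalStack:
    """Read a two-channel (Z, C, Y, X by default) TIFF/OME-TIFF stack."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 3 and arr.shape[0] == 2:
        ch1, ch2 = arr[0], arr[1]          # CYX single plane
    elif arr.ndim == 4:
        arr = np.moveaxis(arr, channel_axis, 0)
        if arr.shape[0] != 2:
            raise VoxelError(f"expected 2 channels, got {arr.shape[0]}")
        ch1, ch2 = arr[0], arr[1]
    else:
        raise VoxelError(f"unsupported TIFF shape {arr.shape}; need (Z,C,Y,X) or (C,Y,X)")
    return ConfocalStack(ch1=ch1, ch2=ch2, pixel_size_um=pixel_size_um)
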