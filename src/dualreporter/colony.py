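"""Radial fluorescence profiling of colony biofilm images.

The procedure quantifies how reporter expression varies from the colony
center to its edge.  The colony footprint is segmented from the
brightfield channel by thresholding the Laplacian-of-Gaussian response
(both agar and colony are near-uniform, so the response concentrates at
the colony edge).  Each pixel's Euclidean distance to the mask centroid
is divided by the mean centroid-to-boundary distance, turning distance
into a percentage with the average colony edge at 100%.  Distances are
binned (default 1% of radius), the mean fluorescence per bin is taken for
each channel out to 120% — retaining the background just beyond the edge
— and profiles may be normalized per channel for display on a shared axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu


class NoColonyFound(ValueError):
    """No colony-sized component could be segmented from the brightfield."""


class ProfileError(ValueError):
    """Invalid profiling input (shape mismatch, degenerate mask, ...)."""


@dataclass(frozen=True)
class ColonyImage:
    """A colony image: brightfield plus named fluorescence channels."""

    brightfield: np.ndarray
    channels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        bf = np.asarray(self.brightfield)
        if bf.ndim != 2:
            raise ProfileError("brightfield must be a 2D array")
        for name, ch in self.channels.items():
            if np.asarray(ch).shape != bf.shape:
                raise ProfileError(f"channel {name!r} shape differs from brightfield")


@dataclass(frozen=True)
class ColonyMask:
    """Segmented colony footprint with derived geometry.

    ``boundary`` is the ordered (row, col) trace of the footprint outline
    at subpixel precision; ``mean_radius`` is the mean Euclidean distance
    from the centroid to the boundary, the 100% reference of the radial
    scale.
    """

    mask: np.ndarray
    centroid: tuple[float, float]
    boundary: np.ndarray
    mean_radius: float

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RadialDistanceField:
    """Per-pixel distance from the colony centroid, as percent of mean radius."""

    percent: np.ndarray
    centroid: tuple[float, float]
    mean_radius: float


@dataclass(frozen=True)
class RadialProfile:
    """Binned mean intensity versus percent of colony radius.

    ``bins`` are the bin center values (ascending, <= max_percent);
    ``counts`` the pixels per bin; ``means`` maps channel name to the
    per-bin mean intensity.  ``normalization`` records the constant each
    channel was divided by (None if the profile is unnormalized).
    """

    bins: np.ndarray
    counts: np.ndarray
    means: Mapping[str, np.ndarray]
    bin_resolution: float
    max_percent: float
    normalization: Mapping[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {
            "percent_radius": self.bins,
            "n_pixels": self.counts,
        }
        for name, values in self.means.items():
            key = f"norm_mean_{name}" if name in self.normalization else f"mean_{name}"
            data[key] = values
        return pd.DataFrame(data)

    def argmax_bin(self, channel: str) -> float:
        """Bin value (percent radius) at which the channel's mean peaks."""
        return float(self.bins[int(np.argmax(self.means[channel]))])


def mask_colony(
    brightfield: np.ndarray,
    log_sigma: float = 2.0,
    min_area: int = 100,
) -> ColonyMask:
    """Segment the colony footprint from a brightfield image.

    The Laplacian-of-Gaussian magnitude (scale ``log_sigma`` pixels) is
    thresholded by Otsu's method, giving a band along the colony/agar
    edge; morphological closing and hole-filling turn the band into a
    solid footprint.  Because the band straddles the edge, the footprint
    is then trimmed to the LoG zero crossing — the signed response changes
    sign exactly at the intensity step, so band pixels carrying the agar
    side's sign are removed.  The largest connected component
    (8-connected, at least ``min_area`` pixels) is kept.  The centroid is
    the mask's center of mass, the boundary its traced outline, and
    ``mean_radius`` the mean centroid-to-boundary distance.

    Raises :class:`NoColonyFound` on constant images or when no component
    reaches ``min_area``.
    """
    bf = np.asarray(brightfield, dtype=float)
    if bf.ndim != 2:
        raise ProfileError("brightfield must be a 2D array")
    signed = ndi.gaussian_laplace(bf, sigma=log_sigma)
    response = np.abs(signed)
    if not np.any(response > 0) or np.isclose(response.max(), response.min()):
        raise NoColonyFound("constant brightfield image")
    try:
        thresh = threshold_otsu(response)
    except ValueError as exc:  # fewer than two distinct values
        raise NoColonyFound("no colony/agar contrast") from exc

    band = response > thresh
    band = ndi.binary_closing(band, structure=np.ones((3, 3)), iterations=2)
    filled = ndi.binary_fill_holes(band)
    if not filled.any():
        raise NoColonyFound("no component above threshold")

    # Trim the filled footprint to the LoG zero crossing: the signed
    # response flips sign at the intensity step, so the band's agar-side
    # half is the part whose sign matches the agar polarity.
    colony_darker = bf[filled].mean() < bf[~filled].mean() if (~filled).any() else True
    agar_side = band & ((signed < 0) if colony_darker else (signed > 0))
    trimmed = ndi.binary_fill_holes(filled & ~agar_side)

    labels, n_comp = ndi.label(trimmed, structure=np.ones((3, 3)))
    if n_comp == 0:
        raise NoColonyFound("no component above threshold")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise NoColonyFound(f"largest component {int(sizes[best - 1])} px < min_area {min_area}")
    mask = labels == best

    centroid = ndi.center_of_mass(mask)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise NoColonyFound("mask has no traceable boundary")
    boundary = max(contours, key=len)
    radii = np.hypot(boundary[:, 0] - centroid[0], boundary[:, 1] - centroid[1])
    mean_radius = float(radii.mean())
    if mean_radius <= 0:
        raise NoColonyFound("degenerate mask with zero mean radius")
    return ColonyMask(mask=mask, centroid=(float(centroid[0]), float(centroid[1])),
                      boundary=boundary, mean_radius=mean_radius)


def radial_distance_field(
    mask: ColonyMask,
    shape: tuple[int, int] | None = None,
) -> RadialDistanceField:
    """Assign every pixel its distance from the centroid as percent of mean radius.

    All pixels of the frame (inside and outside the colony) are assigned
    ``100 * d(pixel, centroid) / mean_radius``; the downstream cutoff at
    120% keeps the near-edge background and drops the rest.
    """
    if mask.mean_radius <= 0:
        raise ProfileError("degenerate mask: mean radius is zero")
    shape = shape if shape is not None else mask.mask.shape
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dist = np.hypot(rr - mask.centroid[0], cc - mask.centroid[1])
    percent = 100.0 * dist / mask.mean_radius
    return RadialDistanceField(percent=percent, centroid=mask.centroid,
                               mean_radius=mask.mean_radius)


def radial_profile(
    channels: Mapping[str, np.ndarray] | np.ndarray,
    distance_field: RadialDistanceField,
    bin_resolution: float = 1.0,
    max_percent: float = 120.0,
) -> RadialProfile:
    """Bin pixels by rounded radial distance and average each channel per bin.

    Distances (percent of radius) are rounded to the nearest multiple of
    ``bin_resolution`` — the default 1% grid corresponds to rounding the
    edge-normalized distance ratio to two decimals — and the mean signal
    per unique rounded distance is reported, dropping bins beyond
    ``max_percent`` (default 120%, keeping the just-beyond-edge background).
    """
    if isinstance(channels, np.ndarray):
        channels = {"signal": channels}
    if bin_resolution <= 0:
        raise ProfileError("bin_resolution must be positive")
    percent = distance_field.percent
    for name, ch in channels.items():
        if np.asarray(ch).shape != percent.shape:
            raise ProfileError(f"channel {name!r} shape differs from distance field")

    idx = np.rint(percent / bin_resolution).astype(np.int64)
    keep = idx * bin_resolution <= max_percent
    flat = idx[keep].ravel()
    counts = np.bincount(flat)
    present = np.nonzero(counts)[0]
    means = {}
    for name, ch in channels.items():
        sums = np.bincount(flat, weights=np.asarray(ch, dtype=float)[keep].ravel())
        means[name] = sums[present] / counts[present]
    return RadialProfile(
        bins=present.astype(float) * bin_resolution,
        counts=counts[present],
        means=means,
        bin_resolution=bin_resolution,
        max_percent=max_percent,
    )


def normalize_profile(
    profile: RadialProfile,
    mode: str | float | Mapping[str, float] = "max",
) -> RadialProfile:
    """Rescale each channel's binned means to a consistent reference.

    ``mode="max"`` divides each channel by its peak bin mean over bins
    within the colony (<= 100% of radius), putting every channel's peak at
    1.0; a float or a per-channel mapping divides by that fixed constant.
    The constant used is recorded in ``normalization``.
    """
    if profile.bins.size == 0:
        raise ProfileError("cannot normalize an empty profile")
    constants: dict[str, float] = {}
    for name, values in profile.means.items():
        if mode == "max":
            inside = profile.bins <= 100.0
            ref = values[inside] if inside.any() else values
            const = float(np.max(ref))
        elif isinstance(mode, Mapping):
            const = float(mode[name])
        else:
            const = float(mode)
        if const == 0:
            raise ProfileError(f"zero normalization constant for channel {name!r}")
        constants[name] = const
    means = {name: values / constants[name] for name, values in profile.means.items()}
    return replace(profile, means=means, normalization=constants)


def load_colony_tiff(
    path: str | Path,
    channel_names: list[str] | None = None,
) -> ColonyImage:
    """Read a multi-page/multi-channel TIFF into a :class:`ColonyImage`.

    The first page (or the page named ``brightfield``) is the brightfield;
    remaining pages are fluorescence channels.  ``channel_names`` overrides
    the page naming, listing the brightfield name first.
    """
    pages = tifffile.imread(Path(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ProfileError(f"expected 2D or stacked-2D TIFF, got shape {pages.shape}")
    if channel_names is None:
        channel_names = ["brightfield"] + [f"channel_{i}" for i in range(1, pages.shape[0])]
    if len(channel_names) != pages.shape[0]:
        raise ProfileError("channel_names length must match page count")
    return ColonyImage(
        brightfield=pages[0],
        channels={name: pages[i] for i, name in enumerate(channel_names) if i > 0},
    )


def profile_colony(
    image: ColonyImage,
    log_sigma: float = 2.0,
    bin_resolution: float = 1.0,
    max_percent: float = 120.0,
    normalize: str | float | Mapping[str, float] | None = "max",
) -> tuple[ColonyMask, RadialProfile]:
    """End-to-end convenience: mask, distance field, binned (and normalized) profile."""
    mask = mask_colony(image.brightfield, log_sigma=log_sigma)
    dist = radial_distance_field(mask, shape=image.brightfield.shape)
    profile = radial_profile(image.channels, dist, bin_resolution=bin_resolution,
                             max_percent=max_percent)
    if normalize is not None:
        profile = normalize_profile(profile, mode=normalize)
    return mask, profile
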