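"""Seeded synthetic-data generators with ground truth.

Three generators emulate the statistical structure the analysis pipelines
assume, so every downstream stage can be tested against a known answer:

- :func:`make_colony` — a multi-channel colony image: a brightfield channel
  with colony/agar contrast and fluorescence channels whose mean intensity
  is a chosen function of percent-of-colony-radius (uniform, center-peaked,
  edge-peaked, or a ring), emulating interior- versus periphery-enriched
  expression patterns.
- :func:`make_stack` — a two-channel confocal stack whose pixelwise
  channel pair realizes a target Pearson correlation field ``rho(z, y, x)``,
  with an optional no-fluorescence background region.
- :func:`make_flow` — a two-channel flow-cytometry sample drawn from a
  four-component mixture (neither / mTurq-only / YPet-only / both) with
  log-normal intensity clusters; :func:`make_control` draws the matching
  non-fluorescent control.

Every generator takes a seed and is bit-reproducible; ground truth (mask,
per-bin profile, rho field, cluster labels) is returned alongside the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import tifffile

from dualreporter.colony import ColonyImage
from dualreporter.flow import FlowSample
from dualreporter.voxel import ConfocalStack

U16_MAX = 65535


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


# --------------------------------------------------------------------------
# Radial intensity functions, defined on percent-of-radius in [0, 120]

@dataclass(frozen=True)
class Uniform:
    """Constant expression level across the colony."""
    level: float = 10000.0

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(p, dtype=float), self.level)


@dataclass(frozen=True)
class CenterPeaked:
    """Expression concentrated in the colony interior (Gaussian falloff)."""
    amplitude: float = 10000.0
    sigma: float = 35.0   # percent of radius
    baseline: float = 0.0

    def __call__(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.baseline + self.amplitude * np.exp(-0.5 * (p / self.sigma) ** 2)


@dataclass(frozen=True)
class EdgePeaked:
    """Expression concentrated at the colony periphery (peak at 100%)."""
    amplitude: float = 10000.0
    sigma: float = 15.0
    baseline: float = 0.0

    def __call__(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.baseline + self.amplitude * np.exp(-0.5 * ((p - 100.0) / self.sigma) ** 2)


@dataclass(frozen=True)
class Ring:
    """Annulus of expression centered at ``center`` percent of radius."""
    center: float = 50.0
    width: float = 5.0
    amplitude: float = 10000.0
    baseline: float = 0.0

    def __call__(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.baseline + self.amplitude * np.exp(-0.5 * ((p - self.center) / self.width) ** 2)


RadialFunction = Callable[[np.ndarray], np.ndarray]


# --------------------------------------------------------------------------
# Colony images

@dataclass(frozen=True)
class ColonySpec:
    """Specification of one synthetic colony image.

    The default frame matches the 1388x1040-pixel acquisition format of
    stereomicroscope colony images; tests typically use smaller frames.
    Boundary irregularity is a low-order Fourier perturbation of the
    radius (modes 2-5), with peak amplitude ``boundary_amplitude`` as a
    fraction of the mean radius — colonies are not perfect disks.
    """

    shape: tuple[int, int] = (1040, 1388)
    center: tuple[float, float] | None = None     # (row, col); default image center
    radius: float = 300.0                          # mean radius, pixels
    boundary_amplitude: float = 0.05               # fraction of radius
    background: float = 500.0                      # fluorescence background level
    channels: Mapping[str, RadialFunction] = field(
        default_factory=lambda: {"YPet": CenterPeaked(), "mTurq": EdgePeaked()}
    )
    noise_sd: float = 100.0
    agar_level: float = 30000.0                    # brightfield
    colony_level: float = 12000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SpecError("radius must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise sd must be non-negative")
        r_max = self.radius * (1 + self.boundary_amplitude)
        if 2 * r_max > min(self.shape):
            raise SpecError(
                f"colony diameter {2 * r_max:.0f} px exceeds image extent {min(self.shape)} px"
            )


@dataclass(frozen=True)
class SyntheticColony:
    """A generated colony image bundled with its ground truth."""

    image: ColonyImage
    true_mask: np.ndarray                 # bool, colony footprint
    true_center: tuple[float, float]
    true_radius: float                    # mean center-to-edge distance
    true_percent: np.ndarray              # per-pixel percent-of-radius field
    true_profile: pd.DataFrame            # percent_radius + per-channel noise-free mean
    spec: ColonySpec


def _boundary_perturbation(rng: np.random.Generator, amplitude: float) -> Callable[[np.ndarray], np.ndarray]:
    # Random-phase modes 2..5, rescaled so the peak deviation equals `amplitude`.
    ks = np.arange(2, 6)
    coef = rng.normal(size=ks.size)
    phase = rng.uniform(0, 2 * np.pi, size=ks.size)
    theta_dense = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    dense = (coef[:, None] * np.cos(ks[:, None] * theta_dense[None, :] + phase[:, None])).sum(0)
    peak = np.abs(dense).max()
    scale = 0.0 if peak == 0 or amplitude == 0 else amplitude / peak

    def pert(theta: np.ndarray) -> np.ndarray:
        return scale * (coef[:, None] * np.cos(ks[:, None] * theta[None, :] + phase[:, None])).sum(0)

    return pert


def _quantize(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, U16_MAX).astype(np.uint16)


def make_colony(spec: ColonySpec) -> SyntheticColony:
    """Render a colony image from its spec, with ground truth attached.

    Fluorescence channels realize ``background + f(percent_radius)`` inside
    the colony footprint and ``background`` outside, plus Gaussian noise,
    quantized to unsigned 16-bit.  The ground-truth radial profile bins the
    noise-free signal on the same 1% grid the analysis uses, out to 120%.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    center = spec.center if spec.center is not None else ((rows - 1) / 2.0, (cols - 1) / 2.0)

    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = rr - center[0]
    dx = cc - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    pert = _boundary_perturbation(rng, spec.boundary_amplitude)
    local_radius = spec.radius * (1.0 + pert(theta.ravel()).reshape(theta.shape))
    mask = dist <= local_radius
    percent = 100.0 * dist / spec.radius

    brightfield = np.where(mask, spec.colony_level, spec.agar_level).astype(float)
    if spec.noise_sd > 0:
        brightfield += rng.normal(0, spec.noise_sd, size=brightfield.shape)

    channels: dict[str, np.ndarray] = {}
    clean: dict[str, np.ndarray] = {}
    for name, f in spec.channels.items():
        signal = np.full(spec.shape, float(spec.background))
        signal[mask] += f(percent[mask])
        clean[name] = signal
        noisy = signal if spec.noise_sd == 0 else signal + rng.normal(0, spec.noise_sd, size=signal.shape)
        channels[name] = _quantize(noisy)

    # Noise-free profile on the analysis' own 1% bins, limited to 120%.
    bin_idx = np.rint(percent).astype(int)
    keep = bin_idx <= 120
    flat_idx = bin_idx[keep].ravel()
    n_per = np.bincount(flat_idx)
    present = np.nonzero(n_per)[0]
    prof = {"percent_radius": present.astype(float), "n_pixels": n_per[present]}
    for name, sig in clean.items():
        sums = np.bincount(flat_idx, weights=sig[keep].ravel())
        prof[f"mean_{name}"] = sums[present] / n_per[present]
    true_profile = pd.DataFrame(prof)

    image = ColonyImage(brightfield=_quantize(brightfield), channels=channels)
    return SyntheticColony(
        image=image,
        true_mask=mask,
        true_center=center,
        true_radius=spec.radius,
        true_percent=percent,
        true_profile=true_profile,
        spec=spec,
    )


# --------------------------------------------------------------------------
# Confocal stacks

@dataclass(frozen=True)
class StackSpec:
    """Specification of a two-channel stack with a target correlation field.

    ``rho`` may be a scalar or an array broadcastable to ``shape``; within
    the foreground, each pixel's channel pair is drawn from a bivariate
    normal with that pixel's correlation.  ``background_mask`` marks a
    no-fluorescence region where both channels sit near zero.
    """

    shape: tuple[int, int, int] = (40, 120, 120)   # (z, y, x)
    rho: float | np.ndarray = 0.7
    ch1_mean: float = 10000.0
    ch1_sd: float = 2000.0
    ch2_mean: float = 8000.0
    ch2_sd: float = 1500.0
    background_mask: np.ndarray | None = None
    background_level: float = 20.0
    background_sd: float = 5.0
    pixel_size_um: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise SpecError("stack dimensions must be positive")
        rho = np.asarray(self.rho, dtype=float)
        if np.any(np.abs(rho) > 1):
            raise SpecError("|rho| must be <= 1 everywhere")
        if self.background_mask is not None and self.background_mask.shape != self.shape:
            raise SpecError("background_mask shape must match stack shape")


@dataclass(frozen=True)
class SyntheticStack:
    stack: ConfocalStack
    true_rho: np.ndarray                  # per-pixel target correlation
    background_mask: np.ndarray           # bool, True = no fluorescence
    spec: StackSpec


def make_stack(spec: StackSpec) -> SyntheticStack:
    """Draw a two-channel stack realizing the target correlation field.

    Channel 1 is ``mean1 + sd1*z1`` and channel 2 is
    ``mean2 + sd2*(rho*z1 + sqrt(1-rho^2)*z2)`` with independent standard
    normals z1, z2, so the pixelwise pair has correlation exactly ``rho``
    and, at ``|rho| = 1`` the second channel is an affine function of the
    first.  Intensities are kept on a floating-point scale (clipped at
    zero) so exact-correlation constructions stay exact.
    """
    rng = np.random.default_rng(spec.seed)
    rho = np.broadcast_to(np.asarray(spec.rho, dtype=float), spec.shape)
    z1 = rng.standard_normal(spec.shape)
    z2 = rng.standard_normal(spec.shape)
    latent2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    ch1 = spec.ch1_mean + spec.ch1_sd * z1
    ch2 = spec.ch2_mean + spec.ch2_sd * latent2

    bg = spec.background_mask
    if bg is None:
        bg = np.zeros(spec.shape, dtype=bool)
    if bg.any():
        ch1[bg] = spec.background_level + spec.background_sd * rng.standard_normal(bg.sum())
        ch2[bg] = spec.background_level + spec.background_sd * rng.standard_normal(bg.sum())

    ch1 = np.clip(ch1, 0, None)
    ch2 = np.clip(ch2, 0, None)
    stack = ConfocalStack(ch1=ch1, ch2=ch2, pixel_size_um=spec.pixel_size_um)
    return SyntheticStack(stack=stack, true_rho=np.array(rho), background_mask=bg, spec=spec)


def two_region_stack(
    shape: tuple[int, int, int],
    rho_inner: float,
    rho_outer: float,
    split_axis: int = 2,
    split_frac: float = 0.5,
    background_frac: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SyntheticStack:
    """Convenience builder: two homogeneous-correlation regions side by side.

    Splits the stack along ``split_axis``: the first ``split_frac`` of the
    extent gets ``rho_inner``, the rest ``rho_outer``.  Optionally the last
    ``background_frac`` of the axis is a no-fluorescence region.
    """
    rho = np.full(shape, rho_outer, dtype=float)
    cut = int(round(shape[split_axis] * split_frac))
    sl = [slice(None)] * 3
    sl[split_axis] = slice(0, cut)
    rho[tuple(sl)] = rho_inner
    bg = np.zeros(shape, dtype=bool)
    if background_frac > 0:
        bg_cut = int(round(shape[split_axis] * (1 - background_frac)))
        sl[split_axis] = slice(bg_cut, None)
        bg[tuple(sl)] = True
    return make_stack(StackSpec(shape=shape, rho=rho, background_mask=bg, seed=seed, **kwargs))


# --------------------------------------------------------------------------
# Flow-cytometry mixtures

@dataclass(frozen=True)
class FlowMixtureSpec:
    """Four-component mixture of two-channel events.

    ``fractions`` follow the quadrant order (neither, mTurq-only,
    YPet-only, both) and must sum to 1.  Each channel's intensity is
    log-normal: ``(mu, sigma)`` on the log scale for the off state, with
    ``log_shift`` added to mu when the channel is on (default ln(10), a
    10x brighter positive cluster).
    """

    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n: int = 24000
    ypet_null: tuple[float, float] = (math.log(150.0), 0.35)
    mturq_null: tuple[float, float] = (math.log(150.0), 0.35)
    log_shift: float = math.log(10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.size != 4 or np.any(frac < 0):
            raise SpecError("fractions must be four non-negative values")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise SpecError(f"fractions must sum to 1, got {frac.sum()!r}")
        if self.n < 1:
            raise SpecError("n must be >= 1")


#: quadrant label -> (mturq on?, ypet on?)
_LABEL_STATES = {0: (False, False), 1: (True, False), 2: (False, True), 3: (True, True)}

QUADRANT_LABELS = ("neither", "mturq_only", "ypet_only", "both")


def make_flow(
    spec: FlowMixtureSpec,
    gene_ypet: str | None = None,
    gene_mturq: str | None = None,
    orientation: int | None = None,
) -> FlowSample:
    """Draw a dual-reporter flow sample; true cluster labels are retained."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(4, size=spec.n, p=np.asarray(spec.fractions, dtype=float))
    mturq_on = np.isin(labels, [1, 3])
    ypet_on = np.isin(labels, [2, 3])

    mu_y = spec.ypet_null[0] + spec.log_shift * ypet_on
    mu_m = spec.mturq_null[0] + spec.log_shift * mturq_on
    ypet = np.exp(rng.normal(mu_y, spec.ypet_null[1]))
    mturq = np.exp(rng.normal(mu_m, spec.mturq_null[1]))

    return FlowSample(
        ypet=ypet,
        mturq=mturq,
        gene_ypet=gene_ypet,
        gene_mturq=gene_mturq,
        orientation=orientation,
        true_labels=labels,
    )


def make_control(
    n: int = 100_000,
    ypet_null: tuple[float, float] = (math.log(150.0), 0.35),
    mturq_null: tuple[float, float] = (math.log(150.0), 0.35),
    seed: int = 0,
) -> FlowSample:
    """Draw a non-fluorescent control sample (all events double-negative)."""
    spec = FlowMixtureSpec(
        fractions=(1.0, 0.0, 0.0, 0.0), n=n,
        ypet_null=ypet_null, mturq_null=mturq_null, seed=seed,
    )
    sample = make_flow(spec)
    return FlowSample(
        ypet=sample.ypet, mturq=sample.mturq,
        gene_ypet=None, gene_mturq=None, orientation=None,
        true_labels=sample.true_labels, is_control=True,
    )


# --------------------------------------------------------------------------
# Disk writers (TIFF images, CSV flow tables, JSON ground-truth sidecars)

def _sidecar(path: Path, payload: dict) -> Path:
    side = path.with_suffix(path.suffix + ".truth.json")
    side.write_text(json.dumps(payload, indent=2, default=str))
    return side


def write_colony(colony: SyntheticColony, path: str | Path) -> Path:
    """Write a multi-channel TIFF (brightfield first) plus a truth sidecar."""
    path = Path(path)
    names = ["brightfield", *colony.image.channels.keys()]
    pages = np.stack([colony.image.brightfield, *colony.image.channels.values()])
    tifffile.imwrite(path, pages, photometric="minisblack",
                     metadata={"axes": "CYX", "channel_names": names})
    truth_csv = path.with_suffix(".truth.csv")
    colony.true_profile.to_csv(truth_csv, index=False)
    spec = asdict(colony.spec)
    spec["channels"] = {k: repr(v) for k, v in colony.spec.channels.items()}
    _sidecar(path, {
        "spec": spec,
        "true_center": list(colony.true_center),
        "true_radius": colony.true_radius,
        "true_mask_area": int(colony.true_mask.sum()),
        "true_profile_csv": truth_csv.name,
        "channel_order": names,
    })
    return path


def write_stack(synthetic: SyntheticStack, path: str | Path) -> Path:
    """Write a two-channel stack as ZCYX OME-TIFF plus a truth sidecar."""
    path = Path(path)
    zcyx = np.stack([synthetic.stack.ch1, synthetic.stack.ch2], axis=1)
    tifffile.imwrite(path, _quantize(zcyx), ome=True, metadata={"axes": "ZCYX"})
    spec = asdict(synthetic.spec)
    spec["rho"] = "field" if np.ndim(synthetic.spec.rho) else float(synthetic.spec.rho)
    spec["background_mask"] = bool(synthetic.background_mask.any())
    _sidecar(path, {"spec": spec, "rho_mean": float(synthetic.true_rho.mean())})
    return path


def write_flow(sample: FlowSample, path: str | Path, include_labels: bool = True) -> Path:
    """Write a flow sample as a CSV event table (event_id, ypet, mturq[, true_label])."""
    path = Path(path)
    data = {"event_id": np.arange(sample.n), "ypet": sample.ypet, "mturq": sample.mturq}
    if include_labels and sample.true_labels is not None:
        data["true_label"] = sample.true_labels
    pd.DataFrame(data).to_csv(path, index=False)
    return path
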