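"""Ground-truthed synthetic inputs for the morphometrics pipeline.

Fluorescence-like channel images with known droplet populations (and
optional point-particle placements for encapsulation counting), plus
solver-free order-parameter field fixtures.  Everything is seeded and
bit-reproducible: identical spec + seed give identical outputs.

The image generator emulates what the microscope sees in a dehydrating
channel: bright DEX-rich disks in single file along a dark channel, with a
Gaussian point-spread blur and additive Gaussian noise.  Diameters are drawn
from a normal distribution truncated to (0, channel width] — droplets cannot
outgrow the channel — optionally mixed with a small-satellite population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridSpec
from .solver import FieldState

__all__ = [
    "SyntheticImageSpec",
    "TrueDroplet",
    "Particle",
    "GroundTruth",
    "PackingError",
    "WIDTH_PRESETS",
    "preset_spec",
    "generate_droplet_image",
    "generate_particle_placements",
    "generate_field_fixture",
]


class PackingError(ValueError):
    """Requested droplets do not fit in the channel."""


#: Emulation presets per channel width (µm): mean diameter (µm) and CV (%)
#: of the droplet populations measured for 5/10/15/20 µm channels.
WIDTH_PRESETS: dict[float, tuple[float, float]] = {
    5.0: (4.6, 9.8),
    10.0: (9.3, 14.6),
    15.0: (14.1, 12.1),
    20.0: (18.3, 16.3),
}


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic channel image.

    ``n_droplets = None`` fills the channel ("auto"); otherwise exactly that
    many droplets are placed or a :class:`PackingError` is raised naming the
    constraint.  Intensities are arbitrary fluorescence units.
    """

    channel_length: float = 512.0  # µm
    channel_width: float = 20.0  # µm
    px_scale: float = 1.0  # µm / px
    n_droplets: int | None = None
    diameter_mean: float = 18.3  # µm
    diameter_sd: float = 3.0  # µm
    satellite_fraction: float = 0.0
    satellite_mean: float = 6.0  # µm
    satellite_sd: float = 1.5  # µm
    min_gap: float = 2.0  # µm between droplet rims
    droplet_intensity: float = 1.0
    background_intensity: float = 0.0
    psf_sigma: float = 0.3  # µm
    noise_sd: float = 0.02
    margin: float = 2.0  # dark border beyond the channel walls, µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_mean <= 0 or self.diameter_mean > self.channel_width:
            raise ValueError("diameter_mean must lie in (0, channel_width]")
        if self.min_gap < 0 or self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("min_gap, psf_sigma and noise_sd must be non-negative")
        if not 0 <= self.satellite_fraction <= 1:
            raise ValueError("satellite_fraction must lie in [0, 1]")
        if self.px_scale <= 0:
            raise ValueError("px_scale must be positive")


@dataclass(frozen=True)
class TrueDroplet:
    id: int
    center: tuple[float, float]  # (x, z) µm, image frame
    diameter: float  # µm
    is_satellite: bool


@dataclass(frozen=True)
class Particle:
    x: float  # µm
    z: float  # µm
    parent_id: int  # droplet id, or -1 for a background stray


@dataclass
class GroundTruth:
    """Truth table consistent with the rendered image geometry."""

    droplets: list[TrueDroplet]
    channel_length: float
    channel_width: float
    margin: float
    particles: list[Particle] = dataclass_field(default_factory=list)

    def diameters(self, satellites: bool = True) -> np.ndarray:
        return np.array(
            [d.diameter for d in self.droplets if satellites or not d.is_satellite]
        )


def preset_spec(
    width: float,
    n_droplets: int = 140,
    px_scale: float = 0.2,
    seed: int = 0,
    **overrides,
) -> SyntheticImageSpec:
    """Image spec emulating the measured population for a given channel width.

    Uses :data:`WIDTH_PRESETS` (mean diameter and CV per width) and sizes the
    channel to hold ``n_droplets`` in single file.
    """
    mean, cv = WIDTH_PRESETS[float(width)]
    sd = cv / 100.0 * mean
    gap = overrides.pop("min_gap", 2.0)
    length = math.ceil(n_droplets * (mean + 3.0 * sd + gap) + 4.0 * gap)
    return SyntheticImageSpec(
        channel_length=float(length),
        channel_width=float(width),
        px_scale=px_scale,
        n_droplets=n_droplets,
        diameter_mean=mean,
        diameter_sd=sd,
        min_gap=gap,
        seed=seed,
        **overrides,
    )


def _draw_diameter(rng: np.random.Generator, mean: float, sd: float, hi: float) -> float:
    """Normal truncated to (0, hi] by redraw; sd = 0 returns the mean."""
    if sd == 0:
        return min(mean, hi)
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if 0.0 < d <= hi:
            return d
    raise RuntimeError("truncated-normal rejection failed; check mean/sd")  # pragma: no cover


def generate_droplet_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one channel image and its ground truth.

    Disks are placed sequentially along the channel axis with jittered gaps
    and a small transverse jitter that keeps each disk inside the channel.
    With ``noise_sd = 0`` and ``psf_sigma = 0`` the image is binary and every
    disk's pixel area matches its truth diameter up to rasterization.
    Returns an (nx, nz) array indexed (x, z), in µm via ``px_scale``.
    """
    rng = np.random.default_rng(spec.seed)
    hi = spec.channel_width
    placements: list[TrueDroplet] = []
    cursor = spec.min_gap  # x position of the next free rim
    idx = 1
    target = spec.n_droplets

    while True:
        if target is not None and len(placements) == target:
            break
        is_sat = spec.satellite_fraction > 0 and rng.uniform() < spec.satellite_fraction
        if is_sat:
            d = _draw_diameter(rng, spec.satellite_mean, spec.satellite_sd, hi)
        else:
            d = _draw_diameter(rng, spec.diameter_mean, spec.diameter_sd, hi)
        gap = spec.min_gap * (1.0 + rng.uniform())
        cx = cursor + gap + d / 2.0
        if cx + d / 2.0 > spec.channel_length - spec.min_gap:
            if target is None:
                break
            raise PackingError(
                f"only {len(placements)} of {target} droplets fit: cumulative "
                f"diameters + gaps exceed channel_length = {spec.channel_length} µm"
            )
        slack = (spec.channel_width - d) / 2.0
        cz = spec.margin + spec.channel_width / 2.0 + rng.uniform(-0.5, 0.5) * slack
        placements.append(TrueDroplet(idx, (cx, float(cz)), float(d), is_sat))
        cursor = cx + d / 2.0
        idx += 1

    nx = int(round(spec.channel_length / spec.px_scale))
    nz = int(round((spec.channel_width + 2 * spec.margin) / spec.px_scale))
    image = np.full((nx, nz), spec.background_intensity, dtype=float)
    x_centers = (np.arange(nx) + 0.5) * spec.px_scale
    z_centers = (np.arange(nz) + 0.5) * spec.px_scale
    for d in placements:
        cx, cz = d.center
        r = d.diameter / 2.0
        i0 = max(0, int((cx - r) / spec.px_scale) - 1)
        i1 = min(nx, int((cx + r) / spec.px_scale) + 2)
        j0 = max(0, int((cz - r) / spec.px_scale) - 1)
        j1 = min(nz, int((cz + r) / spec.px_scale) + 2)
        xx = x_centers[i0:i1, None] - cx
        zz = z_centers[None, j0:j1] - cz
        image[i0:i1, j0:j1][xx**2 + zz**2 <= r * r] = spec.droplet_intensity
    if spec.psf_sigma > 0:
        image = gaussian_filter(image, spec.psf_sigma / spec.px_scale)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    truth = GroundTruth(
        droplets=placements,
        channel_length=spec.channel_length,
        channel_width=spec.channel_width,
        margin=spec.margin,
    )
    return image, truth


def generate_particle_placements(
    truth: GroundTruth,
    lambda_occupancy: float,
    miss_fraction: float = 0.0,
    seed: int = 0,
) -> list[Particle]:
    """Poisson particle placements for encapsulation counting.

    Each droplet receives Poisson(lambda) particles uniformly over its disk.
    Background strays (outside every droplet) are added with expected count
    ``miss_fraction * lambda * n_droplets``, uniform over the channel with
    rejection against the droplets.
    """
    if lambda_occupancy < 0:
        raise ValueError("lambda_occupancy must be non-negative")
    if not 0 <= miss_fraction <= 1:
        raise ValueError("miss_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    particles: list[Particle] = []
    for d in truth.droplets:
        n = rng.poisson(lambda_occupancy)
        if n == 0:
            continue
        r = d.diameter / 2.0 * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0.0, 2.0 * np.pi, size=n)
        for rr, tt in zip(r, th):
            particles.append(
                Particle(
                    d.center[0] + rr * math.cos(tt),
                    d.center[1] + rr * math.sin(tt),
                    d.id,
                )
            )
    n_stray = rng.poisson(miss_fraction * lambda_occupancy * len(truth.droplets))
    centers = np.array([d.center for d in truth.droplets]).reshape(-1, 2)
    radii = np.array([d.diameter / 2.0 for d in truth.droplets])
    placed = 0
    while placed < n_stray:
        x = rng.uniform(0.0, truth.channel_length)
        z = rng.uniform(truth.margin, truth.margin + truth.channel_width)
        if len(radii) and np.any(
            (centers[:, 0] - x) ** 2 + (centers[:, 1] - z) ** 2 <= radii**2
        ):
            continue
        particles.append(Particle(x, z, -1))
        placed += 1
    return particles


def generate_field_fixture(
    grid: GridSpec,
    droplets: Sequence[tuple[float, float]],
    eta_high: float = 0.9,
    eta_low: float = 0.3,
    interface_width: float | None = None,
) -> FieldState:
    """Order-parameter field with tanh-profile disks on a uniform background.

    ``droplets`` is a sequence of (x_center µm, diameter µm) pairs, placed at
    the channel mid-plane on the periodic x axis (a disk near x = 0 wraps);
    the interface width defaults to 2 dx.  Overlapping disks (closer than the
    sum of radii plus one interface width, with periodic distance) raise.
    An empty sequence gives the uniform background.
    """
    if interface_width is None:
        interface_width = 2.0 * grid.dx
    length = grid.channel_length
    ds = sorted(droplets, key=lambda p: p[0])
    for (x1, d1), (x2, d2) in zip(ds, ds[1:] + ds[:1] if len(ds) > 1 else []):
        gap = min(abs(x2 - x1), length - abs(x2 - x1))
        if gap < (d1 + d2) / 2.0 + interface_width:
            raise ValueError(f"droplets at x = {x1} and x = {x2} µm overlap")
    for x, d in ds:
        if d > grid.channel_width:
            raise ValueError(f"diameter {d} µm exceeds channel width")
    x_centers = (np.arange(grid.nx) + 0.5) * grid.dx
    z_centers = (np.arange(grid.nz) + 0.5) * grid.dx
    eta = np.full(grid.shape, eta_low, dtype=float)
    cz = grid.channel_width / 2.0
    for x, d in ds:
        dx_wrap = (x_centers - x + length / 2.0) % length - length / 2.0
        rr = np.sqrt(dx_wrap[:, None] ** 2 + (z_centers[None, :] - cz) ** 2)
        profile = 0.5 * (1.0 - np.tanh(2.0 * (rr - d / 2.0) / interface_width))
        eta += (eta_high - eta_low) * profile
    np.clip(eta, None, eta_high, out=eta)
    return FieldState(eta=eta, t=0.0, step=0)
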