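"""Droplet segmentation and size / throughput / encapsulation statistics.

Works on either simulated order-parameter fields (threshold eta > 0.5, the
midpoint of the two bulk phases) or fluorescence-like channel images.  All
arrays are indexed (x, z) with x along the channel; physical coordinates are
micrometres with pixel centres at (i + 0.5) * grid_scale.

The reported "diameter" is the 2D equivalent-circle diameter
2 sqrt(area / pi) of each connected component.  Boundary-touching components
are flagged (partial objects bias the diameter) and excluded from summary
statistics by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import linregress

__all__ = [
    "LabeledDroplet",
    "DropletSet",
    "SizeStats",
    "RegressionResult",
    "GaussianFit",
    "EncapsulationResult",
    "segment_droplets",
    "size_statistics",
    "filter_satellites",
    "gaussian_fit",
    "width_diameter_regression",
    "throughput_estimate",
    "encapsulation_efficiency",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class LabeledDroplet:
    id: int
    centroid: tuple[float, float]  # (x, z) in µm
    area: float  # µm^2
    equiv_diameter: float  # 2 sqrt(area / pi), µm
    touches_boundary: bool
    label_value: int = 0  # value in the label image (0 when not from one)


@dataclass
class DropletSet:
    """Labeled droplets plus the geometry and segmentation settings used."""

    droplets: list[LabeledDroplet]
    channel_length: float  # µm
    channel_width: float  # µm
    threshold: float
    grid_scale: float = 1.0  # µm / px
    labels: np.ndarray | None = None  # label image, same shape as the input
    periodic_x: bool = False

    def __len__(self) -> int:
        return len(self.droplets)

    def diameters(self, exclude_boundary: bool = False) -> np.ndarray:
        return np.array(
            [
                d.equiv_diameter
                for d in self.droplets
                if not (exclude_boundary and d.touches_boundary)
            ]
        )


@dataclass(frozen=True)
class SizeStats:
    n: int
    mean: float  # µm
    sd: float  # sample SD (n-1 denominator), µm
    cv: float  # 100 * sd / mean, percent
    linear_density: float  # droplets per µm of channel


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float  # maximum-likelihood (n denominator)
    degenerate: bool = False  # True when the sample variance is zero


@dataclass
class EncapsulationResult:
    efficiency: float  # fraction of droplets containing >= 1 particle
    counts: np.ndarray  # per-droplet particle counts, aligned with droplets
    n_particles_inside: int
    n_particles_outside: int


def _merge_periodic_labels(labels: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Union components that are 8-adjacent across the periodic x seam."""
    parent = np.arange(n + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    nz = labels.shape[1]
    first, last = labels[0], labels[-1]
    for j in range(nz):
        if last[j] == 0:
            continue
        for dj in (-1, 0, 1):
            jj = j + dj
            if 0 <= jj < nz and first[jj] > 0:
                ra, rb = find(int(last[j])), find(int(first[jj]))
                if ra != rb:
                    parent[rb] = ra
    roots = np.array([find(i) for i in range(n + 1)])
    # compact to 1..m
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]], len(uniq)


def segment_droplets(
    field_or_image: np.ndarray,
    threshold: float,
    min_area: float = 2.0,
    grid_scale: float = 1.0,
    periodic_x: bool = False,
) -> DropletSet:
    """Connected components (8-connectivity) of above-threshold pixels.

    Components smaller than ``min_area`` (µm^2) are discarded; the rest are
    measured (area, centroid, equivalent diameter) in physical units.
    Components touching the z walls — or the x edges when not periodic — are
    flagged ``touches_boundary``.  With ``periodic_x``, components adjacent
    across the x seam are merged and their x centroid is the circular mean.
    An empty segmentation returns an empty set, not an error.
    """
    arr = np.asarray(field_or_image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("array contains non-finite values")
    nx, nz = arr.shape
    mask = arr > threshold
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if periodic_x and n > 1:
        labels, n = _merge_periodic_labels(labels, n)

    droplets: list[LabeledDroplet] = []
    if n > 0:
        px_area = grid_scale * grid_scale
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=n + 1)
        ii, jj = np.nonzero(labels)
        lab_at = labels[ii, jj]
        # z centroid: plain mean of pixel centres
        z_sum = np.bincount(lab_at, weights=jj + 0.5, minlength=n + 1)
        if periodic_x:
            theta = 2.0 * np.pi * (ii + 0.5) / nx
            cos_s = np.bincount(lab_at, weights=np.cos(theta), minlength=n + 1)
            sin_s = np.bincount(lab_at, weights=np.sin(theta), minlength=n + 1)
        else:
            x_sum = np.bincount(lab_at, weights=ii + 0.5, minlength=n + 1)
        edge_labels = set()
        edge_labels.update(np.unique(labels[:, 0]))
        edge_labels.update(np.unique(labels[:, -1]))
        if not periodic_x:
            edge_labels.update(np.unique(labels[0, :]))
            edge_labels.update(np.unique(labels[-1, :]))
        edge_labels.discard(0)

        next_id = 1
        for lab in range(1, n + 1):
            area = counts[lab] * px_area
            if area < min_area:
                continue
            cz = z_sum[lab] / counts[lab] * grid_scale
            if periodic_x:
                ang = math.atan2(sin_s[lab], cos_s[lab]) % (2.0 * np.pi)
                cx = ang / (2.0 * np.pi) * nx * grid_scale
            else:
                cx = x_sum[lab] / counts[lab] * grid_scale
            droplets.append(
                LabeledDroplet(
                    id=next_id,
                    centroid=(float(cx), float(cz)),
                    area=float(area),
                    equiv_diameter=float(2.0 * math.sqrt(area / math.pi)),
                    touches_boundary=lab in edge_labels,
                    label_value=lab,
                )
            )
            next_id += 1

    return DropletSet(
        droplets=droplets,
        channel_length=nx * grid_scale,
        channel_width=nz * grid_scale,
        threshold=threshold,
        grid_scale=grid_scale,
        labels=labels,
        periodic_x=periodic_x,
    )


def size_statistics(ds: DropletSet, exclude_boundary: bool = True) -> SizeStats:
    """Mean, sample SD, CV (%) and linear density of the droplet diameters.

    Boundary-touching droplets are excluded by default; the linear density
    counts the retained droplets per µm of channel length.
    """
    d = ds.diameters(exclude_boundary=exclude_boundary)
    n = len(d)
    if n == 0:
        raise ValueError("size statistics are undefined for an empty droplet set")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    cv = 100.0 * sd / mean if mean > 0 else float("nan")
    return SizeStats(
        n=n, mean=mean, sd=sd, cv=cv, linear_density=n / ds.channel_length
    )


def filter_satellites(ds: DropletSet, min_diameter: float) -> DropletSet:
    """Retain droplets with equivalent diameter >= min_diameter (µm)."""
    if min_diameter < 0:
        raise ValueError("min_diameter must be non-negative")
    kept = [d for d in ds.droplets if d.equiv_diameter >= min_diameter]
    return replace(ds, droplets=kept)


def gaussian_fit(diameters: Sequence[float]) -> GaussianFit:
    """Maximum-likelihood normal fit (sample mean, ML sigma) to diameters.

    Intended for histogram overlays.  Zero variance gives sigma = 0 with the
    ``degenerate`` flag set.  Invariant to sample order.
    """
    d = np.asarray(diameters, dtype=float)
    if len(d) < 3:
        raise ValueError("gaussian fit needs at least 3 samples")
    mu = float(np.mean(d))
    sigma = float(np.std(d, ddof=0))
    return GaussianFit(mu=mu, sigma=sigma, degenerate=sigma == 0.0)


def width_diameter_regression(
    pairs: Sequence[tuple[float, float]]
) -> RegressionResult:
    """Ordinary least squares of mean droplet diameter on channel width."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("regression needs at least 2 points")
    w = np.array([p[0] for p in pairs], dtype=float)
    d = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(w, w[0]):
        raise ValueError("singular design: all widths identical")
    res = linregress(w, d)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def throughput_estimate(
    linear_density: float, channels_per_cm: float
) -> dict[str, float]:
    """Droplet production per cm of channel and per cm of device width.

    ``droplets_per_cm_channel = linear_density (per µm) * 1e4 µm``, then
    multiplied by the channel packing density for the per-width figure.
    Exactly linear in both arguments.
    """
    if linear_density < 0 or channels_per_cm < 0:
        raise ValueError("inputs must be non-negative")
    per_channel = linear_density * 1.0e4
    return {
        "droplets_per_cm_channel": per_channel,
        "droplets_per_cm_width": per_channel * channels_per_cm,
    }


def encapsulation_efficiency(
    ds: DropletSet, particles: Sequence[tuple[float, float]]
) -> EncapsulationResult:
    """Fraction of droplets containing at least one particle.

    Particles are (x, z) positions in µm.  When the droplet set carries its
    label image the test is exact point-in-component lookup; otherwise each
    droplet is treated as the disk of its equivalent diameter around its
    centroid.  Particles inside no droplet are counted as outside.
    """
    n = len(ds.droplets)
    counts = np.zeros(n, dtype=int)
    pts = np.asarray(list(particles), dtype=float).reshape(-1, 2)
    inside = 0
    if len(pts) and n:
        if ds.labels is not None:
            lab_to_idx = {d.label_value: k for k, d in enumerate(ds.droplets)}
            i_px = np.clip((pts[:, 0] / ds.grid_scale).astype(int), 0, ds.labels.shape[0] - 1)
            j_px = np.clip((pts[:, 1] / ds.grid_scale).astype(int), 0, ds.labels.shape[1] - 1)
            for lab in ds.labels[i_px, j_px]:
                k = lab_to_idx.get(int(lab))
                if k is not None:
                    counts[k] += 1
                    inside += 1
        else:
            centers = np.array([d.centroid for d in ds.droplets])
            radii = np.array([d.equiv_diameter / 2.0 for d in ds.droplets])
            for p in pts:
                d2 = np.sum((centers - p) ** 2, axis=1)
                k = int(np.argmin(d2 - radii**2))
                if d2[k] <= radii[k] ** 2:
                    counts[k] += 1
                    inside += 1
    efficiency = float(np.mean(counts > 0)) if n else 0.0
    return EncapsulationResult(
        efficiency=efficiency,
        counts=counts,
        n_particles_inside=inside,
        n_particles_outside=len(pts) - inside,
    )
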