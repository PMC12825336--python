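"""Channel grid geometry and the discrete Laplacian.

The simulation domain is a quasi-1D channel segment: the x axis runs along
the channel (periodic), the z axis spans the channel cross-section (solid
walls, zero flux).  All lengths are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Uniform finite-difference grid for the channel.

    Parameters
    ----------
    nx : int
        Cells along the channel axis (periodic direction).  At least 64 so
        that the domain can host several droplets of channel-width scale.
    nz : int
        Cells across the channel; ``nz * dx`` is the channel width.
    dx : float
        Grid spacing in µm (the same in both directions).
    """

    nx: int = 256
    nz: int = 20
    dx: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 64:
            raise ValueError(f"nx must be >= 64, got {self.nx}")
        if self.nz < 4:
            raise ValueError(f"nz must be >= 4, got {self.nz}")
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.nz)

    @property
    def channel_width(self) -> float:
        """Channel width in µm."""
        return self.nz * self.dx

    @property
    def channel_length(self) -> float:
        """Length of the simulated channel segment in µm."""
        return self.nx * self.dx


def laplacian(field: np.ndarray, dx: float) -> np.ndarray:
    """Five-point Laplacian, periodic in x (axis 0), zero-flux in z (axis 1).

    The z walls are implemented with mirror ghost cells, which makes the
    associated flux across the wall exactly zero: summing the result over any
    column telescopes to zero, so conservative updates built on this stencil
    conserve mass identically up to floating point.
    """
    out = np.roll(field, -1, axis=0) + np.roll(field, 1, axis=0) - 2.0 * field
    nx, nz = field.shape
    padded = np.empty((nx, nz + 2), dtype=field.dtype)
    padded[:, 1:-1] = field
    padded[:, 0] = field[:, 0]      # mirror ghost: zero flux at the wall
    padded[:, -1] = field[:, -1]
    out += padded[:, 2:] + padded[:, :-2] - 2.0 * field
    out /= dx * dx
    return out
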