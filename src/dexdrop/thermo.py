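"""Thermodynamics of the PEG/dextran aqueous two-phase system.

This module holds the regular-solution free energy that drives the
Cahn-Hilliard dynamics, the time-ramped PEG-DEX interaction parameter that
models progressive dehydration, and an empirical binodal curve for
classifying (PEG%, DEX%) compositions as homogeneous or two-phase.

Conventions
-----------
The order parameter ``eta`` is the local dextran fraction of the total
polymer (eta = 0 pure PEG, eta = 1 pure dextran).  Energies are molar
(J mol^-1), the gradient-energy coefficient ``alpha`` is J m^2 mol^-1, and
compositions are % w/v.  The bulk free-energy density is

    f(eta) = RT [eta ln eta + (1 - eta) ln(1 - eta)] + L eta (1 - eta)

i.e. ideal mixing entropy plus a pairwise interaction of strength L.  The
interaction grows in time as water is absorbed by the channel walls:

    L(t) = L0 + a (1 - 10^(-b t))

so the quench deepens smoothly from L0 to L0 + a.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .grids import GridSpec, laplacian

__all__ = [
    "ThermoParams",
    "InteractionSchedule",
    "Composition",
    "BinodalModel",
    "ClassificationResult",
    "interaction_parameter",
    "bulk_free_energy_density",
    "chemical_potential_field",
    "spinodal_curvature",
    "classify_composition",
    "dilution_trajectory",
    "binodal_crossing_factor",
    "save_binodal",
    "load_binodal",
    "export_phase_diagram",
]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic constants of the model.

    Defaults are the study conditions: PEG/DEX in water at 295 K with a
    polymer diffusion constant three orders of magnitude below that of water
    self-diffusion.

    Attributes
    ----------
    R : float
        Gas constant, J mol^-1 K^-1.
    T : float
        Temperature, K.
    D0 : float
        Diffusion constant, m^2 s^-1 (composition independent).
    alpha : float
        Gradient-energy coefficient, J m^2 mol^-1.
    L0, a, b : float
        Baseline interaction (J mol^-1), dehydration ramp amplitude
        (J mol^-1) and ramp rate (s^-1) of ``L(t) = L0 + a(1 - 10^(-b t))``.
    eps_log : float
        Guard for eta inside logarithms; eta is clipped to
        [eps_log, 1 - eps_log] before evaluating ln.
    """

    R: float = 8.31
    T: float = 295.0
    D0: float = 1.0e-14
    alpha: float = 3.5e-8
    L0: float = 7300.0
    a: float = 10000.0
    b: float = 5.0e-3
    eps_log: float = 1.0e-6

    def __post_init__(self) -> None:
        for name in ("R", "T", "D0", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.a < 0 or self.b < 0:
            raise ValueError("ramp constants a, b must be non-negative")
        if not 0 < self.eps_log < 0.01:
            raise ValueError("eps_log must lie in (0, 0.01)")

    @property
    def RT(self) -> float:
        """Thermal energy scale R*T in J mol^-1."""
        return self.R * self.T

    @property
    def mobility(self) -> float:
        """Cahn-Hilliard mobility Mc = D0 / RT in mol m^2 J^-1 s^-1."""
        return self.D0 / self.RT

    # micrometre-based variants used by the solver (grid lengths are in µm)
    @property
    def mobility_um2(self) -> float:
        """Mc with lengths in µm: mol µm^2 J^-1 s^-1."""
        return (self.D0 * 1.0e12) / self.RT

    @property
    def alpha_um2(self) -> float:
        """Gradient coefficient with lengths in µm: J µm^2 mol^-1."""
        return self.alpha * 1.0e12


@dataclass(frozen=True)
class InteractionSchedule:
    """Time ramp of the PEG-DEX interaction parameter.

    ``L(0) = L0`` and L increases strictly (for a, b > 0) towards the
    supremum ``L0 + a`` as the solution dehydrates.
    """

    thermo: ThermoParams = dataclass_field(default_factory=ThermoParams)

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return interaction_parameter(t, self)

    @property
    def L_max(self) -> float:
        """Supremum of L(t) over t >= 0."""
        return self.thermo.L0 + self.thermo.a


def interaction_parameter(
    t: float | np.ndarray, schedule: InteractionSchedule
) -> float | np.ndarray:
    """Interaction parameter L(t) = L0 + a (1 - 10^(-b t)), J mol^-1.

    The base-10 exponential is deliberate: the ramp reaches 90% of its
    amplitude at t = 1/b (200 s at the default rate).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p = schedule.thermo
    out = p.L0 + p.a * (1.0 - 10.0 ** (-p.b * t))
    return float(out) if out.ndim == 0 else out


def _check_guard(eta: np.ndarray, eps: float) -> None:
    if np.any(eta < eps) or np.any(eta > 1.0 - eps):
        raise ValueError(
            f"eta outside guarded interval [{eps}, {1 - eps}]"
        )


def bulk_free_energy_density(
    eta: float | np.ndarray, L: float, p: ThermoParams
) -> float | np.ndarray:
    """Bulk free-energy density f(eta), J mol^-1.

    f = RT [eta ln eta + (1-eta) ln(1-eta)] + L eta (1-eta); symmetric about
    eta = 0.5.  Raises for eta outside the logarithm guard interval.
    """
    eta = np.asarray(eta, dtype=float)
    _check_guard(eta, p.eps_log)
    out = p.RT * (eta * np.log(eta) + (1.0 - eta) * np.log1p(-eta)) + L * eta * (
        1.0 - eta
    )
    return float(out) if out.ndim == 0 else out


def _bulk_potential(eta: np.ndarray, L: float, p: ThermoParams) -> np.ndarray:
    """df/deta with eta clipped into the guard interval (C0 extension)."""
    e = np.clip(eta, p.eps_log, 1.0 - p.eps_log)
    return p.RT * (np.log(e) - np.log1p(-e)) + L * (1.0 - 2.0 * e)


def chemical_potential_field(
    field: np.ndarray, L: float, p: ThermoParams, grid: GridSpec
) -> np.ndarray:
    """Chemical potential mu = RT ln(eta/(1-eta)) + L(1-2 eta) - alpha lap(eta).

    The Laplacian is periodic along the channel (x) and zero-flux across it
    (z).  ``field`` values are clipped into the logarithm guard interval when
    evaluating the entropic term; the field itself is untouched.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2 or field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} != grid shape {grid.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    return _bulk_potential(field, L, p) - p.alpha_um2 * laplacian(field, grid.dx)


def spinodal_curvature(
    eta: float | np.ndarray, L: float, p: ThermoParams
) -> float | np.ndarray:
    """Second derivative f''(eta) = RT (1/eta + 1/(1-eta)) - 2L, J mol^-1.

    Negative values mark the spinodal region where a homogeneous mixture is
    linearly unstable.
    """
    eta = np.asarray(eta, dtype=float)
    _check_guard(eta, p.eps_log)
    out = p.RT * (1.0 / eta + 1.0 / (1.0 - eta)) - 2.0 * L
    return float(out) if out.ndim == 0 else out


def coexistence_composition(L: float, p: ThermoParams) -> float:
    """Dilute-branch equilibrium composition of the symmetric double well.

    Solves mu_bulk(eta) = 0 for eta < 0.5 (the DEX-poor phase; the DEX-rich
    phase is 1 - eta by symmetry).  Returns 0.5 if L <= 2 RT (no demixing).
    """
    if L <= 2.0 * p.RT:
        return 0.5
    lo = p.eps_log
    return brentq(
        lambda e: p.RT * (math.log(e) - math.log1p(-e)) + L * (1.0 - 2.0 * e),
        lo,
        0.5 - 1e-12,
        xtol=1e-15,
    )


# ---------------------------------------------------------------------------
# Phase diagram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Composition:
    """A (PEG%, DEX%) point in % w/v."""

    c_peg: float
    c_dex: float

    def __post_init__(self) -> None:
        if self.c_peg < 0 or self.c_dex < 0:
            raise ValueError("concentrations must be non-negative")

    def scaled(self, f: float) -> "Composition":
        """Concentrate by factor f (removes water at fixed PEG:DEX ratio)."""
        return Composition(self.c_peg * f, self.c_dex * f)


@dataclass(frozen=True)
class BinodalModel:
    """Empirical binodal c_dex = g(c_peg) = A exp(B sqrt(c_peg) - C c_peg^3).

    The three-parameter exponential form is the standard empirical fit for
    PEG/DEX binodals.  Default coefficients pass through (1, 9.6),
    (4.8, 4.8) and (8, 1.8) % w/v, placing the diagonal (1:1 composition)
    crossing at 4.8% so that a 4%:4% mixture is homogeneous while 5%:5% is
    two-phase.  g is positive and strictly decreasing over the fitted PEG
    range.
    """

    A: float = 14.612301876529456
    B: float = -0.4183215975723383
    C: float = 0.0017790721677167286
    peg_range: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.peg_range[0] >= self.peg_range[1]:
            raise ValueError("peg_range must be increasing")

    def curve(self, c_peg: float | np.ndarray) -> float | np.ndarray:
        """DEX concentration on the binodal at the given PEG concentration."""
        c = np.asarray(c_peg, dtype=float)
        out = self.A * np.exp(self.B * np.sqrt(c) - self.C * c**3)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ClassificationResult:
    label: str  # "homogeneous" or "two_phase"
    extrapolated: bool  # True if c_peg fell outside the fitted PEG range

    def __eq__(self, other: object):  # convenient comparison against a label
        if isinstance(other, str):
            return self.label == other
        return (
            isinstance(other, ClassificationResult)
            and self.label == other.label
            and self.extrapolated == other.extrapolated
        )

    def __hash__(self) -> int:
        return hash((self.label, self.extrapolated))


def classify_composition(c: Composition, m: BinodalModel) -> ClassificationResult:
    """Classify a composition as homogeneous (below binodal) or two_phase.

    Points with c_peg outside the fitted range are still classified (the
    curve extrapolates smoothly) but carry ``extrapolated=True``.
    """
    extrapolated = not (m.peg_range[0] <= c.c_peg <= m.peg_range[1])
    label = "two_phase" if c.c_dex > m.curve(c.c_peg) else "homogeneous"
    return ClassificationResult(label, extrapolated)


def dilution_trajectory(
    c0: Composition, water_loss_fraction: Iterable[float]
) -> list[Composition]:
    """Compositions along the dehydration ray for a series of water-loss
    fractions phi: each point is c0 scaled by 1/(1 - phi), preserving the
    PEG:DEX ratio exactly."""
    out = []
    for phi in water_loss_fraction:
        if not 0.0 <= phi < 1.0:
            raise ValueError(f"water loss fraction must lie in [0, 1), got {phi}")
        out.append(c0.scaled(1.0 / (1.0 - phi)))
    return out


def binodal_crossing_factor(
    c0: Composition,
    m: BinodalModel,
    f_cap: float = 10.0,
    rtol: float = 1.0e-6,
) -> float | None:
    """Smallest concentration factor f* >= 1 at which f*.c0 is two-phase.

    Returns 1.0 if c0 already classifies two-phase, None if no crossing is
    found for f <= f_cap (e.g. pure water).  Found by bisection to relative
    tolerance ``rtol``.
    """
    if classify_composition(c0, m) == "two_phase":
        return 1.0
    if classify_composition(c0.scaled(f_cap), m) != "two_phase":
        return None
    lo, hi = 1.0, f_cap
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if classify_composition(c0.scaled(mid), m) == "two_phase":
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_binodal(m: BinodalModel, path: str | Path) -> None:
    """Write the binodal model as a small JSON document."""
    doc = {
        "form": "exponential_sqrt_cubic",
        "coefficients": {"A": m.A, "B": m.B, "C": m.C},
        "peg_range": list(m.peg_range),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_binodal(path: str | Path) -> BinodalModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("form") != "exponential_sqrt_cubic":
        raise ValueError(f"unknown binodal form: {doc.get('form')!r}")
    c = doc["coefficients"]
    return BinodalModel(A=c["A"], B=c["B"], C=c["C"], peg_range=tuple(doc["peg_range"]))


def export_phase_diagram(
    m: BinodalModel,
    path: str | Path,
    c_peg_grid: Sequence[float] | None = None,
    c_dex_grid: Sequence[float] | None = None,
) -> None:
    """Write a CSV with columns c_peg, c_dex, label over a composition grid."""
    import pandas as pd

    if c_peg_grid is None:
        c_peg_grid = np.linspace(m.peg_range[0], m.peg_range[1], 37)
    if c_dex_grid is None:
        c_dex_grid = np.linspace(0.0, 12.0, 25)
    rows = [
        (cp, cd, classify_composition(Composition(cp, cd), m).label)
        for cp in c_peg_grid
        for cd in c_dex_grid
    ]
    pd.DataFrame(rows, columns=["c_peg", "c_dex", "label"]).to_csv(path, index=False)
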