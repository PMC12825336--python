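"""Diffusion-limited dehydration timing of the channel contents.

Water leaves the channel by vapor diffusion through the elastomer wall, so
the polymer concentration rises until the composition crosses the binodal
and demixing starts.  Referencing the water loss to channel volume per wall
area gives a 1/width^2 sensitivity of the concentration rise; one global
rate coefficient absorbs permeability, ambient humidity and geometry.  Two
scaling families are provided:

    quadratic:    phi(t) = min(0.99, c t / w^2)
    exponential:  phi(t) = phi_max (1 - exp(-c t / w^2))

where phi is the water-loss fraction, w the channel width (µm) and c the
rate coefficient (µm^2 s^-1 per unit fraction).  The onset time for an
initially homogeneous composition c0 is the time at which the dilution ray
c0 / (1 - phi(t)) first classifies two-phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .thermo import BinodalModel, Composition, binodal_crossing_factor, classify_composition

__all__ = [
    "ChannelCondition",
    "DehydrationParams",
    "OnsetResult",
    "DEFAULT_CONDITIONS",
    "water_loss_fraction",
    "time_to_separation",
    "calibrate",
]

PHI_CAP = 0.99  # quadratic mode saturates here (the channel never dries out)


@dataclass(frozen=True)
class ChannelCondition:
    """One observed (channel width, initial composition, onset time) triple."""

    width: float  # µm
    c0: Composition  # symmetric PEG:DEX composition, % w/v
    observed_onset: float  # minutes

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.observed_onset <= 0:
            raise ValueError("observed onset must be positive")


#: Reference onset measurements: phase separation observed ~3 min after
#: loading 1%:1% PEG/DEX in 5 µm channels, ~7 min for 2%:2% in 10 µm,
#: ~8 min for 3%:3% in 15 µm and ~10 min for 4%:4% in 20 µm channels.
DEFAULT_CONDITIONS: tuple[ChannelCondition, ...] = (
    ChannelCondition(5.0, Composition(1.0, 1.0), 3.0),
    ChannelCondition(10.0, Composition(2.0, 2.0), 7.0),
    ChannelCondition(15.0, Composition(3.0, 3.0), 8.0),
    ChannelCondition(20.0, Composition(4.0, 4.0), 10.0),
)


@dataclass(frozen=True)
class DehydrationParams:
    """Fitted water-loss model: rate coefficient and scaling family."""

    rate_coefficient: float  # µm^2 s^-1
    scaling_mode: str = "quadratic"  # "quadratic" | "exponential"
    phi_max: float = PHI_CAP  # saturation level (exponential mode only)

    def __post_init__(self) -> None:
        if self.rate_coefficient <= 0:
            raise ValueError("rate_coefficient must be positive")
        if self.scaling_mode not in ("quadratic", "exponential"):
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")
        if not 0 < self.phi_max < 1:
            raise ValueError("phi_max must lie in (0, 1)")


def water_loss_fraction(
    t: float | np.ndarray, width: float, p: DehydrationParams
) -> float | np.ndarray:
    """Water-loss fraction phi(t) in [0, 1) for a channel of the given width.

    phi(0) = 0, phi is strictly increasing in t (until the cap) and, at fixed
    t, decreasing in width; doubling the width quarters phi at small t in
    both modes.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if width <= 0:
        raise ValueError("width must be positive")
    x = p.rate_coefficient * t / width**2
    if p.scaling_mode == "quadratic":
        out = np.minimum(PHI_CAP, x)
    else:
        out = p.phi_max * (1.0 - np.exp(-x))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OnsetResult:
    """Time to phase separation, minutes; flags for the edge cases."""

    minutes: float
    already_two_phase: bool = False
    never_separates: bool = False


def time_to_separation(
    c0: Composition,
    width: float,
    p: DehydrationParams,
    m: BinodalModel,
) -> OnsetResult:
    """First time (minutes) at which the dehydrating composition is two-phase.

    Returns 0 with ``already_two_phase`` set if c0 starts above the binodal,
    and ``never_separates`` (minutes = inf) if the water-loss model saturates
    before the required concentration factor is reached.
    """
    if classify_composition(c0, m) == "two_phase":
        return OnsetResult(0.0, already_two_phase=True)
    fstar = binodal_crossing_factor(c0, m)
    if fstar is None:
        return OnsetResult(math.inf, never_separates=True)
    phi_star = 1.0 - 1.0 / fstar
    phi_limit = PHI_CAP if p.scaling_mode == "quadratic" else p.phi_max
    if phi_star >= phi_limit:
        return OnsetResult(math.inf, never_separates=True)
    # bracket then invert phi(t) = phi_star
    t_hi = width**2 / p.rate_coefficient
    while water_loss_fraction(t_hi, width, p) < phi_star:
        t_hi *= 2.0
        if t_hi > 1e12:  # pragma: no cover - defensive
            return OnsetResult(math.inf, never_separates=True)
    t_sec = brentq(
        lambda t: water_loss_fraction(t, width, p) - phi_star, 0.0, t_hi, xtol=1e-9
    )
    return OnsetResult(t_sec / 60.0)


def _required_phi(conditions, m: BinodalModel) -> np.ndarray:
    phis = []
    for cond in conditions:
        if classify_composition(cond.c0, m) == "two_phase":
            raise ValueError(
                f"condition {cond} starts two-phase; onset calibration needs "
                "initially homogeneous compositions"
            )
        fstar = binodal_crossing_factor(cond.c0, m)
        if fstar is None:
            raise ValueError(f"condition {cond} never crosses the binodal")
        phis.append(1.0 - 1.0 / fstar)
    return np.asarray(phis)


def calibrate(
    conditions=DEFAULT_CONDITIONS,
    m: BinodalModel | None = None,
    mode: str = "quadratic",
) -> tuple[DehydrationParams, pd.DataFrame]:
    """Least-squares fit of the water-loss model to observed onset times.

    Squared log-time residuals are minimized so minute-scale and
    few-minute-scale conditions weight comparably.  Quadratic mode has the
    closed-form solution ln c = mean(ln(phi* w^2 / t_obs)); exponential mode
    fits (c, phi_max) numerically.  Returns the fitted parameters and a
    per-condition report (observed vs predicted onset, minutes).
    """
    if m is None:
        m = BinodalModel()
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError("calibration needs at least 2 conditions")
    widths = np.array([c.width for c in conditions])
    if np.allclose(widths, widths[0]):
        raise ValueError("ill-posed calibration: all conditions share one width")
    t_obs = np.array([c.observed_onset for c in conditions]) * 60.0  # s
    phi_star = _required_phi(conditions, m)

    if mode == "quadratic":
        rate = float(np.exp(np.mean(np.log(phi_star * widths**2 / t_obs))))
        params = DehydrationParams(rate, "quadratic")
    elif mode == "exponential":
        phi_floor = float(phi_star.max()) + 1e-6

        def resid(theta):
            c, pm = np.exp(theta[0]), phi_floor + (1 - phi_floor) / (1 + np.exp(-theta[1]))
            t_pred = (widths**2 / c) * np.log(pm / (pm - phi_star))
            return np.log(t_pred) - np.log(t_obs)

        x0 = [np.log(np.exp(np.mean(np.log(phi_star * widths**2 / t_obs)))), 0.0]
        sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        c_fit = float(np.exp(sol.x[0]))
        pm_fit = float(phi_floor + (1 - phi_floor) / (1 + np.exp(-sol.x[1])))
        params = DehydrationParams(c_fit, "exponential", phi_max=pm_fit)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pred = [
        time_to_separation(c.c0, c.width, params, m).minutes for c in conditions
    ]
    report = pd.DataFrame(
        {
            "width_um": widths,
            "c_peg": [c.c0.c_peg for c in conditions],
            "c_dex": [c.c0.c_dex for c in conditions],
            "observed_min": t_obs / 60.0,
            "predicted_min": pred,
        }
    )
    report["ratio"] = report["predicted_min"] / report["observed_min"]
    return params, report
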