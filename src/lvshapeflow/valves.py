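"""2D-planar valve model and blood rheology.

Valves live in their annulus planes as time-varying 2D orifices. Opening
and closing are modeled by a porous-baffle interface: a zero-thickness
surface that impresses a Darcy-type pressure drop

    Δp = −ρ (α |v_n| + β) v_n

onto the fluid (ρ density, v_n interface-normal velocity, α inertial and β
viscous resistance). Orifice areas ramp linearly over the opening/closing
intervals (AV 57/39 ms, MV 48/60 ms; fully open areas AV 4.0 cm², MV
5.65 cm²). Mitral regurgitation is represented by a residual orifice that
stays open during systole, sized from the regurgitation fraction of the
stroke volume and a target jet velocity.

Blood behaves as a Carreau–Yasuda shear-thinning fluid:

    η(γ̇) = η_inf + (η_0 − η_inf) [1 + (λ γ̇)^a]^((n−1)/a)

with η_0 = 0.16 Pa·s, η_inf = 0.0035 Pa·s, λ = 8.2 s, n = 0.2128, a = 0.64.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

__all__ = [
    "ValveSpec",
    "BafflePorosity",
    "RheologyParams",
    "ValveEvents",
    "mr_to_regurg_fraction",
    "opening_schedule",
    "baffle_pressure_drop",
    "size_regurg_orifice",
    "apparent_viscosity",
    "mv_intermediate_outline",
]

BLOOD_DENSITY = 1050.0  # kg/m³


@dataclass
class ValveSpec:
    """Geometric and timing description of one 2D valve."""

    kind: str                       # "aortic" | "mitral"
    opened_area: float = None       # cm²
    opening_duration: float = None  # s
    closing_duration: float = None  # s
    aspect_ratio: float = 1.4       # AV ellipse major/minor in opened state
    regurg_area: float = 0.0        # cm², mitral only

    _DEFAULTS = {
        "aortic": dict(opened_area=4.0, opening_duration=0.057, closing_duration=0.039),
        "mitral": dict(opened_area=5.65, opening_duration=0.048, closing_duration=0.060),
    }

    def __post_init__(self):
        if self.kind not in self._DEFAULTS:
            raise ValueError(f"unknown valve kind '{self.kind}'")
        for name, val in self._DEFAULTS[self.kind].items():
            if getattr(self, name) is None:
                setattr(self, name, val)
        if self.opened_area <= 0 or self.opening_duration <= 0 or self.closing_duration <= 0:
            raise ValueError("areas and durations must be positive")
        if self.regurg_area < 0:
            raise ValueError("regurgitant area must be >= 0")


@dataclass
class BafflePorosity:
    """Porous-baffle resistances of the Darcy pressure-drop law.

    Defaults make an open valve free (α = β = 0); a closed valve should use
    a large β so the baffle is effectively impermeable — these schedules are
    a documented stand-in, only the pressure-drop law itself is canonical.
    """

    alpha: float = 0.0       # inertial resistance, 1/m
    beta: float = 0.0        # viscous resistance, m/s scale
    rho: float = BLOOD_DENSITY

    CLOSED_BETA = 1.0e6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.rho <= 0:
            raise ValueError("invalid porosity parameters")

    @classmethod
    def closed(cls, rho: float = BLOOD_DENSITY) -> "BafflePorosity":
        return cls(alpha=0.0, beta=cls.CLOSED_BETA, rho=rho)


@dataclass
class RheologyParams:
    """Carreau–Yasuda parameters for blood."""

    eta_inf: float = 0.0035   # Pa·s
    eta_0: float = 0.16       # Pa·s
    relaxation_time: float = 8.2   # s
    power_constant: float = 0.2128
    a: float = 0.64

    def __post_init__(self):
        if not (0 < self.eta_inf < self.eta_0):
            raise ValueError("need 0 < eta_inf < eta_0")
        if self.relaxation_time <= 0 or self.a <= 0:
            raise ValueError("relaxation time and a must be positive")


def mr_to_regurg_fraction(grade: float) -> float:
    """Regurgitation fraction of stroke volume from a continuous MR grade.

    Piecewise-linear through (I, 15%), (II, 30%), (III, 50%), and linearly
    down to zero at grade 0. No extrapolation outside [0, 3].
    """
    if not (0.0 <= grade <= 3.0):
        raise ValueError(f"MR grade {grade} outside [0, 3]")
    return float(np.interp(grade, [0.0, 1.0, 2.0, 3.0], [0.0, 0.15, 0.30, 0.50]))


@dataclass
class ValveEvents:
    """Trigger times (s) within one cycle for one valve."""

    open_start: float
    close_start: float


def _mv_outline_cache():
    import pandas as pd

    with resources.files("lvshapeflow.data").joinpath(
            "mv_intermediate_orifice_synthetic.csv").open() as fh:
        df = pd.read_csv(fh)
    return df[["x", "y"]].to_numpy()


_MV_OUTLINE = None


def mv_intermediate_outline() -> np.ndarray:
    """Tabulated intermediate mitral orifice outline, normalized to unit area.

    The shipped polygon is a synthetic kidney-shaped stand-in for the
    published intermediate-state orifice; users can substitute their own CSV.
    """
    global _MV_OUTLINE
    if _MV_OUTLINE is None:
        poly = _mv_outline_cache()
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        _MV_OUTLINE = poly / np.sqrt(area)
    return _MV_OUTLINE.copy()


def _ellipse_outline(area: float, aspect: float, n: int = 64) -> np.ndarray:
    b = np.sqrt(area / (np.pi * aspect))
    a = aspect * b
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def opening_schedule(valve: ValveSpec, t: float, events: ValveEvents,
                     systole: Optional[tuple] = None):
    """Valve state at time ``t``: ``(opening_fraction, orifice_area_cm2, outline)``.

    The orifice area ramps linearly over the opening/closing durations. The
    aortic outline is a fixed-aspect ellipse scaled to the current area; the
    mitral outline is the intermediate-state polygon scaled to the current
    area. When the mitral valve is closed during ``systole = (t0, t1)`` and
    ``regurg_area > 0``, the regurgitant orifice remains open.
    """
    if events.close_start < events.open_start + valve.opening_duration:
        raise ValueError("closing ramp starts before the opening ramp completes")
    if t < events.open_start:
        frac = 0.0
    elif t < events.open_start + valve.opening_duration:
        frac = (t - events.open_start) / valve.opening_duration
    elif t < events.close_start:
        frac = 1.0
    elif t < events.close_start + valve.closing_duration:
        frac = 1.0 - (t - events.close_start) / valve.closing_duration
    else:
        frac = 0.0
    area = frac * valve.opened_area
    if (valve.kind == "mitral" and valve.regurg_area > 0 and systole is not None
            and systole[0] <= t < systole[1]):
        area = max(area, valve.regurg_area)
    if area <= 0:
        return frac, 0.0, np.zeros((0, 2))
    if valve.kind == "aortic":
        outline = _ellipse_outline(area, valve.aspect_ratio)
    else:
        outline = mv_intermediate_outline() * np.sqrt(area)
    return frac, area, outline


def baffle_pressure_drop(v_n, porosity: BafflePorosity):
    """Darcy pressure drop Δp = −ρ(α|v_n| + β)v_n over the baffle (Pa).

    Antisymmetric in v_n and always dissipative (Δp·v_n ≤ 0 for α, β ≥ 0).
    """
    v_n = np.asarray(v_n, float)
    dp = -porosity.rho * (porosity.alpha * np.abs(v_n) + porosity.beta) * v_n
    return float(dp) if dp.ndim == 0 else dp


def size_regurg_orifice(sv: float, regurg_fraction: float, systole_duration: float,
                        target_jet_velocity: float = 4.0) -> float:
    """Regurgitant orifice area (cm²) moving the regurgitant volume through
    systole at a physiological jet velocity (default 4 m/s, the middle of
    the regurgitant-jet range such simulations produce)."""
    if sv <= 0 or systole_duration <= 0:
        raise ValueError("stroke volume and systole duration must be positive")
    if regurg_fraction < 0:
        raise ValueError("regurgitation fraction must be >= 0")
    if target_jet_velocity <= 0:
        raise ValueError("target jet velocity must be positive")
    flow_cm3_s = sv * regurg_fraction / systole_duration  # ml/s = cm³/s
    return flow_cm3_s / (target_jet_velocity * 100.0)     # v in cm/s -> cm²


def apparent_viscosity(shear_rate, params: Optional[RheologyParams] = None):
    """Carreau–Yasuda apparent viscosity η(γ̇) in Pa·s.

    Bounded in [η_inf, η_0]; strictly decreasing for γ̇ > 0.
    """
    params = params or RheologyParams()
    g = np.asarray(shear_rate, float)
    if np.any(g < 0):
        raise ValueError("shear rate must be >= 0")
    lam_g = params.relaxation_time * g
    eta = params.eta_inf + (params.eta_0 - params.eta_inf) * (
        1.0 + lam_g**params.a) ** ((params.power_constant - 1.0) / params.a)
    return float(eta) if eta.ndim == 0 else eta
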