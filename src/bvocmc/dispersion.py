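"""Analytic BVOC concentration fields for an instantaneous point release.

A stressed plant is modelled as releasing a bolus of ``m`` mg of a single
tracer compound at height ``H`` into a steady wind ``u`` along +x.  Downwind
transport is advection plus turbulent diffusion whose eddy diffusivity is
absorbed into cumulative spread variables ``r_y(x)``, ``r_z(x)`` (units m²),
here parametrized for stable (Pasquill class F) conditions.  The field is a
Gaussian puff with a ground-image term (zero flux at z = 0), an optional
buoyancy/gravity vertical drift of the puff centre and an optional
pseudo-first-order photochemical decay with Arrhenius temperature dependence.

Two evaluation modes are provided (``DispersionScheme.normalization_mode``):

``as_printed``
    The literal published form: prefactor ``m/(4 pi r_y r_z)**1.5``,
    streamwise exponent ``(x-ut)**2 / (4 r_y r_z)``, with spreads evaluated
    at the field point x.  This is the mode used to reproduce the reported
    uptake results; it is not dimensionally homogeneous.

``consistent``
    A dimensionally consistent variant with streamwise spread
    ``r_x = sqrt(r_y r_z)`` and prefactor
    ``m / ((4 pi)**1.5 * sqrt(r_x r_y r_z))``, spreads evaluated at the puff
    age ``u (t - t0)`` so that the spatial integral of the field is exactly
    the released mass (times ``exp(-k_eff t)`` when decay is on).  Used for
    conservation checks and as the closed-form reference for the particle
    simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Environment",
    "SourceEvent",
    "DispersionScheme",
    "FieldOptions",
    "PASQUILL_F_PRINTED",
    "pasquill_f_textbook",
    "dispersion_coeffs",
    "air_density",
    "vertical_drift",
    "drift_acceleration",
    "decay_rate",
    "puff_concentration",
    "continuous_concentration",
]


@dataclass(frozen=True)
class Environment:
    """Meteorological and physical constants of the channel.

    Defaults are the study's reference conditions: standard atmosphere at
    293.15 K, a heavier-than-air tracer (1.26 kg/m³) and an Arrhenius
    photochemical sink with A = 1e10 1/s, E_a = 50 kJ/mol.  ``u`` is the mean
    wind speed along +x (m/s).
    """

    P: float = 101325.0        # pressure, Pa
    M: float = 0.029           # molar mass of air, kg/mol
    R: float = 8.314           # gas constant, J/(mol K)
    T: float = 293.15          # absolute temperature, K
    g: float = 9.81            # gravitational acceleration, m/s^2
    rho_b: float = 1.26        # tracer parcel density, kg/m^3
    u: float = 3.0             # mean wind speed, m/s
    A: float = 1.0e10          # Arrhenius pre-exponential factor, 1/s
    E_a: float = 50000.0       # activation energy, J/mol

    def __post_init__(self) -> None:
        for name in ("P", "M", "R", "T", "g", "rho_b", "A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Environment.{name} must be strictly positive")
        if self.E_a < 0:
            raise ValueError("Environment.E_a must be non-negative")
        if self.u < 0:
            raise ValueError("Environment.u must be non-negative")

    def replace(self, **kw) -> "Environment":
        return replace(self, **kw)


@dataclass(frozen=True)
class SourceEvent:
    """Instantaneous release of ``m`` mg at (0, 0, H) at time ``t0``."""

    m: float = 0.0016          # released mass, mg
    H: float = 0.8             # emitter height, m
    t0: float = 0.0            # release time, s

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("SourceEvent.m must be non-negative")
        if self.H < 0:
            raise ValueError("SourceEvent.H must be non-negative")

    def replace(self, **kw) -> "SourceEvent":
        return replace(self, **kw)


@dataclass(frozen=True)
class DispersionScheme:
    """Class-F cumulative spread formulas r_y, r_z and the evaluation mode.

    r_y(x) = cy_num x^2 / (1 + cy_den x)
    r_z(x) = cz_num x^2 / (1 + cz_den x)^2
    """

    cy_num: float = 0.08
    cy_den: float = 0.0001
    cz_num: float = 0.000128
    cz_den: float = 0.0003
    normalization_mode: str = "as_printed"   # or "consistent"

    def __post_init__(self) -> None:
        for name in ("cy_num", "cy_den", "cz_num", "cz_den"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DispersionScheme.{name} must be positive")
        if self.normalization_mode not in ("as_printed", "consistent"):
            raise ValueError(
                "normalization_mode must be 'as_printed' or 'consistent'"
            )

    def replace(self, **kw) -> "DispersionScheme":
        return replace(self, **kw)


#: The published class-F scheme (lateral coefficient 0.08 as printed).
PASQUILL_F_PRINTED = DispersionScheme()


def pasquill_f_textbook(normalization_mode: str = "as_printed") -> DispersionScheme:
    """Class-F scheme with the textbook lateral coefficient.

    The standard class-F lateral spread gives r_y = sigma_y^2/2
    = 0.0008 x^2/(1 + 0.0001 x); the vertical formula already matches
    sigma_z^2/2.  Provided as a named preset alongside the printed 0.08.
    """
    return DispersionScheme(cy_num=0.0008, normalization_mode=normalization_mode)


@dataclass(frozen=True)
class FieldOptions:
    """Composition switches for the analytic field."""

    include_drift: bool = True
    include_decay: bool = True
    ground_reflection: bool = True

    def replace(self, **kw) -> "FieldOptions":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# scalar building blocks


def dispersion_coeffs(x, scheme: DispersionScheme = PASQUILL_F_PRINTED):
    """Cumulative spreads (r_y, r_z) in m² at downwind distance x >= 0 (m).

    Both vanish at x = 0 and increase monotonically for x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("downwind distance x must be non-negative")
    r_y = scheme.cy_num * x**2 / (1.0 + scheme.cy_den * x)
    r_z = scheme.cz_num * x**2 / (1.0 + scheme.cz_den * x) ** 2
    return r_y, r_z


def air_density(env: Environment) -> float:
    """Ambient air density rho_a = P M / (R T) in kg/m³ (ideal gas)."""
    return env.P * env.M / (env.R * env.T)


def drift_acceleration(env: Environment) -> float:
    """Net buoyancy-gravity acceleration a = (rho_a - rho_b) g / rho_b (m/s²).

    Negative for a heavier-than-air tracer (the puff centre sinks).
    """
    return (air_density(env) - env.rho_b) * env.g / env.rho_b


def vertical_drift(t, env: Environment):
    """Upper-bound vertical displacement s_z(t) = a t²/2 of the puff centre.

    Drag-free envelope of the density-driven drift; negative when the tracer
    is denser than air.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    return 0.5 * drift_acceleration(env) * t**2


def decay_rate(env: Environment) -> float:
    """Effective pseudo-first-order photochemical loss rate k_eff (1/s).

    Arrhenius form A exp(-E_a/(R T)); strictly increasing in temperature.
    """
    return env.A * math.exp(-env.E_a / (env.R * env.T))


# ----------------------------------------------------------------------
# the puff field


def _vertical_factor(z, H, s_z, r_z, ground_reflection: bool):
    direct = np.exp(-((z - s_z - H) ** 2) / (4.0 * r_z))
    if not ground_reflection:
        return direct
    # image term literally as printed: drift applied to the image as well
    image = np.exp(-((z - s_z + H) ** 2) / (4.0 * r_z))
    return direct + image


def puff_concentration(x, y, z, t, src: SourceEvent = SourceEvent(),
                       env: Environment = Environment(),
                       scheme: DispersionScheme = PASQUILL_F_PRINTED,
                       opts: FieldOptions = FieldOptions()):
    """Concentration (mg/m³) of a single instantaneous puff.

    Array inputs broadcast.  Points upwind of the release time (t <= t0)
    return 0.  The delta-function origin (x = 0 with vanishing spread, or
    puff age 0 in consistent mode) follows the singular-point contract:
    +inf exactly on the (shifted) source point, 0 elsewhere.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if np.any(z < 0):
        raise ValueError("z must be non-negative")

    age = t - src.t0
    x_b, y_b, z_b, age_b = np.broadcast_arrays(x, y, z, age)
    out = np.zeros(x_b.shape, dtype=float)
    live = age_b > 0
    if not np.any(live):
        return out if out.shape else float(out)

    xl, yl, zl, al = (a[live] for a in (x_b, y_b, z_b, age_b))

    if scheme.normalization_mode == "as_printed":
        r_y, r_z = dispersion_coeffs(xl, scheme)
    else:
        r_y, r_z = dispersion_coeffs(env.u * al, scheme)

    s_z = vertical_drift(al, env) if opts.include_drift else np.zeros_like(al)

    vals = np.zeros_like(xl)
    ok = (r_y > 0) & (r_z > 0)
    if np.any(ok):
        ry, rz = r_y[ok], r_z[ok]
        du = xl[ok] - env.u * al[ok]
        if scheme.normalization_mode == "as_printed":
            pref = src.m / (4.0 * np.pi * ry * rz) ** 1.5
            stream = np.exp(-(du**2) / (4.0 * ry * rz))
        else:
            rx = np.sqrt(ry * rz)
            pref = src.m / ((4.0 * np.pi) ** 1.5 * np.sqrt(rx * ry * rz))
            stream = np.exp(-(du**2) / (4.0 * rx))
        lat = np.exp(-(yl[ok] ** 2) / (4.0 * ry))
        vert = _vertical_factor(zl[ok], src.H, s_z[ok], rz, opts.ground_reflection)
        v = pref * stream * lat * vert
        if opts.include_decay:
            v = v * np.exp(-decay_rate(env) * al[ok])
        vals[ok] = v

    # singular-point contract: vanishing spread is a delta at the (drifted)
    # source point -> +inf there, 0 off it
    sing = ~ok
    if np.any(sing):
        on_pt = (
            np.isclose(xl[sing], env.u * al[sing] if scheme.normalization_mode
                       == "consistent" else 0.0)
            & np.isclose(yl[sing], 0.0)
            & np.isclose(zl[sing], src.H + s_z[sing])
        )
        sv = np.zeros(int(sing.sum()))
        sv[on_pt] = np.inf if src.m > 0 else 0.0
        vals[sing] = sv

    out[live] = vals
    return out if out.shape else float(out)


def puff_column_integral(x, y, z_lo, z_hi, t, src: SourceEvent = SourceEvent(),
                         env: Environment = Environment(),
                         scheme: DispersionScheme = PASQUILL_F_PRINTED,
                         opts: FieldOptions = FieldOptions()):
    """Exact vertical integral of the puff field over a column.

    Returns ``int_{z_lo}^{z_hi} C(x, y, z, t) dz`` in closed form (erf),
    clipping the column at the ground z = 0.  The vertical Gaussian is
    centimetre-thin at metre ranges, so receiver-volume quadratures use this
    instead of pointwise z-sampling.  Array inputs broadcast.
    """
    from scipy.special import erf

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z_lo = np.maximum(np.asarray(z_lo, dtype=float), 0.0)
    z_hi = np.asarray(z_hi, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")

    age = t - src.t0
    x_b, y_b, lo_b, hi_b, age_b = np.broadcast_arrays(x, y, z_lo, z_hi, age)
    out = np.zeros(x_b.shape, dtype=float)
    live = (age_b > 0) & (hi_b > lo_b)
    if not np.any(live):
        return out if out.shape else float(out)
    xl, yl, lol, hil, al = (a[live] for a in (x_b, y_b, lo_b, hi_b, age_b))

    if scheme.normalization_mode == "as_printed":
        r_y, r_z = dispersion_coeffs(xl, scheme)
    else:
        r_y, r_z = dispersion_coeffs(env.u * al, scheme)
    vals = np.zeros_like(xl)
    ok = (r_y > 0) & (r_z > 0)
    if np.any(ok):
        ry, rz = r_y[ok], r_z[ok]
        du = xl[ok] - env.u * al[ok]
        if scheme.normalization_mode == "as_printed":
            pref = src.m / (4.0 * np.pi * ry * rz) ** 1.5
            stream = np.exp(-(du**2) / (4.0 * ry * rz))
        else:
            rx_ = np.sqrt(ry * rz)
            pref = src.m / ((4.0 * np.pi) ** 1.5 * np.sqrt(rx_ * ry * rz))
            stream = np.exp(-(du**2) / (4.0 * rx_))
        lat = np.exp(-(yl[ok] ** 2) / (4.0 * ry))
        s_z = vertical_drift(al[ok], env) if opts.include_drift else 0.0
        s = np.sqrt(4.0 * rz)                      # sqrt(2) * sigma_z
        half = 0.5 * np.sqrt(np.pi) * s
        c1 = src.H + s_z
        col = half * (erf((hil[ok] - c1) / s) - erf((lol[ok] - c1) / s))
        if opts.ground_reflection:
            c2 = s_z - src.H
            col = col + half * (erf((hil[ok] - c2) / s) - erf((lol[ok] - c2) / s))
        v = pref * stream * lat * col
        if opts.include_decay:
            v = v * np.exp(-decay_rate(env) * al[ok])
        vals[ok] = v
    out[live] = vals
    return out if out.shape else float(out)


def continuous_concentration(x, y, z, t, emission_rate: float,
                             env: Environment = Environment(),
                             scheme: DispersionScheme = PASQUILL_F_PRINTED,
                             opts: FieldOptions = FieldOptions(),
                             quad: float = 0.001,
                             H: float = 0.8):
    """Quasi-steady plume field from a continuous release (mg/s).

    Superposition of puffs released every ``quad`` seconds from 0 to t, each
    carrying ``emission_rate * quad`` mg.  Linear in the emission rate; with
    decay on the value approaches a steady plateau as t grows.
    """
    if quad <= 0:
        raise ValueError("quad (release time step) must be positive")
    if emission_rate < 0:
        raise ValueError("emission_rate must be non-negative")
    t = float(t)
    if t < 0:
        raise ValueError("t must be non-negative")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    shape = np.broadcast(x, y, z).shape
    if emission_rate == 0.0 or t == 0.0:
        out = np.zeros(shape)
        return out if out.shape else 0.0

    release_times = np.arange(0.0, t, quad)
    src = SourceEvent(m=emission_rate * quad, H=H)
    # broadcast release times on a leading axis, sum over it
    tt = t - release_times.reshape((-1,) + (1,) * len(shape))
    c = puff_concentration(x[None, ...], y[None, ...], z[None, ...],
                           tt, src=src, env=env, scheme=scheme, opts=opts)
    total = np.sum(c, axis=0)
    return total if total.shape else float(total)
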