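"""Closed-form field and intensity correlation models.

Conventions.  q is in nm^-1; diffusion coefficients in um^2/s; velocities in
um/s; beam width sigma_B in um; times in s.  One conversion layer turns these
into nm-based units internally.  The intermediate scattering function g1 and
the intensity autocorrelation g2 are linked by the Siegert relation
g2 = baseline + beta * g1^2, with speckle contrast beta set by the beam
coherence and the angular resolution of the setup.

For driven suspensions g1 factorizes into a diffusive term, a beam-transit
term and an advective (Doppler) term:

    g1(q, t) = exp(-D q^2 t) * exp(-t^2 / (2 t_T^2)) * g1_A(q, t)

with transit time t_T = sigma_B / v, and the advective factor either
Gaussian, exp(-(q dv t)^2 / 2) (Gaussian spread of particle velocities), or
exponential, exp(-q dv t) (Lorentzian spread, turbulence-like).  For ideal
Couette flow probed along the flow direction the homodyne g2 instead carries
a sinc^2 Doppler term:

    g2(q, t) = 1 + beta * exp(-2 D q^2 t) * sinc^2(q dv t / 2),

whose first node sits at q dv t = 2 pi.  The three numeric conventions
(Gaussian transit and advective prefactors, sinc argument factor) live in
the named-constant block below so a convention change is a one-line edit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BrownianParams",
    "ActiveParams",
    "ShearParams",
    "stokes_einstein",
    "g1_brownian",
    "g2_siegert",
    "g1_active",
    "g2_active",
    "transit_time",
    "g2_shear_flow",
    "peclet_number",
]

# --- convention constants (see module docstring) ---------------------------
#: transit factor exp(-TRANSIT_GAUSS_COEFF * (t/t_T)^2)
TRANSIT_GAUSS_COEFF = 0.5
#: Gaussian advective factor exp(-ADVECTIVE_GAUSS_COEFF * (q dv t)^2)
ADVECTIVE_GAUSS_COEFF = 0.5
#: sinc argument factor: sinc(SINC_ARG_COEFF * q dv t) in the flow-direction g2
SINC_ARG_COEFF = 0.5
# ---------------------------------------------------------------------------

BOLTZMANN = 1.380649e-23  # J/K

_UM2_TO_NM2 = 1.0e6  # um^2 -> nm^2
_UM_TO_NM = 1.0e3  # um -> nm


@dataclass(frozen=True)
class BrownianParams:
    """Free diffusion: D0 in um^2/s, contrast beta, g2 baseline."""

    D0: float
    beta: float = 0.4
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")


@dataclass(frozen=True)
class ActiveParams:
    """Self-propelled suspension: diffusion D, mean speed v, velocity spread
    dv (all um-based), beam width sigma_B (um) and the advective form."""

    D: float
    v: float = 0.0
    dv: float = 0.0
    sigma_b: float = 10.62
    advective_form: str = "gaussian"

    def __post_init__(self) -> None:
        if self.v < 0 or self.dv < 0 or self.sigma_b <= 0:
            raise ValueError("require v >= 0, dv >= 0, sigma_b > 0")
        if self.advective_form not in ("gaussian", "exponential"):
            raise ValueError("advective_form must be 'gaussian' or 'exponential'")

    @property
    def transit_time_s(self) -> float:
        return transit_time(self.sigma_b, self.v)


@dataclass(frozen=True)
class ShearParams:
    """Couette shear: D0 (um^2/s), velocity difference dv across the
    scattering volume (um/s), apparent shear rate (1/s) and the cell
    geometry.  The rheometer's apparent shear rate exceeds the real one by
    ``geometry_factor`` (1.67 for a 0.5/1.0 mm capillary pair)."""

    D0: float
    dv: float
    beta: float = 0.35
    apparent_shear_rate: float = 0.0
    geometry_factor: float = 1.67
    r_inner: float = 0.5
    r_outer: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r_outer > self.r_inner > 0):
            raise ValueError("need r_outer > r_inner > 0")
        if self.geometry_factor < 1:
            raise ValueError("geometry_factor must be >= 1")

    @property
    def real_shear_rate(self) -> float:
        return self.apparent_shear_rate / self.geometry_factor


def stokes_einstein(temperature: float, viscosity: float, radius_nm: float) -> float:
    """Stokes-Einstein free diffusion coefficient, in um^2/s.

    D0 = k_B T / (6 pi eta R_H) with temperature in K, viscosity in Pa s and
    hydrodynamic radius in nm.
    """
    if temperature <= 0 or viscosity <= 0 or radius_nm <= 0:
        raise ValueError("temperature, viscosity and radius must be positive")
    d_m2 = BOLTZMANN * temperature / (6.0 * np.pi * viscosity * radius_nm * 1e-9)
    return d_m2 * 1e12  # m^2/s -> um^2/s


def g1_brownian(q: float | np.ndarray, t: float | np.ndarray, D0: float) -> np.ndarray:
    """g1 = exp(-Gamma t) with relaxation rate Gamma = D0 q^2."""
    gamma = D0 * _UM2_TO_NM2 * np.asarray(q, float) ** 2
    return np.exp(-gamma * np.asarray(t, float))


def g2_siegert(
    g1: float | np.ndarray, beta: float, baseline: float = 1.0
) -> np.ndarray:
    """Siegert relation g2 = baseline + beta * g1^2."""
    g1 = np.asarray(g1, float)
    return baseline + beta * g1 * g1


def transit_time(sigma_b: float, v: float) -> float:
    """Beam transit time t_T = sigma_B / v (s); infinite for v = 0."""
    if v < 0 or sigma_b <= 0:
        raise ValueError("require v >= 0 and sigma_b > 0")
    return np.inf if v == 0.0 else sigma_b / v


def g1_active(
    q: float | np.ndarray,
    t: float | np.ndarray,
    params: ActiveParams,
) -> np.ndarray:
    """Factorized g1 for a driven suspension (diffusive x transit x advective).

    With v = 0 the transit factor is 1 (t_T infinite); with dv = 0 the
    advective factor is 1; both zero recovers pure Brownian g1.
    """
    q = np.asarray(q, float)
    t = np.asarray(t, float)
    out = g1_brownian(q, t, params.D)
    t_t = params.transit_time_s
    if np.isfinite(t_t):
        out = out * np.exp(-TRANSIT_GAUSS_COEFF * (t / t_t) ** 2)
    if params.dv > 0.0:
        x = q * params.dv * _UM_TO_NM * t
        if params.advective_form == "gaussian":
            out = out * np.exp(-ADVECTIVE_GAUSS_COEFF * x * x)
        else:
            out = out * np.exp(-np.abs(x))
    return out


def g2_active(
    q: float | np.ndarray,
    t: float | np.ndarray,
    params: ActiveParams,
    beta: float = 0.4,
    baseline: float = 1.0,
) -> np.ndarray:
    """Siegert g2 of the factorized active g1."""
    return g2_siegert(g1_active(q, t, params), beta, baseline)


def g2_shear_flow(
    q: float | np.ndarray,
    t: float | np.ndarray,
    params: ShearParams,
    direction: str = "flow",
    baseline: float = 1.0,
) -> np.ndarray:
    """Homodyne g2 for ideal Couette flow in the radial configuration.

    direction='flow' (horizontal): g2 = 1 + beta exp(-2 Gamma t)
    sinc^2(q dv t / 2); the sinc nodes produce the characteristic
    undulations when the Doppler term dominates.  direction='vertical':
    the Doppler spread decays as a Gaussian, g2 = 1 + beta exp(-2 Gamma t)
    exp(-(q dv t)^2).
    """
    q = np.asarray(q, float)
    t = np.asarray(t, float)
    decay = np.exp(-2.0 * params.D0 * _UM2_TO_NM2 * q * q * t)
    x = q * params.dv * _UM_TO_NM * t
    if direction == "flow":
        adv = np.sinc(SINC_ARG_COEFF * x / np.pi) ** 2
    elif direction == "vertical":
        adv = np.exp(-2.0 * ADVECTIVE_GAUSS_COEFF * x * x)
    else:
        raise ValueError("direction must be 'flow' or 'vertical'")
    return baseline + params.beta * decay * adv


def peclet_number(v: float, D: float, length_scale: float) -> float:
    """Peclet number Pe = v * L / D (advection over diffusion).

    v in um/s, D in um^2/s, length_scale L in um.  In XPCS the natural probe
    length is 1/q, so pass length_scale = 1/(q * 1e3) for q in nm^-1.
    """
    if D <= 0 or length_scale <= 0 or v < 0:
        raise ValueError("require v >= 0, D > 0, length_scale > 0")
    return v * length_scale / D
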