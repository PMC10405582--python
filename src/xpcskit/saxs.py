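"""USAXS intensity models: polydisperse spheres, long hollow cylinders,
resolution smearing, and 1D lattice (axial-repeat) peak patterns.

All q values are in nm^-1 and all sizes in nm unless stated otherwise.
Polydisperse intensities are normalized so that the forward-scattering limit
equals the ``scale`` parameter; the particle-volume-squared weighting of the
dilute-suspension convention is applied inside the size average and divided
out at q = 0, so ``scale`` absorbs the contrast and concentration prefactors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.special import j1

from .geometry import RadialProfile

__all__ = [
    "SphereModel",
    "TubeModel",
    "LatticeModel",
    "sphere_form_factor",
    "polydisperse_sphere_intensity",
    "annulus_amplitude",
    "hollow_cylinder_intensity",
    "smear_resolution",
    "smeared_model",
    "lattice_peak_pattern",
    "peak_spacing",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548

#: First zero of the sphere form-factor amplitude: smallest x > 0 with
#: tan(x) = x, so the first intensity minimum sits at q*R = 4.4934.
SPHERE_FIRST_ZERO = 4.493409457909064


@dataclass(frozen=True)
class SphereModel:
    """Gaussian-polydisperse homogeneous sphere.

    mean_radius and radius_std in nm; the distribution is truncated at R > 0.
    Validity of the Gaussian description requires polydispersity
    radius_std/mean_radius < 0.3 (a warning is emitted beyond that).
    """

    mean_radius: float
    radius_std: float = 0.0
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if self.radius_std < 0:
            raise ValueError("radius_std must be >= 0")

    @property
    def polydispersity(self) -> float:
        return self.radius_std / self.mean_radius


@dataclass(frozen=True)
class TubeModel:
    """Long hollow cylinder (microtube) with Gaussian size distributions.

    mean_radius R_C is the midwall radius and wall_thickness t_W the wall
    thickness, both in nm; outer/inner radii are R_C +- t_W/2.  Both size
    distributions are truncated so the inner radius stays positive.
    """

    mean_radius: float
    wall_thickness: float
    radius_polydispersity: float = 0.0
    thickness_polydispersity: float = 0.0
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mean_radius > self.wall_thickness / 2.0 > 0.0):
            raise ValueError("need mean_radius > wall_thickness/2 > 0")
        if self.radius_polydispersity < 0 or self.thickness_polydispersity < 0:
            raise ValueError("polydispersities must be >= 0")


@dataclass(frozen=True)
class LatticeModel:
    """1D lattice of Gaussian reflections at q_n = 2*pi*n/d.

    period d in um, peak_width (FWHM) in nm^-1; ``amplitudes`` holds the
    per-order relative amplitudes (the form-factor envelope), defaulting to
    equal amplitudes.
    """

    period: float
    peak_width: float = 2.4e-4
    n_orders: int = 5
    amplitudes: tuple[float, ...] | None = None
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")
        if self.amplitudes is not None and len(self.amplitudes) != self.n_orders:
            raise ValueError("amplitudes must have n_orders entries")


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized single-sphere form factor P(q, R), with P(0, R) = 1.

    P = [3 (sin(qR) - qR cos(qR)) / (qR)^3]^2; the q -> 0 limit is handled
    by the series expansion of the amplitude.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    x = np.asarray(q, dtype=float) * radius
    # series below x = 1e-2 (error ~ x^4/280) avoids the x^3 cancellation
    small = np.abs(x) < 1e-2
    xs = np.where(small, 1.0, x)
    amp = np.where(
        small,
        1.0 - x * x / 10.0 + x**4 / 280.0,
        3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3,
    )
    return amp * amp


def _gauss_nodes(mean: float, sigma: float, n: int, lower: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for a Gaussian number density truncated
    at ``lower``; weights include the (unnormalized) Gaussian density."""
    lo = max(lower, mean - 5.0 * sigma)
    hi = mean + 5.0 * sigma
    x, w = np.polynomial.legendre.leggauss(n)
    nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    dens = np.exp(-0.5 * ((nodes - mean) / sigma) ** 2)
    return nodes, w * 0.5 * (hi - lo) * dens


def polydisperse_sphere_intensity(
    q: np.ndarray, model: SphereModel, n_nodes: int = 61
) -> np.ndarray:
    """Number-averaged sphere intensity with V(R)^2 weighting.

    I(q) = scale * <V(R)^2 P(q, R)> / <V(R)^2> + background, where <.> is the
    average over the truncated Gaussian radius distribution, evaluated by
    fixed-order Gauss-Legendre quadrature over mean +- 5 sigma.
    """
    q = np.asarray(q, dtype=float)
    if model.polydispersity >= 0.3:
        warnings.warn(
            "polydispersity >= 0.3: Gaussian size distribution is a poor "
            "description in this regime",
            stacklevel=2,
        )
    if model.radius_std == 0.0:
        return model.scale * sphere_form_factor(q, model.mean_radius) + model.background
    radii, wts = _gauss_nodes(
        model.mean_radius, model.radius_std, n_nodes, lower=1e-6 * model.mean_radius
    )
    v2 = radii**6  # (4*pi/3)^2 cancels in the normalization
    pq = np.empty((q.size, radii.size))
    for j, r in enumerate(radii):
        pq[:, j] = sphere_form_factor(q, r)
    num = pq @ (wts * v2)
    den = np.sum(wts * v2)
    return model.scale * num / den + model.background


def annulus_amplitude(q: np.ndarray, r_outer: float, r_inner: float) -> np.ndarray:
    """Normalized annular cross-section amplitude A_cs(q), A_cs(0) = 1.

    A_cs = [R_o^2 2J1(qR_o)/(qR_o) - R_i^2 2J1(qR_i)/(qR_i)] / (R_o^2 - R_i^2).
    ``r_inner = 0`` gives the solid-disc amplitude 2J1(qR_o)/(qR_o).
    """
    if not (r_outer > r_inner >= 0):
        raise ValueError("need r_outer > r_inner >= 0")
    q = np.asarray(q, dtype=float)

    def disc(qr: np.ndarray) -> np.ndarray:
        small = np.abs(qr) < 1e-8
        qrs = np.where(small, 1.0, qr)
        return np.where(small, 1.0 - qr * qr / 8.0, 2.0 * j1(qrs) / qrs)

    if r_inner == 0.0:
        return disc(q * r_outer)
    ro2, ri2 = r_outer**2, r_inner**2
    return (ro2 * disc(q * r_outer) - ri2 * disc(q * r_inner)) / (ro2 - ri2)


def hollow_cylinder_intensity(
    q: np.ndarray,
    model: TubeModel,
    n_radius: int = 31,
    n_thickness: int = 61,
) -> np.ndarray:
    """Orientationally averaged long hollow-cylinder intensity.

    In the long-tube limit (length >> 2*pi/q) the orientational average
    contributes a 1/q prefactor and the cross-section scatters as
    A_cs(q)^2, weighted by the cross-section area squared across the joint
    Gaussian distribution of midwall radius and wall thickness (nested
    quadrature, truncated so that the inner radius stays positive):

        I(q) = scale * (1/q) * <area^2 A_cs^2> / <area^2> + background.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("hollow-cylinder model requires q > 0 (1/q prefactor)")
    sig_r = model.radius_polydispersity * model.mean_radius
    sig_t = model.thickness_polydispersity * model.wall_thickness

    if sig_r == 0.0:
        radii, w_r = np.array([model.mean_radius]), np.array([1.0])
    else:
        radii, w_r = _gauss_nodes(model.mean_radius, sig_r, n_radius, lower=1e-3)
    if sig_t == 0.0:
        thicks, w_t = np.array([model.wall_thickness]), np.array([1.0])
    else:
        thicks, w_t = _gauss_nodes(
            model.wall_thickness, sig_t, n_thickness, lower=1e-3 * model.wall_thickness
        )

    num = np.zeros_like(q)
    den = 0.0
    for rc, wr in zip(radii, w_r):
        r_out = rc + thicks / 2.0
        r_in = rc - thicks / 2.0
        ok = r_in > 0.0
        if not ok.any():
            continue
        for t_idx in np.nonzero(ok)[0]:
            ro, ri = r_out[t_idx], r_in[t_idx]
            area2 = (ro**2 - ri**2) ** 2
            w = wr * w_t[t_idx] * area2
            a = annulus_amplitude(q, ro, ri)
            num += w * a * a
            den += w
    if den == 0.0:
        raise ValueError("size distributions leave no geometry with R_inner > 0")
    return model.scale * num / (den * q) + model.background


def smeared_model(model_fn, q: np.ndarray, dq_fwhm: float, oversample: float = 4.0) -> np.ndarray:
    """Evaluate ``model_fn`` on ``q`` convolved with a Gaussian resolution
    function of FWHM ``dq_fwhm``.

    The model is re-evaluated on a uniform fine grid extended 6 sigma beyond
    both ends of ``q`` (no padding artefacts), convolved, and interpolated
    back onto ``q``.  ``dq_fwhm <= 0`` is the identity.
    """
    q = np.asarray(q, dtype=float)
    if dq_fwhm <= 0:
        return model_fn(q)
    sigma = dq_fwhm * FWHM_TO_SIGMA
    step = sigma / oversample
    lo = max(q[0] - 6.0 * sigma, step / 10.0)
    hi = q[-1] + 6.0 * sigma
    fine = np.arange(lo, hi + step, step)
    vals = model_fn(fine)
    half = int(np.ceil(6.0 * sigma / step))
    kq = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (kq / sigma) ** 2)
    kernel /= kernel.sum()
    sm = np.convolve(vals, kernel, mode="same")
    # drop the edge region where the kernel ran off the extended grid
    return np.interp(q, fine, sm)


def smear_resolution(profile: RadialProfile, dq_fwhm: float) -> RadialProfile:
    """Gaussian resolution smearing of a tabulated profile.

    Where no analytic model is available the profile itself is interpolated
    (edge values extended) to build the fine grid.  If the tabulated spacing
    is coarser than dq_fwhm/2 the profile is already unresolved and smearing
    is a no-op (with a warning).
    """
    if dq_fwhm <= 0:
        return profile
    spacing = np.min(np.diff(profile.q))
    if spacing >= dq_fwhm / 2.0:
        warnings.warn(
            "profile q-spacing exceeds dq_fwhm/2; smearing skipped", stacklevel=2
        )
        return profile

    def interp_model(qf: np.ndarray) -> np.ndarray:
        return np.interp(qf, profile.q, profile.intensity)

    sm = smeared_model(interp_model, profile.q, dq_fwhm)
    return RadialProfile(
        q=profile.q.copy(), intensity=sm, error=profile.error.copy(),
        n_pix=profile.n_pix.copy(),
    )


def lattice_peak_pattern(q: np.ndarray, model: LatticeModel) -> np.ndarray:
    """Sum of Gaussian reflections at q_n = 2*pi*n/d, n = 1..n_orders."""
    q = np.asarray(q, dtype=float)
    d_nm = model.period * 1e3
    sigma = model.peak_width * FWHM_TO_SIGMA
    amps = model.amplitudes or (1.0,) * model.n_orders
    out = np.full_like(q, model.background)
    for n, a in enumerate(amps, start=1):
        qn = 2.0 * np.pi * n / d_nm
        out += a * np.exp(-0.5 * ((q - qn) / sigma) ** 2)
    return out


class NoPeakError(ValueError):
    """No local maximum above background was found in the profile."""


def peak_spacing(profile: RadialProfile, background: float = 0.0) -> float:
    """Lattice period d (in um) from the reflections of a 1D profile.

    Local maxima above ``background`` are located with a prominence
    criterion, each refined by a 3-point parabolic fit, the first-order
    peak inverted as d = 2*pi/q1 and cross-checked against the mean of
    2*pi*n/q_n over all detected orders (consistent order assignment by
    rounding q_n/q1).
    """
    y = profile.intensity - background
    span = float(np.max(y) - np.min(y))
    if span <= 0:
        raise NoPeakError("profile is flat")
    idx, _ = find_peaks(y, prominence=0.05 * span)
    idx = idx[y[idx] > 0]
    if idx.size == 0:
        raise NoPeakError("no peak above background")

    q_peaks = []
    for i in idx:
        if 0 < i < len(y) - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2.0 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            # parabolic vertex in index space; map through the local grid
            qp = profile.q[i] + delta * (profile.q[min(i + 1, len(y) - 1)] - profile.q[i - 1]) / 2.0
        else:
            qp = profile.q[i]
        q_peaks.append(qp)
    q_peaks = np.sort(np.asarray(q_peaks))
    q1 = q_peaks[0]
    orders = np.maximum(np.round(q_peaks / q1), 1.0)
    d_nm = float(np.mean(2.0 * np.pi * orders / q_peaks))
    return d_nm * 1e-3
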