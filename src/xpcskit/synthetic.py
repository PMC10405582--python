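"""Synthetic inputs: particle trajectories, phasor-sum speckle stacks, and
directly synthesized noisy g2 / I(q) tables.

The speckle renderer computes, per frame, the coherent far field
E(q_vec) = sum_j exp(i q_vec . r_j) on the detector's transverse (q_x, q_y)
grid (small-angle limit: the beam-axis coordinate evolves but does not enter
the phase), converts |E|^2 to a target mean count rate and Poisson-samples
it.  A fully coherent single mode gives exponential intensity statistics
across pixels and speckle contrast beta = 1; averaging M independent mode
fields lowers the contrast to 1/M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .correlator import CorrelationSet, FrameStack
from .geometry import DetectorGeometry, RadialProfile, transverse_q_components
from .saxs import (
    LatticeModel,
    SphereModel,
    TubeModel,
    hollow_cylinder_intensity,
    lattice_peak_pattern,
    polydisperse_sphere_intensity,
    smeared_model,
)

__all__ = [
    "ParticleEnsemble",
    "commensurate_box_um",
    "simulate_tracks",
    "speckle_frames",
    "synth_g2_curves",
    "synth_saxs_profile",
]

_UM_TO_NM = 1.0e3


def commensurate_box_um(geometry: DetectorGeometry) -> float:
    """Periodic box size (um) commensurate with the detector q grid.

    Returns 2*pi / dq_pixel with dq_pixel the transverse q spacing of one
    pixel.  With an integer-pixel beam center every pixel q is then an
    integer multiple of 2*pi/box, so the phasor sum is exactly invariant
    under periodic wrapping of the particle coordinates; any other box size
    makes each boundary crossing a phase jump, i.e. a spurious extra
    decorrelation channel.
    """
    dq = (2.0 * np.pi / geometry.wavelength) * geometry.pixel_pitch / geometry.distance
    return 2.0 * np.pi / dq / _UM_TO_NM


@dataclass
class ParticleEnsemble:
    """Trajectories of point particles in a periodic box.

    positions: (n_steps, n_particles, 3) in nm, wrapped into [0, box);
    dt: step in s; motion: generator label with its parameters.
    """

    positions: np.ndarray
    box: float
    dt: float
    motion: str
    params: dict

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]


def simulate_tracks(
    motion: str,
    n_particles: int,
    n_steps: int,
    dt: float,
    seed: int,
    D0: float = 0.0,
    v: float = 0.0,
    dv: float = 0.0,
    speed_distribution: str = "gaussian",
    shear_rate: float = 0.0,
    box_um: float = 40.0,
) -> ParticleEnsemble:
    """Simulate Brownian / active / sheared point-particle trajectories.

    motion:
      'brownian' — isotropic steps of std sqrt(2 D0 dt) per axis;
      'active'   — Brownian plus ballistic drift v_j * n_j * dt with fixed
                   random headings n_j and per-particle speeds drawn from a
                   Gaussian(v, dv) or Lorentzian(v, dv) distribution;
      'shear'    — Brownian plus a deterministic linear profile
                   v_x(y) = shear_rate * (y - box/2) (gradient along y).

    D0 in um^2/s, v and dv in um/s, shear_rate in 1/s, box in um; positions
    come out in nm, periodically wrapped.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if motion not in ("brownian", "active", "shear"):
        raise ValueError(f"unknown motion kind {motion!r}")
    rng = np.random.default_rng(seed)
    box = box_um * _UM_TO_NM
    d_nm = D0 * 1e6  # um^2/s -> nm^2/s
    step_rms = np.sqrt(2.0 * d_nm * dt)
    if step_rms > box / 10.0:
        warnings.warn(
            "diffusive step exceeds box/10; trajectories are under-resolved",
            stacklevel=2,
        )

    start = rng.uniform(0.0, box, size=(1, n_particles, 3))
    steps = np.zeros((n_steps - 1, n_particles, 3)) if n_steps > 1 else np.zeros((0, n_particles, 3))
    if step_rms > 0 and n_steps > 1:
        steps = rng.normal(0.0, step_rms, size=(n_steps - 1, n_particles, 3))

    if motion == "active":
        headings = rng.normal(size=(n_particles, 3))
        headings /= np.linalg.norm(headings, axis=1, keepdims=True)
        if speed_distribution == "gaussian":
            speeds = rng.normal(v, dv, size=n_particles)
        elif speed_distribution == "lorentzian":
            speeds = v + dv * rng.standard_cauchy(size=n_particles)
        else:
            raise ValueError("speed_distribution must be 'gaussian' or 'lorentzian'")
        drift = speeds[:, None] * headings * _UM_TO_NM * dt  # nm per step
        steps = steps + drift[None, :, :]
        positions = np.concatenate([start, start + np.cumsum(steps, axis=0)]) % box
        extra = {"headings": headings, "speeds": speeds}
    elif motion == "shear":
        extra = {}
        positions = np.empty((n_steps, n_particles, 3))
        positions[0] = start[0]
        for i in range(1, n_steps):
            prev = positions[i - 1]
            vx = shear_rate * (prev[:, 1] - box / 2.0)  # nm/s from nm offset
            disp = steps[i - 1].copy()
            disp[:, 0] += vx * dt
            positions[i] = (prev + disp) % box
    else:
        extra = {}
        positions = np.concatenate([start, start + np.cumsum(steps, axis=0)]) % box

    return ParticleEnsemble(
        positions=positions,
        box=box,
        dt=dt,
        motion=motion,
        params={
            "D0": D0, "v": v, "dv": dv, "shear_rate": shear_rate,
            "speed_distribution": speed_distribution, "seed": seed,
            **extra,
        },
    )


def speckle_frames(
    tracks: ParticleEnsemble,
    geometry: DetectorGeometry,
    shape: tuple[int, int],
    mean_counts: float = 5.0,
    n_modes: int = 1,
    seed: int = 0,
    beam_sigma_weights: bool = False,
    max_count: int = 255,
) -> FrameStack:
    """Render a coherent speckle frame stack from particle tracks.

    Per frame the field is the phasor sum over particles on the separable
    (q_x, q_y) pixel grid, evaluated as two small complex matrix products.
    Intensities are scaled to ``mean_counts`` photons/pixel on average and
    Poisson-sampled.  ``n_modes > 1`` splits the particles into independent
    groups whose intensities add, lowering the speckle contrast to
    1/n_modes.  ``beam_sigma_weights`` applies a Gaussian illumination
    envelope of width sigma_B (transit effect) to the particle weights.
    """
    rng = np.random.default_rng(seed)
    qx, qy = transverse_q_components(geometry, shape)
    pos = tracks.positions
    n_steps, n_part = pos.shape[0], pos.shape[1]
    if mean_counts < 0.01:
        warnings.warn("mean counts < 0.01: correlation statistics will be poor",
                      stacklevel=2)
    groups = np.array_split(np.arange(n_part), n_modes)
    intensity = np.empty((n_steps, shape[0], shape[1]))
    for i in range(n_steps):
        x = pos[i, :, 0]
        y = pos[i, :, 1]
        if beam_sigma_weights:
            sig = geometry.beam_sigma * _UM_TO_NM
            w = np.exp(-0.5 * ((x - tracks.box / 2.0) / sig) ** 2)
        else:
            w = None
        frame = np.zeros((shape[0], shape[1]))
        for g in groups:
            a = np.exp(1j * np.outer(qx, x[g]))  # (ncol, n_g)
            if w is not None:
                a = a * w[g]
            b = np.exp(1j * np.outer(qy, y[g]))  # (nrow, n_g)
            e = b @ a.T  # (nrow, ncol)
            frame += np.abs(e) ** 2
        intensity[i] = frame
    scale = mean_counts / intensity.mean()
    counts = rng.poisson(intensity * scale)
    if counts.max() > max_count:
        warnings.warn(
            f"counts exceed {max_count}; a saturating detector would clip these",
            stacklevel=2,
        )
    return FrameStack(counts=counts, frame_interval=tracks.dt)


def synth_g2_curves(
    model_fn,
    q_values: np.ndarray,
    lags: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CorrelationSet:
    """Evaluate a g2 model on a (q, lag) grid and add Gaussian noise.

    ``model_fn(q, t)`` must broadcast; the noise is lag-independent Gaussian
    of standard deviation ``noise_sigma`` and the per-point uncertainty
    column is set to that value.
    """
    rng = np.random.default_rng(seed)
    q_values = np.atleast_1d(np.asarray(q_values, float))
    lags = np.asarray(lags, float)
    g2 = np.empty((lags.size, q_values.size))
    for j, qv in enumerate(q_values):
        g2[:, j] = model_fn(qv, lags)
    if noise_sigma > 0:
        g2 = g2 + rng.normal(0.0, noise_sigma, size=g2.shape)
    err = np.full_like(g2, noise_sigma if noise_sigma > 0 else 0.0)
    return CorrelationSet(lags=lags, q=q_values, g2=g2, g2_err=err)


def synth_saxs_profile(
    model: SphereModel | TubeModel | LatticeModel,
    q: np.ndarray,
    dq_fwhm: float = 0.0,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> RadialProfile:
    """Generate a noisy, resolution-smeared 1D scattering profile.

    The model intensity is smeared with the Gaussian resolution function of
    FWHM ``dq_fwhm`` (re-evaluating the model beyond the grid edges) and
    multiplied by log-normal noise of fractional standard deviation
    ``noise_fraction``; the uncertainty column is set accordingly.
    """
    q = np.asarray(q, float)
    if isinstance(model, SphereModel):
        fn = lambda qq: polydisperse_sphere_intensity(qq, model)  # noqa: E731
    elif isinstance(model, TubeModel):
        fn = lambda qq: hollow_cylinder_intensity(qq, model)  # noqa: E731
    elif isinstance(model, LatticeModel):
        fn = lambda qq: lattice_peak_pattern(qq, model)  # noqa: E731
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    intensity = smeared_model(fn, q, dq_fwhm) if dq_fwhm > 0 else fn(q)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * np.exp(
            rng.normal(0.0, noise_fraction, size=q.shape)
        )
    error = np.abs(intensity) * noise_fraction
    return RadialProfile(q=q, intensity=intensity, error=error)
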