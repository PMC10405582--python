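"""Detector geometry, q-maps and reduction of 2D patterns to 1D profiles.

The scattering-vector magnitude for a pixel at radial distance ``r`` (in
fractional pixels) from the beam center is

    q = (4*pi/lambda) * sin(theta/2),   theta = atan(r * pitch / L),

with the X-ray wavelength ``lambda`` in nm and the sample-detector distance
``L`` in m, so q comes out in nm^-1.  Azimuth is measured from the
+horizontal (column) axis, counter-clockwise positive, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DetectorGeometry",
    "QMap",
    "RadialProfile",
    "InvalidGeometryError",
    "EmptyProfileError",
    "EmptySectorError",
    "GridMismatchError",
    "build_qmap",
    "azimuthal_average",
    "sector_average",
    "subtract_background",
]


class InvalidGeometryError(ValueError):
    """Non-physical detector geometry (non-positive length scales)."""


class EmptyProfileError(ValueError):
    """Reduction produced no usable bins (e.g. everything masked)."""


class EmptySectorError(ValueError):
    """An azimuthal sector selection contains no pixels."""


class GridMismatchError(ValueError):
    """Two radial profiles do not share the same q grid."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Beamline geometry needed to map pixels to scattering vectors.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in nm.
    distance : float
        Sample-to-detector distance in m.
    pixel_pitch : float
        Detector pixel pitch in m.
    beam_center : tuple of float
        (row, col) position of the direct beam in fractional pixels; may lie
        outside the detector area.
    beam_sigma : float
        Gaussian width sigma_B of the beam at the sample position, in um.
        A 25 um FWHM beam corresponds to sigma_B = 25/2.3548 = 10.62 um.
    q_resolution_fwhm : float
        FWHM q resolution of the setup, in nm^-1.  This is a configuration
        input, not derived from the other fields.
    """

    wavelength: float
    distance: float
    pixel_pitch: float
    beam_center: tuple[float, float]
    beam_sigma: float = 10.62
    q_resolution_fwhm: float = 2.4e-4

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.distance <= 0 or self.pixel_pitch <= 0:
            raise InvalidGeometryError(
                "wavelength, distance and pixel_pitch must all be positive"
            )
        if self.beam_sigma <= 0 or self.q_resolution_fwhm <= 0:
            raise InvalidGeometryError(
                "beam_sigma and q_resolution_fwhm must be positive"
            )


@dataclass(frozen=True)
class QMap:
    """Per-pixel scattering-vector magnitude (nm^-1) and azimuth (deg)."""

    q: np.ndarray
    azimuth: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.q.shape


@dataclass
class RadialProfile:
    """Azimuthally averaged 1D scattering profile.

    Attributes
    ----------
    q : ndarray
        Bin-center q values, nm^-1, strictly increasing.
    intensity : ndarray
        Mean intensity per bin.
    error : ndarray
        Standard error of the mean per bin.
    n_pix : ndarray
        Number of contributing pixels per bin (>= 1 for every reported bin).
    """

    q: np.ndarray
    intensity: np.ndarray
    error: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_pix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.error is None:
            self.error = np.zeros_like(self.q)
        else:
            self.error = np.asarray(self.error, dtype=float)
        if self.n_pix is None:
            self.n_pix = np.ones(self.q.shape, dtype=int)
        else:
            self.n_pix = np.asarray(self.n_pix, dtype=int)
        if self.q.ndim != 1 or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be 1D and strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "q_nm_inv": self.q,
                "I": self.intensity,
                "I_err": self.error,
                "n_pix": self.n_pix,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RadialProfile":
        df = pd.read_csv(path)
        return cls(
            q=df["q_nm_inv"].to_numpy(),
            intensity=df["I"].to_numpy(),
            error=df["I_err"].to_numpy(),
            n_pix=df["n_pix"].to_numpy(),
        )


def build_qmap(geometry: DetectorGeometry, shape: tuple[int, int]) -> QMap:
    """Map every pixel of a ``shape = (rows, cols)`` detector to (q, azimuth).

    q(pixel) = (4*pi/lambda) sin(theta/2) with theta = atan(r*pitch/L); the
    azimuth is 0 along +horizontal and increases counter-clockwise (i.e.
    towards decreasing row index in image convention), in [0, 360).
    """
    nrow, ncol = int(shape[0]), int(shape[1])
    if nrow <= 0 or ncol <= 0:
        raise ValueError("shape must be positive")
    r0, c0 = geometry.beam_center
    rows = np.arange(nrow, dtype=float)[:, None] - r0
    cols = np.arange(ncol, dtype=float)[None, :] - c0
    r_pix = np.hypot(rows, cols)
    theta = np.arctan(r_pix * geometry.pixel_pitch / geometry.distance)
    q = (4.0 * np.pi / geometry.wavelength) * np.sin(theta / 2.0)
    azimuth = np.degrees(np.arctan2(-rows, np.broadcast_to(cols, q.shape))) % 360.0
    return QMap(q=q, azimuth=azimuth)


def transverse_q_components(
    geometry: DetectorGeometry, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Small-angle transverse (q_x, q_y) per pixel, nm^-1.

    q_x runs along +columns, q_y along the upward (decreasing-row) axis;
    used by the phasor-sum speckle renderer where q_vec . r uses only the
    transverse coordinates.
    """
    nrow, ncol = int(shape[0]), int(shape[1])
    r0, c0 = geometry.beam_center
    k = 2.0 * np.pi / geometry.wavelength
    qx = k * (np.arange(ncol) - c0) * geometry.pixel_pitch / geometry.distance
    qy = k * -(np.arange(nrow) - r0) * geometry.pixel_pitch / geometry.distance
    return qx, qy


def azimuthal_average(
    pattern: np.ndarray,
    qmap: QMap,
    q_bins: np.ndarray,
    mask: np.ndarray | None = None,
) -> RadialProfile:
    """Azimuthally average a 2D pattern into q bins.

    ``q_bins`` are strictly increasing bin edges; a pixel belongs to the bin
    containing its center q (no pixel splitting).  Masked pixels (mask True)
    are excluded and empty bins are omitted from the output.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != qmap.shape:
        raise ValueError("pattern and qmap shapes differ")
    q_bins = np.asarray(q_bins, dtype=float)
    if np.any(np.diff(q_bins) <= 0):
        raise ValueError("q_bins must be strictly increasing")
    keep = np.ones(pattern.shape, dtype=bool) if mask is None else ~np.asarray(mask, bool)
    if not keep.any():
        raise EmptyProfileError("all pixels are masked")

    qv = qmap.q[keep]
    iv = pattern[keep]
    idx = np.digitize(qv, q_bins) - 1
    valid = (idx >= 0) & (idx < len(q_bins) - 1)
    qv, iv, idx = qv[valid], iv[valid], idx[valid]
    if idx.size == 0:
        raise EmptyProfileError("no unmasked pixel falls inside the q bins")

    nbin = len(q_bins) - 1
    counts = np.bincount(idx, minlength=nbin)
    sums = np.bincount(idx, weights=iv, minlength=nbin)
    occupied = counts > 0
    mean_full = np.where(occupied, sums / np.maximum(counts, 1), 0.0)
    # two-pass variance: immune to cancellation on near-constant images
    dev2 = np.bincount(idx, weights=(iv - mean_full[idx]) ** 2, minlength=nbin)
    n = counts[occupied]
    mean = mean_full[occupied]
    var = dev2[occupied] / n
    # sample std (ddof=1) / sqrt(N); zero where a bin has a single pixel
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(n > 1, np.sqrt(var * n / np.maximum(n - 1, 1)), 0.0)
    stderr = std / np.sqrt(n)
    centers = 0.5 * (q_bins[:-1] + q_bins[1:])[occupied]
    return RadialProfile(q=centers, intensity=mean, error=stderr, n_pix=n)


def sector_average(
    qmap: QMap,
    center_angle: float,
    half_width: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean selection of pixels in an azimuthal sector (plus its mirror).

    Selects pixels whose azimuth lies within ``half_width`` degrees of
    ``center_angle`` or of ``center_angle + 180`` (Friedel symmetry).
    """
    if not (0.0 < half_width <= 90.0):
        raise ValueError("half_width must be in (0, 90]")
    diff = np.abs((qmap.azimuth - center_angle + 90.0) % 180.0 - 90.0)
    selected = diff <= half_width
    if mask is not None:
        selected &= ~np.asarray(mask, bool)
    if not selected.any():
        raise EmptySectorError(
            f"no pixel within +-{half_width} deg of {center_angle} deg"
        )
    return selected


def subtract_background(
    sample: RadialProfile,
    background: RadialProfile,
    transmission_ratio: float = 1.0,
) -> RadialProfile:
    """I_out = I_sample - ratio * I_background, errors added in quadrature."""
    if sample.q.shape != background.q.shape or not np.allclose(
        sample.q, background.q, rtol=1e-10, atol=0.0
    ):
        raise GridMismatchError("sample and background q grids differ")
    intensity = sample.intensity - transmission_ratio * background.intensity
    error = np.hypot(sample.error, transmission_ratio * background.error)
    return RadialProfile(
        q=sample.q.copy(), intensity=intensity, error=error, n_pix=sample.n_pix.copy()
    )
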