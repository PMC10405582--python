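"""Pixel-wise intensity autocorrelation and ensemble averaging.

The estimator is the symmetric-normalization form

    g2(k) = < I_t I_{t+k} >_t / ( <I_t>_{t in [0, N-k)} <I_{t+k}> ),

which normalizes numerator and denominator over the same time window and so
suppresses slow-drift bias.  ``direct_correlate`` is the O(N * max_lag)
reference; ``multitau_correlate`` reproduces it exactly at level 0 and, at
higher levels, applies the same estimator to progressively pair-averaged
frames, producing the standard quasi-logarithmic lag grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .geometry import QMap, sector_average

__all__ = [
    "FrameStack",
    "CorrelationSet",
    "UndefinedG2Error",
    "InsufficientFramesError",
    "NoContrastError",
    "direct_correlate",
    "multitau_correlate",
    "ensemble_g2",
    "estimate_contrast",
]


class UndefinedG2Error(ValueError):
    """g2 is undefined (zero mean intensity in the normalization window)."""


class InsufficientFramesError(ValueError):
    """The stack is too short for the requested correlator configuration."""


class NoContrastError(ValueError):
    """The correlation curve shows no decaying contrast to estimate."""


@dataclass
class FrameStack:
    """Time-ordered stack of detector count frames.

    counts: (n_frames, rows, cols) non-negative integers;
    frame_interval: s; mask: optional boolean image (True = excluded).
    """

    counts: np.ndarray
    frame_interval: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[0] < 2:
            raise ValueError("counts must be (n_frames >= 2, rows, cols)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.counts.shape[1:]:
                raise ValueError("mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.counts, compression="gzip")
            f.create_dataset("frame_interval_s", data=self.frame_interval)
            if self.mask is not None:
                f.create_dataset("mask", data=self.mask.astype(np.uint8))

    @classmethod
    def from_hdf5(cls, path) -> "FrameStack":
        with h5py.File(path, "r") as f:
            counts = f["frames"][...]
            interval = float(f["frame_interval_s"][()])
            mask = f["mask"][...].astype(bool) if "mask" in f else None
        return cls(counts=counts, frame_interval=interval, mask=mask)


@dataclass
class CorrelationSet:
    """Ensemble-averaged g2(q, t) curves.

    lags: (n_lags,) strictly increasing lag times in s, starting at the
    frame interval; q: (n_q,) representative q per bin (nm^-1); g2 and
    g2_err: (n_lags, n_q); n_pix and mean_intensity: (n_q,).  ``q_sq`` holds
    the pixel-mean q^2 per bin, the correct abscissa for Gamma-vs-q^2
    regressions when bins have finite width.
    """

    lags: np.ndarray
    q: np.ndarray
    g2: np.ndarray
    g2_err: np.ndarray = None  # type: ignore[assignment]
    n_pix: np.ndarray = None  # type: ignore[assignment]
    mean_intensity: np.ndarray = None  # type: ignore[assignment]
    q_sq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.q = np.atleast_1d(np.asarray(self.q, float))
        self.g2 = np.atleast_2d(np.asarray(self.g2, float))
        if self.g2.shape != (self.lags.size, self.q.size):
            raise ValueError("g2 must have shape (n_lags, n_q)")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.g2_err is None:
            self.g2_err = np.zeros_like(self.g2)
        else:
            self.g2_err = np.atleast_2d(np.asarray(self.g2_err, float))
        if self.n_pix is None:
            self.n_pix = np.ones(self.q.size, dtype=int)
        if self.mean_intensity is None:
            self.mean_intensity = np.ones(self.q.size)
        if self.q_sq is None:
            self.q_sq = self.q**2

    def to_csv(self, path) -> None:
        rows = []
        for j, qv in enumerate(self.q):
            for i, lag in enumerate(self.lags):
                rows.append(
                    (lag, qv, self.g2[i, j], self.g2_err[i, j],
                     self.n_pix[j], self.mean_intensity[j])
                )
        pd.DataFrame(
            rows, columns=["lag_s", "q_nm_inv", "g2", "g2_err", "n_pix", "mean_I"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorrelationSet":
        df = pd.read_csv(path)
        qs = np.sort(df["q_nm_inv"].unique())
        lags = np.sort(df["lag_s"].unique())
        g2 = np.empty((lags.size, qs.size))
        err = np.empty_like(g2)
        n_pix = np.empty(qs.size, int)
        mean_i = np.empty(qs.size)
        for j, qv in enumerate(qs):
            sub = df[df["q_nm_inv"] == qv].sort_values("lag_s")
            g2[:, j] = sub["g2"].to_numpy()
            err[:, j] = sub["g2_err"].to_numpy()
            n_pix[j] = int(sub["n_pix"].iloc[0])
            mean_i[j] = float(sub["mean_I"].iloc[0])
        return cls(lags=lags, q=qs, g2=g2, g2_err=err, n_pix=n_pix,
                   mean_intensity=mean_i)


def _g2_at_lag(data: np.ndarray, k: int) -> np.ndarray:
    """Symmetric-normalization estimator at integer lag k.

    ``data`` is (n_times, ...) float; returns g2 with the leading axis
    reduced.  Zero mean in either window makes the estimate undefined.
    """
    head = data[:-k] if k > 0 else data
    tail = data[k:]
    num = np.mean(head * tail, axis=0)
    m1 = np.mean(head, axis=0)
    m2 = np.mean(tail, axis=0)
    den = m1 * m2
    bad = den == 0
    if np.isscalar(bad):
        if bad:
            raise UndefinedG2Error("zero mean intensity")
        return num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return out


def direct_correlate(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Reference O(N * max_lag) autocorrelator for a single intensity trace.

    Returns g2 at integer lags 1..max_lag.
    """
    series = np.asarray(series, float)
    n = series.shape[0]
    if max_lag < 1 or max_lag >= n:
        raise ValueError("need 1 <= max_lag < len(series)")
    if np.all(series == 0):
        raise UndefinedG2Error("zero mean intensity trace")
    return np.array([_g2_at_lag(series, k) for k in range(1, max_lag + 1)])


def multitau_lags(n_frames: int, n_per_level: int = 16, n_levels: int | None = None) -> np.ndarray:
    """Integer frame lags of the multi-tau grid for a stack of n_frames."""
    lags, _ = _multitau_plan(n_frames, n_per_level, n_levels)
    return lags


def _multitau_plan(n_frames: int, n_per_level: int, n_levels: int | None):
    if n_per_level < 4 or n_per_level % 2:
        raise ValueError("n_per_level must be even and >= 4")
    if n_frames <= n_per_level:
        raise InsufficientFramesError(
            f"need more than {n_per_level} frames, got {n_frames}"
        )
    plan = []  # (level, lag_in_level_units)
    level = 0
    n = n_frames
    while True:
        lag_set = range(1, n_per_level + 1) if level == 0 else range(
            n_per_level // 2 + 1, n_per_level + 1
        )
        for j in lag_set:
            if j < n:  # at least one product pair at this lag
                plan.append((level, j))
        level += 1
        n //= 2
        if n <= n_per_level // 2 + 1 or (n_levels is not None and level >= n_levels):
            break
    lags = np.array([j << lv for lv, j in plan])
    return lags, plan


def multitau_correlate(
    stack: FrameStack,
    n_per_level: int = 16,
    n_levels: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel multi-tau g2 tables.

    Returns ``(lags_s, g2)`` with lags_s the quasi-logarithmic lag grid in
    seconds and g2 of shape (n_lags, rows, cols).  Level 0 applies the
    symmetric estimator to the raw frames at lags 1..n_per_level; each
    subsequent level averages adjacent frame pairs and evaluates lags
    n_per_level/2+1..n_per_level of the averaged series.
    """
    _, plan = _multitau_plan(stack.n_frames, n_per_level, n_levels)
    data = stack.counts.astype(float)
    g2_list = []
    lag_frames = []
    level = 0
    for lv, j in plan:
        while level < lv:
            n_pairs = data.shape[0] // 2
            data = 0.5 * (data[: 2 * n_pairs : 2] + data[1 : 2 * n_pairs : 2])
            level += 1
        g2_list.append(_g2_at_lag(data, j))
        lag_frames.append(j << lv)
    lags_s = np.asarray(lag_frames, float) * stack.frame_interval
    return lags_s, np.stack(g2_list, axis=0)


def ensemble_g2(
    lags_s: np.ndarray,
    g2_pixels: np.ndarray,
    mean_intensity: np.ndarray,
    qmap: QMap,
    q_bins: np.ndarray,
    mask: np.ndarray | None = None,
    sector: tuple[float, float] | None = None,
) -> CorrelationSet:
    """Intensity-weighted ensemble average of per-pixel g2 into q bins.

    ``g2_pixels`` is (n_lags, rows, cols); ``mean_intensity`` the per-pixel
    time-averaged intensity used as averaging weight; ``sector`` an optional
    (center_angle_deg, half_width_deg) azimuthal restriction.  Empty bins
    are omitted; the per-bin standard error is the weighted std across
    pixels over sqrt(n_pix).
    """
    q_bins = np.asarray(q_bins, float)
    keep = np.isfinite(g2_pixels).all(axis=0) & (mean_intensity > 0)
    if mask is not None:
        keep &= ~np.asarray(mask, bool)
    if sector is not None:
        keep &= sector_average(qmap, sector[0], sector[1])

    qs, q_sq, g2s, errs, npixs, meis = [], [], [], [], [], []
    idx = np.digitize(qmap.q, q_bins) - 1
    for b in range(len(q_bins) - 1):
        sel = keep & (idx == b)
        n = int(sel.sum())
        if n == 0:
            continue
        w = mean_intensity[sel]
        wsum = w.sum()
        curves = g2_pixels[:, sel]  # (n_lags, n)
        mean = curves @ w / wsum
        var = ((curves - mean[:, None]) ** 2) @ w / wsum
        qs.append(float(np.average(qmap.q[sel], weights=w)))
        q_sq.append(float(np.average(qmap.q[sel] ** 2, weights=w)))
        g2s.append(mean)
        errs.append(np.sqrt(var / n))
        npixs.append(n)
        meis.append(float(w.mean()))
    if not qs:
        raise UndefinedG2Error("no q bin contains usable pixels")
    return CorrelationSet(
        lags=np.asarray(lags_s, float),
        q=np.array(qs),
        g2=np.stack(g2s, axis=1),
        g2_err=np.stack(errs, axis=1),
        n_pix=np.array(npixs),
        mean_intensity=np.array(meis),
        q_sq=np.array(q_sq),
    )


def estimate_contrast(lags: np.ndarray, g2: np.ndarray) -> float:
    """Speckle contrast beta = g2(t -> 0) - baseline from an exponential fit.

    Fits g2 = 1 + beta exp(-2 Gamma t); raises NoContrastError when the
    curve does not decay.
    """
    import lmfit

    lags = np.asarray(lags, float)
    g2 = np.asarray(g2, float)
    if lags.size < 5:
        raise ValueError("need at least 5 lag points")
    beta0 = g2[0] - 1.0
    if beta0 <= 1e-3 or g2[0] <= np.mean(g2[-max(3, lags.size // 5):]) + 1e-3:
        raise NoContrastError("curve shows no decaying contrast")

    def resid(p):
        return 1.0 + p["beta"] * np.exp(-2.0 * p["gamma"] * lags) - g2

    params = lmfit.Parameters()
    params.add("beta", value=beta0, min=0.0, max=2.0)
    params.add("gamma", value=1.0 / lags[lags.size // 2], min=0.0)
    out = lmfit.minimize(resid, params)
    beta = float(out.params["beta"].value)
    if beta <= 1e-3:
        raise NoContrastError("fitted contrast is zero")
    return beta
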