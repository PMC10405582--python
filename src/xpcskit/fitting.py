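"""Weighted least-squares fitting of the correlation and form-factor models.

g2 fits run in linear space (additive noise); SAXS fits run in
log-intensity space because the profiles span many decades.  Global g2
fits share the physical parameters (contrast, diffusion coefficient,
speeds) across q curves by default while baselines may float per curve;
which parameters are shared is configurable per fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .correlator import CorrelationSet
from .geometry import RadialProfile
from .saxs import (
    SPHERE_FIRST_ZERO,
    SphereModel,
    TubeModel,
    hollow_cylinder_intensity,
    polydisperse_sphere_intensity,
    smeared_model,
)
from .xpcs import ActiveParams, ShearParams, g1_active, g2_shear_flow, g2_siegert

__all__ = ["FitSpec", "FitResult", "fit_g2", "gamma_vs_q2", "fit_saxs"]

_UM2_TO_NM2 = 1.0e6
_UM_TO_NM = 1.0e3

#: physical parameters of each g2 model (baseline handled separately)
_G2_MODEL_PARAMS = {
    "brownian": ("beta", "D0"),
    "active_gaussian": ("beta", "D", "v", "dv"),
    "active_exponential": ("beta", "D", "v", "dv"),
    "shear_flow": ("beta", "D0", "dv"),
    "shear_vertical": ("beta", "D0", "dv"),
}


@dataclass
class FitSpec:
    """Configuration of one fit.

    model: one of the g2 model names above, or 'sphere' / 'tube' for SAXS.
    values/bounds/vary: per-parameter initial values, (lo, hi) bounds and
    vary flags; unspecified parameters get heuristic starts.  share: which
    physical parameters are common to all curves in a global g2 fit.
    q_min/q_max restrict the fitted q window; weighting is '1/sigma2' or
    'unweighted'.  sigma_b (um) feeds the transit term of the active
    models; dq_fwhm (nm^-1) the resolution smearing of the SAXS models;
    float_baseline lets each g2 curve's baseline vary instead of fixing 1.
    """

    model: str
    values: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    vary: dict = field(default_factory=dict)
    share: tuple[str, ...] | None = None
    q_min: float | None = None
    q_max: float | None = None
    weighting: str = "1/sigma2"
    sigma_b: float = 10.62
    dq_fwhm: float = 0.0
    float_baseline: bool = False


@dataclass
class FitResult:
    """Best-fit values with 1-sigma uncertainties and fit diagnostics."""

    params: dict  # name -> (value, stderr or nan)
    redchi: float
    success: bool
    message: str
    residual: np.ndarray

    def value(self, name: str) -> float:
        return self.params[name][0]

    def stderr(self, name: str) -> float:
        return self.params[name][1]


def _result_from_lmfit(out: lmfit.minimizer.MinimizerResult) -> FitResult:
    params = {
        name: (float(p.value), float(p.stderr) if p.stderr is not None else np.nan)
        for name, p in out.params.items()
    }
    return FitResult(
        params=params,
        redchi=float(out.redchi),
        success=bool(out.success),
        message=str(out.message),
        residual=np.asarray(out.residual),
    )


def _half_decay_lag(lags: np.ndarray, curve: np.ndarray) -> float:
    """Lag where the normalized correlation has decayed to half its start."""
    base = np.min(curve)
    top = curve[0]
    if top <= base:
        return lags[lags.size // 2]
    target = base + 0.5 * (top - base)
    below = np.nonzero(curve <= target)[0]
    return lags[below[0]] if below.size else lags[-1]


def _g2_eval(model: str, q: float, t: np.ndarray, p: dict, sigma_b: float) -> np.ndarray:
    bl = p.get("baseline", 1.0)
    if model == "brownian":
        g1 = np.exp(-p["D0"] * _UM2_TO_NM2 * q * q * t)
        return g2_siegert(g1, p["beta"], bl)
    if model in ("active_gaussian", "active_exponential"):
        ap = ActiveParams(
            D=max(p["D"], 1e-12), v=max(p["v"], 0.0), dv=max(p["dv"], 0.0),
            sigma_b=sigma_b,
            advective_form="gaussian" if model.endswith("gaussian") else "exponential",
        )
        return g2_siegert(g1_active(q, t, ap), p["beta"], bl)
    if model in ("shear_flow", "shear_vertical"):
        sp = ShearParams(D0=max(p["D0"], 1e-12), dv=max(p["dv"], 0.0), beta=p["beta"])
        direction = "flow" if model == "shear_flow" else "vertical"
        return g2_shear_flow(q, t, sp, direction=direction, baseline=bl)
    raise ValueError(f"unknown g2 model {model!r}")


def _g2_initial_guesses(
    model: str, curves: CorrelationSet, lags: np.ndarray, g2: np.ndarray
) -> dict:
    beta0 = float(np.clip(np.mean(g2[0, :]) - 1.0, 0.02, 1.0))
    gam, dvs = [], []
    for j, qv in enumerate(curves.q):
        t_half = _half_decay_lag(lags, g2[:, j])
        gam.append(np.log(2.0) / (2.0 * t_half))
        dvs.append(2.0 / (qv * _UM_TO_NM * t_half))
    d0 = float(np.median(np.asarray(gam) / (curves.q**2 * _UM2_TO_NM2)))
    dv0 = float(np.median(dvs))
    guesses = {"beta": beta0, "D0": max(d0, 1e-6), "D": max(d0, 1e-6),
               "v": max(dv0, 1e-3), "dv": max(dv0, 1e-4)}
    return guesses


_DEFAULT_G2_BOUNDS = {
    "beta": (1e-4, 2.0),
    "D0": (0.0, np.inf),
    "D": (0.0, np.inf),
    "v": (0.0, np.inf),
    "dv": (0.0, np.inf),
}


def fit_g2(curves: CorrelationSet, spec: FitSpec) -> FitResult:
    """Global weighted least-squares fit of a g2 model to a CorrelationSet.

    Parameters listed in ``spec.share`` (default: every physical parameter)
    are common to all q curves; the rest get one copy per curve, suffixed
    ``_<index>``.  Baselines are fixed at 1 unless ``spec.float_baseline``.
    Non-convergence is flagged on the result, not raised.
    """
    if spec.model not in _G2_MODEL_PARAMS:
        raise ValueError(f"unknown g2 model {spec.model!r}")
    names = _G2_MODEL_PARAMS[spec.model]
    share = set(spec.share) if spec.share is not None else set(names)

    qsel = np.ones(curves.q.size, bool)
    if spec.q_min is not None:
        qsel &= curves.q >= spec.q_min
    if spec.q_max is not None:
        qsel &= curves.q <= spec.q_max
    qs = curves.q[qsel]
    g2 = curves.g2[:, qsel]
    err = curves.g2_err[:, qsel]
    lags = curves.lags
    if qs.size == 0:
        raise ValueError("q window excludes every curve")
    if lags.size < 5:
        raise ValueError("need at least 5 lag points per curve")

    guess = _g2_initial_guesses(spec.model, CorrelationSet(
        lags=lags, q=qs, g2=g2), lags, g2)
    params = lmfit.Parameters()

    def add_param(pname: str, base: str) -> None:
        v0 = spec.values.get(base, guess.get(base, 0.1))
        lo, hi = spec.bounds.get(base, _DEFAULT_G2_BOUNDS[base])
        params.add(pname, value=v0, min=lo, max=hi,
                   vary=spec.vary.get(base, True))

    per_curve = [n for n in names if n not in share]
    for n in names:
        if n in share:
            add_param(n, n)
    for j in range(qs.size):
        for n in per_curve:
            add_param(f"{n}_{j}", n)
        params.add(f"baseline_{j}", value=1.0, min=0.5, max=1.5,
                   vary=spec.float_baseline)

    use_w = spec.weighting == "1/sigma2" and np.all(err > 0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        res = []
        for j, qv in enumerate(qs):
            pj = {n: p[n].value if n in share else p[f"{n}_{j}"].value
                  for n in names}
            pj["baseline"] = p[f"baseline_{j}"].value
            model = _g2_eval(spec.model, qv, lags, pj, spec.sigma_b)
            r = model - g2[:, j]
            if use_w:
                r = r / err[:, j]
            res.append(r)
        return np.concatenate(res)

    out = lmfit.minimize(residual, params, method="leastsq")
    return _result_from_lmfit(out)


def exponential_decay_rates(
    curves: CorrelationSet,
    float_baseline: bool = True,
    window_factor: float | None = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin relaxation rates from single-exponential fits of g2 curves.

    Fits baseline + beta * exp(-2 Gamma t) to every q bin.  The initial
    Gamma comes from the curve's half-decay lag; when ``window_factor`` is
    set the fit is repeated restricted to t <= window_factor / Gamma, which
    keeps the long-lag region — where the per-pixel symmetric normalization
    of short traces is biased — out of the fit.  A floating baseline
    absorbs the residual baseline suppression of that estimator.
    Returns (gamma, gamma_err) in 1/s.
    """
    gammas = np.empty(curves.q.size)
    errs = np.empty(curves.q.size)
    for j in range(curves.q.size):
        y_all = curves.g2[:, j]
        t_half = _half_decay_lag(curves.lags, y_all)
        gam = np.log(2.0) / (2.0 * t_half)
        beta0 = max(y_all[0] - 1.0, 0.05)
        for _ in range(2 if window_factor else 1):
            sel = (
                curves.lags <= window_factor / gam
                if window_factor
                else np.ones_like(curves.lags, bool)
            )
            if sel.sum() < 5:
                sel = np.zeros_like(sel)
                sel[:5] = True
            t = curves.lags[sel]
            y = y_all[sel]
            params = lmfit.Parameters()
            params.add("beta", value=beta0, min=0.0, max=2.0)
            params.add("gamma", value=gam, min=0.0)
            params.add("bl", value=1.0, min=0.5, max=1.5, vary=float_baseline)

            def resid(p):
                return p["bl"] + p["beta"] * np.exp(-2.0 * p["gamma"] * t) - y

            out = lmfit.minimize(resid, params)
            gam = float(out.params["gamma"].value)
        err = out.params["gamma"].stderr
        gammas[j] = gam
        errs[j] = float(err) if err is not None else np.nan
    return gammas, errs


def gamma_vs_q2(
    q_sq: np.ndarray,
    gamma: np.ndarray,
    gamma_err: np.ndarray | None = None,
) -> tuple[float, float]:
    """Diffusion coefficient from a through-origin regression of Gamma on q^2.

    q_sq in nm^-2, gamma in 1/s; returns (D0, stderr) in um^2/s.  The fit is
    sigma-weighted when uncertainties are supplied, unweighted otherwise.
    """
    q_sq = np.asarray(q_sq, float)
    gamma = np.asarray(gamma, float)
    if q_sq.size < 2:
        raise ValueError("need at least 2 q points (3+ recommended)")
    w = np.ones_like(gamma) if gamma_err is None else 1.0 / np.asarray(gamma_err, float) ** 2
    sxx = np.sum(w * q_sq * q_sq)
    sxy = np.sum(w * q_sq * gamma)
    slope = sxy / sxx  # nm^2/s
    if slope < 0:
        warnings.warn("negative Gamma-vs-q^2 slope: nonphysical fit", stacklevel=2)
    n = q_sq.size
    if n > 2:
        resid = gamma - slope * q_sq
        s2 = np.sum(w * resid**2) / (n - 1)
        stderr = np.sqrt(s2 / sxx)
    else:
        stderr = np.nan
    return slope / _UM2_TO_NM2, stderr / _UM2_TO_NM2


_SPHERE_PARAMS = ("scale", "mean_radius", "radius_std", "background")
_TUBE_PARAMS = (
    "scale", "mean_radius", "wall_thickness",
    "radius_polydispersity", "thickness_polydispersity", "background",
)


def _first_minimum_q(profile: RadialProfile) -> float | None:
    """q position of the first deep form-factor minimum (None if absent).

    Works on -log I with a prominence criterion so percent-level noise does
    not masquerade as a minimum.
    """
    from scipy.signal import find_peaks

    logi = np.log(np.clip(profile.intensity, 1e-300, None))
    idx, _ = find_peaks(-logi, prominence=0.3)
    return float(profile.q[idx[0]]) if idx.size else None


def _saxs_initial_guesses(model: str, profile: RadialProfile) -> dict:
    i_top = float(np.max(profile.intensity))
    q_min1 = _first_minimum_q(profile)
    if model == "sphere":
        r0 = SPHERE_FIRST_ZERO / q_min1 if q_min1 else 2.0 / profile.q[0]
        return {
            "scale": i_top, "mean_radius": r0,
            "radius_std": 0.01 * r0, "background": 0.0,
        }
    # thin-wall tube: A_cs ~ J0(q R_C), first zero at q R = 2.405
    r0 = 2.405 / q_min1 if q_min1 else 2.0 / profile.q[0]
    return {
        "scale": i_top * profile.q[0], "mean_radius": r0,
        "wall_thickness": r0 / 8.0, "radius_polydispersity": 0.1,
        "thickness_polydispersity": 0.5, "background": 0.0,
    }


def fit_saxs(profile: RadialProfile, spec: FitSpec) -> FitResult:
    """Fit the sphere or tube model to a 1D profile in log-intensity space.

    Resolution smearing of FWHM ``spec.dq_fwhm`` is applied inside the model
    at every evaluation.  Residuals are (log I_model - log I_data) weighted
    by I/sigma (the log-space equivalent of 1/sigma weighting); a sphere
    profile that does not reach the second form-factor minimum leaves the
    polydispersity poorly constrained (warning).
    """
    if spec.model not in ("sphere", "tube"):
        raise ValueError(f"unknown SAXS model {spec.model!r}")
    sel = np.ones(profile.q.size, bool)
    if spec.q_min is not None:
        sel &= profile.q >= spec.q_min
    if spec.q_max is not None:
        sel &= profile.q <= spec.q_max
    q = profile.q[sel]
    intensity = profile.intensity[sel]
    error = profile.error[sel]
    if np.any(intensity <= 0):
        raise ValueError("log-space fitting requires positive intensities")

    names = _SPHERE_PARAMS if spec.model == "sphere" else _TUBE_PARAMS
    guess = _saxs_initial_guesses(spec.model, RadialProfile(q=q, intensity=intensity))
    if spec.model == "sphere":
        n_minima = _count_deep_minima(q, intensity)
        if n_minima < 2:
            warnings.warn(
                "profile shows < 2 form-factor minima: polydispersity is "
                "poorly constrained", stacklevel=2,
            )

    params = lmfit.Parameters()
    for n in names:
        v0 = spec.values.get(n, guess[n])
        default_hi = np.inf
        lo, hi = spec.bounds.get(n, (0.0, default_hi))
        params.add(n, value=v0, min=lo, max=hi, vary=spec.vary.get(n, True))

    use_w = spec.weighting == "1/sigma2" and np.all(error > 0)
    log_data = np.log(intensity)
    w = intensity / error if use_w else np.ones_like(intensity)

    def model_intensity(p: lmfit.Parameters) -> np.ndarray:
        if spec.model == "sphere":
            m = SphereModel(
                mean_radius=max(p["mean_radius"].value, 1e-6),
                radius_std=max(p["radius_std"].value, 0.0),
                scale=p["scale"].value,
                background=p["background"].value,
            )
            fn = lambda qq: polydisperse_sphere_intensity(qq, m)  # noqa: E731
        else:
            # keep the geometry valid while the optimizer explores
            rc = max(p["mean_radius"].value, 1e-3)
            tw = float(np.clip(p["wall_thickness"].value, 1e-6, 1.999 * rc))
            m = TubeModel(
                mean_radius=rc,
                wall_thickness=tw,
                radius_polydispersity=max(p["radius_polydispersity"].value, 0.0),
                thickness_polydispersity=max(p["thickness_polydispersity"].value, 0.0),
                scale=p["scale"].value,
                background=p["background"].value,
            )
            fn = lambda qq: hollow_cylinder_intensity(qq, m)  # noqa: E731
        if spec.dq_fwhm > 0:
            return smeared_model(fn, q, spec.dq_fwhm)
        return fn(q)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = model_intensity(p)
        return (np.log(np.clip(model, 1e-300, None)) - log_data) * w

    out = lmfit.minimize(residual, params, method="leastsq")
    return _result_from_lmfit(out)


def _count_deep_minima(q: np.ndarray, intensity: np.ndarray) -> int:
    from scipy.signal import find_peaks

    logi = np.log(np.clip(intensity, 1e-300, None))
    idx, _ = find_peaks(-logi, prominence=0.3)
    return int(idx.size)
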