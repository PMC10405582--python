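"""TOML configuration and file-format plumbing.

Geometry files carry the DetectorGeometry fields under a ``[geometry]``
table; model parameter files use ``[sphere]`` / ``[tube]`` / ``[lattice]``
and ``[brownian]`` / ``[active]`` / ``[shear]`` tables with the field names
of the corresponding dataclasses.  Frame stacks travel as HDF5
(``/frames``, ``/frame_interval_s``, ``/mask``) or multi-page TIFF.
"""

from __future__ import annotations

import tomllib

import numpy as np
import tifffile

from .correlator import FrameStack
from .geometry import DetectorGeometry
from .saxs import LatticeModel, SphereModel, TubeModel
from .xpcs import ActiveParams, BrownianParams, ShearParams

__all__ = [
    "load_config",
    "load_geometry",
    "load_sphere_model",
    "load_tube_model",
    "load_lattice_model",
    "load_dynamics_model",
    "frames_from_tiff",
    "frames_to_tiff",
]

_MODEL_TABLES = {
    "sphere": SphereModel,
    "tube": TubeModel,
    "lattice": LatticeModel,
    "brownian": BrownianParams,
    "active": ActiveParams,
    "shear": ShearParams,
}


def load_config(path) -> dict:
    with open(path, "rb") as f:
        return tomllib.load(f)


def load_geometry(path) -> DetectorGeometry:
    cfg = load_config(path)
    g = cfg.get("geometry", cfg)
    return DetectorGeometry(
        wavelength=g["wavelength"],
        distance=g["distance"],
        pixel_pitch=g["pixel_pitch"],
        beam_center=tuple(g["beam_center"]),
        beam_sigma=g.get("beam_sigma", 10.62),
        q_resolution_fwhm=g.get("q_resolution_fwhm", 2.4e-4),
    )


def _load_table(path, table: str):
    cfg = load_config(path)
    if table not in cfg:
        raise KeyError(f"config has no [{table}] table")
    fields = dict(cfg[table])
    if "amplitudes" in fields:
        fields["amplitudes"] = tuple(fields["amplitudes"])
    return _MODEL_TABLES[table](**fields)


def load_sphere_model(path) -> SphereModel:
    return _load_table(path, "sphere")


def load_tube_model(path) -> TubeModel:
    return _load_table(path, "tube")


def load_lattice_model(path) -> LatticeModel:
    return _load_table(path, "lattice")


def load_dynamics_model(path, kind: str):
    if kind not in ("brownian", "active", "shear"):
        raise ValueError("kind must be brownian, active or shear")
    return _load_table(path, kind)


def frames_to_tiff(stack: FrameStack, path) -> None:
    tifffile.imwrite(path, stack.counts.astype(np.uint32))


def frames_from_tiff(path, frame_interval: float) -> FrameStack:
    counts = tifffile.imread(path)
    return FrameStack(counts=np.asarray(counts), frame_interval=frame_interval)
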