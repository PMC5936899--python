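"""Configuration loading, trajectory serialization and run manifests.

Conventions: flat key-value parameter files (YAML, which includes JSON),
trajectories as CSV with header ``time_yr,T_K,A`` at full double precision
so round-trips are exact, and one JSON manifest per output file recording
the fully resolved parameter set, seeds and code version so any stochastic
output can be regenerated bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .params import PARAM_KEYS, ClimateParams, NoiseConfig
from .trajectory import Trajectory

__all__ = ["load_config", "write_trajectory", "read_trajectory",
           "RunManifest", "write_manifest"]

#: Config keys that override NoiseConfig rather than ClimateParams.
NOISE_KEYS = ("epsilon", "seed", "dt", "t_max")


def load_config(path: str | Path | None) -> tuple[ClimateParams, dict]:
    """Load a flat parameter file; missing keys keep their defaults.

    Returns ``(params, noise_overrides)`` where ``noise_overrides`` holds any
    of ``epsilon``, ``seed``, ``dt``, ``t_max`` found in the file.  Unknown
    keys, non-numeric values, and parameter-invariant violations raise
    ``ValueError`` naming the offender.
    """
    if path is None:
        return ClimateParams(), {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    model_kw: dict = {}
    noise_kw: dict = {}
    for key, value in data.items():
        if key in PARAM_KEYS:
            dest = model_kw
        elif key in NOISE_KEYS:
            dest = noise_kw
        else:
            raise ValueError(
                f"unknown config key {key!r}; expected one of "
                f"{', '.join(PARAM_KEYS + NOISE_KEYS)}")
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValueError(f"config key {key!r} must be numeric, got {value!r}")
        dest[key] = value
    if "seed" in noise_kw:
        noise_kw["seed"] = int(noise_kw["seed"])
    return ClimateParams(**model_kw), noise_kw


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV (``time_yr,T_K,A``), full double precision.

    Metadata (dt, stride, epsilon, seed, ...) is stored in ``#``-prefixed
    comment lines before the header.
    """
    path = Path(path)
    with path.open("w") as fh:
        for key in ("dt", "t_max", "epsilon", "seed", "record_stride", "scheme"):
            if key in traj.meta:
                fh.write(f"# {key} = {traj.meta[key]}\n")
        fh.write("time_yr,T_K,A\n")
        for t, T, A in zip(traj.times, traj.T, traj.A):
            fh.write(f"{float(t)!r},{float(T)!r},{float(A)!r}\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    Validates the header, row shape and the state invariant A in [0, 1]
    (the Trajectory constructor also checks monotone times).
    """
    path = Path(path)
    meta: dict = {}
    times, T, A = [], [], []
    with path.open() as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line.lstrip("# ").partition("=")
                    meta[key.strip()] = _parse_scalar(value.strip())
                continue
            if header is None:
                header = line
                if header != "time_yr,T_K,A":
                    raise ValueError(
                        f"{path}:{lineno}: bad header {header!r}, "
                        "expected 'time_yr,T_K,A'")
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            times.append(float(parts[0]))
            T.append(float(parts[1]))
            A.append(float(parts[2]))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    return Trajectory(np.array(times), np.array(T), np.array(A), meta)


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output file."""

    command: str
    params: dict
    seed: int | None
    outputs: list[str]
    extra: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())


def write_manifest(manifest: RunManifest, out_path: str | Path) -> Path:
    """Write ``<out_path>.manifest.json`` and return its path."""
    mpath = Path(str(out_path) + ".manifest.json")
    mpath.write_text(json.dumps(asdict(manifest), indent=2, default=float) + "\n")
    return mpath
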