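"""Configuration files, result serialization, and run manifests.

Config files are flat YAML documents with four sections (geometry, air,
media, particle, run).  Values are either plain numbers (interpreted as SI)
or strings with an explicit unit suffix ("100 um", "0.3 mm/s", "0.718 mPa.s"),
so the device's customary mixed units can be written verbatim without
transcription slips.  Unspecified keys fall back to the default device
parameter set; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ChannelGeometry
from .properties import (
    ConfigurationError,
    ParticleProperties,
    SimulationConfig,
    air_properties,
    media_properties,
)

__all__ = [
    "parse_quantity", "load_config", "save_config", "resolve_config",
    "RunManifest", "write_results", "write_events",
]

_UNIT_SCALE = {
    # length
    "pm": 1e-12, "nm": 1e-9, "um": 1e-6, "µm": 1e-6, "mm": 1e-3, "cm": 1e-2, "m": 1.0,
    # velocity
    "m/s": 1.0, "mm/s": 1e-3, "um/s": 1e-6, "µm/s": 1e-6,
    # viscosity
    "pa.s": 1.0, "pa*s": 1.0, "mpa.s": 1e-3, "mpa*s": 1e-3,
    # density
    "kg/m3": 1.0, "kg/m^3": 1.0, "g/cm3": 1e3, "g/cm^3": 1e3,
    # time
    "s": 1.0, "ms": 1e-3, "min": 60.0,
    # acceleration
    "m/s2": 1.0, "m/s^2": 1.0,
    # temperature and gas constant handled specially / dimensionless
    "k": 1.0, "j/(kg.k)": 1.0, "j/(kg*k)": 1.0, "j/kg/k": 1.0,
}


def parse_quantity(value):
    """Convert ``3.0``, ``"3 um"``, ``"0.3 mm/s"`` ... to an SI float.

    Bare numbers pass through as SI.  ``"37 degC"`` converts to kelvin.
    """
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise ConfigurationError(f"cannot parse quantity {value!r}")
    parts = value.strip().split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) != 2:
        raise ConfigurationError(f"cannot parse quantity {value!r}")
    num = float(parts[0])
    unit = parts[1].strip()
    if unit.lower() in ("degc", "celsius", "c"):
        return num + 273.15
    scale = _UNIT_SCALE.get(unit) or _UNIT_SCALE.get(unit.lower())
    if scale is None:
        raise ConfigurationError(f"unknown unit {unit!r} in {value!r}")
    return num * scale


_GEOM_KEYS = {"h_air", "h_media", "l", "b", "d", "p2p", "porous_x0", "porous_x1", "depth"}
_FLUID_KEYS = {"rho", "mu", "T", "R", "sigma"}
_PARTICLE_KEYS = {"dp", "rho_p"}
_RUN_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_STR_KEYS = {"integrator_mode", "inlet_profile", "initial_velocity", "membrane_flow"}


def _section(doc: dict, name: str, allowed: set) -> dict:
    sec = doc.get(name) or {}
    if not isinstance(sec, dict):
        raise ConfigurationError(f"config section {name!r} must be a mapping")
    unknown = set(sec) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {name!r}: {sorted(unknown)}")
    out = {}
    for k, v in sec.items():
        if v is None or k in _STR_KEYS or isinstance(v, bool):
            out[k] = v
        else:
            out[k] = parse_quantity(v)
    return out


def resolve_config(doc: dict):
    """Resolve a parsed YAML mapping into the four typed parameter objects.

    Returns ``(geometry, air, media, particle, run_config)``; missing keys
    take the default device values.
    """
    unknown = set(doc) - {"geometry", "air", "media", "particle", "run"}
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    geom = ChannelGeometry(**_section(doc, "geometry", _GEOM_KEYS))
    air = dataclasses.replace(air_properties(), **_section(doc, "air", _FLUID_KEYS))
    media = dataclasses.replace(media_properties(), **_section(doc, "media", _FLUID_KEYS))
    pdoc = {"dp": 100e-9, "rho_p": 1180.0, **_section(doc, "particle", _PARTICLE_KEYS)}
    particle = ParticleProperties(**pdoc)
    run_doc = _section(doc, "run", _RUN_KEYS)
    if "n_particles" in run_doc:
        run_doc["n_particles"] = int(run_doc["n_particles"])
    if "seed" in run_doc:
        run_doc["seed"] = int(run_doc["seed"])
    run = SimulationConfig(**run_doc)
    return geom, air, media, particle, run


def load_config(path):
    """Read, validate and resolve a YAML config file (SI output)."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config root must be a mapping")
    return resolve_config(doc)


def _as_doc(geom, air, media, particle, run) -> dict:
    def clean(obj, drop_none=True):
        d = dataclasses.asdict(obj)
        return {k: v for k, v in d.items() if not (drop_none and v is None)}

    return {
        "geometry": clean(geom),
        "air": clean(air),
        "media": clean(media),
        "particle": clean(particle),
        "run": clean(run),
    }


def save_config(path, geom, air, media, particle, run) -> None:
    """Write the fully-resolved configuration (SI numbers) back to YAML."""
    Path(path).write_text(yaml.safe_dump(_as_doc(geom, air, media, particle, run),
                                         sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record written next to every output set.

    Holds the fully-resolved config snapshot, the software version, the master
    seed and a digest of the inputs; rerunning from a manifest reproduces the
    outputs bit-exactly.
    """

    config: dict
    seed: int
    version: str
    digest: str = ""
    started: str = ""
    finished: str = ""

    @classmethod
    def create(cls, geom, air, media, particle, run) -> "RunManifest":
        from . import __version__

        doc = _as_doc(geom, air, media, particle, run)
        digest = hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()
        return cls(config=doc, seed=run.seed, version=__version__, digest=digest,
                   started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def close(self) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def resolve(self):
        return resolve_config(self.config)


def write_results(summaries, out_dir, manifest: RunManifest | None = None) -> Path:
    """Write case summaries as a CSV (stable column order, full precision).

    Accepts one or a list of :class:`~lungchip.experiments.CaseSummary`.
    Appends to an existing summary.csv, writing the header only once.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(summaries, (list, tuple)):
        summaries = [summaries]
    df = pd.DataFrame([s.to_row() for s in summaries])
    csv_path = out_dir / "summary.csv"
    header = not csv_path.exists()
    df.to_csv(csv_path, mode="a", header=header, index=False,
              float_format="%.17g")
    if manifest is not None:
        manifest.close()
        manifest.write(out_dir / "manifest.json")
    return csv_path


def write_events(result, out_path) -> Path:
    """Dump one JSON-lines record per particle fate event.

    Events: deposit (with position), transfer (with time), media exit (with
    time and height).  Aggregate counts go in a trailing summary record.
    """
    out_path = Path(out_path)
    with out_path.open("w") as fh:
        for x in np.asarray(result.deposits):
            fh.write(json.dumps({"event": "deposit", "x_m": float(x)}) + "\n")
        for t in np.asarray(result.transfers):
            fh.write(json.dumps({"event": "transfer", "t_s": float(t)}) + "\n")
        for t, y in zip(result.media_exit_times, result.media_exit_ys):
            fh.write(json.dumps({"event": "media_exit", "t_s": float(t),
                                 "y_m": float(y)}) + "\n")
        fh.write(json.dumps({"event": "summary", **result.counts()}) + "\n")
    return out_path
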