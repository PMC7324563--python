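"""Configuration loading, table/image IO and run manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .oxygen import (
    CultureConfiguration,
    GridResolution,
    KineticsSpec,
    TransportPhase,
    default_phases,
)

__all__ = [
    "load_yaml_or_json",
    "load_oxygen_config",
    "load_channel_map",
    "write_table",
    "write_manifest",
    "write_field_tiff",
]

#: channel roles longitudinal_report understands
KNOWN_CHANNEL_ROLES = {
    "brightfield",
    "red",
    "green",
    "dapi",
    "live",
    "dead",
    "marker",
}


def load_yaml_or_json(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def load_oxygen_config(
    path: str | Path,
) -> tuple[CultureConfiguration, KineticsSpec, dict[str, TransportPhase], GridResolution, float]:
    """Parse a simulation config document.

    Sections (all optional except ``culture``): ``culture``, ``kinetics``,
    ``phases`` (mapping name -> {solubility_alpha, permeability_K}),
    ``resolution`` and ``dt_s``.
    """
    doc = load_yaml_or_json(path)
    if "culture" not in doc:
        raise ValueError("config must contain a 'culture' section")
    config = CultureConfiguration(**doc["culture"])
    kinetics = KineticsSpec(**doc.get("kinetics", {}))
    phases = default_phases()
    for name, spec in doc.get("phases", {}).items():
        phases[name] = TransportPhase(name=name, **spec)
    resolution = GridResolution(**doc.get("resolution", {}))
    dt_s = float(doc.get("dt_s", 30.0))
    return config, kinetics, phases, resolution, dt_s


def load_channel_map(path: str | Path) -> dict[str, str]:
    """Channel-role map: role -> filename suffix; roles are never inferred."""
    doc = load_yaml_or_json(path)
    for key in doc:
        if key not in KNOWN_CHANNEL_ROLES:
            raise ValueError(f"unknown channel role in channel map: {key!r}")
        if not isinstance(doc[key], str):
            raise ValueError(f"channel map entry {key!r} must be a string suffix")
    return {k: str(v) for k, v in doc.items()}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def write_manifest(outdir: str | Path, command: str, params: Mapping[str, Any], seed: int | None = None) -> Path:
    """Record what produced the outputs of a run (config + version + seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "slicequant",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    return v


def write_field_tiff(po2: np.ndarray, path: str | Path) -> None:
    """Dump one pO2 snapshot as a single-channel 32-bit TIFF grid."""
    tifffile.imwrite(str(path), np.asarray(po2, dtype=np.float32))
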