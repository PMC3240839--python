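"""Configuration handling and deterministic CSV/JSON/manifest writers."""

from __future__ import annotations

import json
from dataclasses import asdict, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .feedback_steady_state import Environment
from .kinetic_core import RateParameters

__all__ = [
    "load_config",
    "default_config_path",
    "write_csv",
    "write_json",
    "write_manifest",
]

_PARAM_FIELDS = {f.name for f in dc_fields(RateParameters)}
_ENV_FIELDS = {f.name for f in dc_fields(Environment)}


def default_config_path() -> Path:
    """Path of the packaged default parameter file (normalized units)."""
    return Path(resources.files("ppdkrp") / "data" / "default.yaml")


def load_config(path: Optional[str] = None) -> Tuple[RateParameters, Environment]:
    """Read a flat key-value YAML config into (RateParameters, Environment).

    Keys are exactly the dataclass field names; unknown keys raise
    :class:`ConfigError`.  Missing keys fall back to the package defaults.
    """
    p = Path(path) if path else default_config_path()
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {p}: {exc}")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {p} must be a flat mapping")
    par_kw, env_kw = {}, {}
    for k, v in raw.items():
        if k in _PARAM_FIELDS:
            par_kw[k] = v
        elif k in _ENV_FIELDS:
            env_kw[k] = v
        else:
            raise ConfigError(f"unknown config key {k!r} in {p}")
    try:
        return RateParameters(**par_kw), Environment(**env_kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value in {p}: {exc}")


def _fmt(x) -> object:
    if isinstance(x, float):
        return float(f"{x:.12g}")
    return x


def write_csv(df: pd.DataFrame, path) -> None:
    """CSV with header row, UTF-8, 12 significant digits (determinism audit)."""
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def write_json(obj, path) -> None:
    def convert(o):
        if isinstance(o, dict):
            return {k: convert(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [convert(v) for v in o]
        if hasattr(o, "item"):  # numpy scalar
            o = o.item()
        return _fmt(o)

    Path(path).write_text(json.dumps(convert(obj), indent=2) + "\n")


def write_manifest(
    out_dir,
    subcommand: str,
    params: Optional[RateParameters] = None,
    env: Optional[Environment] = None,
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> None:
    """Echo everything needed to reproduce a run next to its outputs."""
    manifest = {
        "package": "ppdkrp",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "parameters": asdict(params) if params else None,
        "environment": asdict(env) if env else None,
    }
    if extra:
        manifest.update(extra)
    write_json(manifest, Path(out_dir) / "manifest.json")
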