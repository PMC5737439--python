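"""Configuration loading, unit normalization, and named presets.

Configs are YAML or JSON mappings of :class:`~pelotons.model.ModelParams`
fields plus run controls.  All rates are stored internally in 1/s; rate
fields accept plain numbers (interpreted as 1/s) or strings with an
explicit ``/s`` or ``/min`` suffix, because initiation rates are usually
quoted per minute while hopping rates are per second and silent unit
mix-ups are the classic mistake with these parameter tables.

The ``table1`` preset carries the physiological transcription parameters:
RNAP footprint 35 bp, nucleosome + linker footprint 167 bp, elongation
10 bp/s on bare DNA and 3 bp/s through a nucleosome, nucleosome binding
attempts at 0.02/s, dyad-triggered eviction on an open 3000 bp gene, and
``tau = 0`` for the analytic layer (histone rebinding is fast compared to
clearing the footprint, so the shadow is dominated by the footprint).
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .model import ModelParams

__all__ = ["Config", "load_config", "save_config", "get_preset", "PRESETS",
           "parse_rate"]

_RATE_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*/\s*(s|sec|min)\s*$")

_RATE_FIELDS = {"k_ip", "k_tp", "k_in", "k_b"}
_PARAM_FIELDS = {f.name for f in fields(ModelParams)}


def parse_rate(value) -> float:
    """Normalize a rate to 1/s; accepts numbers or ``"<x>/s"``/``"<x>/min"``."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _RATE_RE.match(str(value))
    if not m:
        raise ValueError(
            f"cannot parse rate {value!r}; use a number (1/s) or 'x/s', 'x/min'")
    x = float(m.group(1))
    return x / 60.0 if m.group(2) == "min" else x


@dataclass(frozen=True)
class Config:
    """Model parameters plus run controls, all in seconds and sites."""

    params: ModelParams
    t_max: float = 9000.0
    dt_sample: float = 1.0
    burn_in: float | None = None     # None -> simulator default 5 L / k_tp
    seed: int = 0
    outdir: str = "pelotons_out"

    @property
    def burn_in_eff(self) -> float:
        if self.burn_in is not None:
            return self.burn_in
        if self.params.boundary == "open":
            return min(5.0 * self.params.L / self.params.k_tp,
                       0.5 * self.t_max)
        return 0.1 * self.t_max

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d


PRESETS: dict[str, dict] = {
    # Physiological transcription scenario: RNAP through nucleosomes on a
    # highly induced 3 kb gene.
    "table1": dict(
        L=3000, delta_m=35, delta_rb=167,
        k_ip=10.0, k_tp=3.0, k_in="0.6/min", k_b=0.02, tau=0.0,
        boundary="open", interaction="dyad",
    ),
    # Bus-Route Model at the intermediate roadblock density where the
    # double-geometric gap distribution appears (k_ip * tau = 10).
    "brm": dict(
        L=1000, delta_m=1, delta_rb=1,
        k_ip=1.0, k_tp=0.3, k_in=0.0, k_b=0.1,
        boundary="periodic", interaction="uniform", n_motors=100,
    ),
}

_RUN_FIELDS = {"t_max", "dt_sample", "burn_in", "seed", "outdir"}


def _build(raw: dict, source: str) -> Config:
    raw = dict(raw)
    pkw: dict = {}
    rkw: dict = {}
    for key, val in raw.items():
        if key in _RATE_FIELDS:
            pkw[key] = parse_rate(val)
        elif key in _RUN_FIELDS:
            # "seed" is routed to the run controls, not ModelParams
            rkw[key] = val
        elif key in _PARAM_FIELDS:
            pkw[key] = val
        else:
            raise ValueError(f"unknown config key {key!r} in {source}")
    try:
        params = ModelParams(**pkw)
    except TypeError as exc:
        raise ValueError(f"incomplete model parameters in {source}: {exc}")
    return Config(params=params, **rkw)


def get_preset(name: str, **overrides) -> Config:
    """Named preset as a validated :class:`Config`; keyword overrides are
    applied before validation (rates may use ``/min`` strings)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    raw = dict(PRESETS[name])
    raw.update(overrides)
    return _build(raw, source=f"preset {name!r}")


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML/JSON config file.

    A top-level ``preset`` key pulls in a named preset with the remaining
    keys as overrides.  Unknown keys are rejected with the field name.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"config file {path} is empty or not a mapping")
    preset = raw.pop("preset", None)
    if preset is not None:
        base = dict(PRESETS.get(preset) or {})
        if not base:
            raise ValueError(f"unknown preset {preset!r} in {path}")
        base.update(raw)
        raw = base
    return _build(raw, source=str(path))


def save_config(config: Config, path: str | Path) -> None:
    """Write a config (JSON-compatible YAML) that round-trips through
    :func:`load_config`."""
    d = dict(config.to_dict()["params"])
    d = {k: v for k, v in d.items() if v is not None}
    d.update({k: getattr(config, k) for k in _RUN_FIELDS
              if getattr(config, k) is not None})
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
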