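"""Configuration files with explicit units, validated into SI objects.

Every dimensional quantity in a config file is written as a string
``"<number> <unit>"`` (``"5 zJ"``, ``"0.159 nm^-1"``, ``"1 ul/min"``);
dimensionless entries are plain numbers.  Loading converts everything to
SI, fills defaults for missing keys, rejects unknown keys and unknown
units, and reports *all* failures at once.  ``dump_config`` writes the
canonical representation back out; a load -> dump -> load round trip
preserves every value to relative 1e-12.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import yaml

from .dielectric import DielectricMaterial
from .errors import ConfigError
from .forces import AdhesionParams, FieldModel
from .transport import ChannelNetwork, SimulationParams

__all__ = ["RunConfig", "load_config", "dump_config", "parse_quantity", "config_hash"]


# unit -> (dimension, factor to SI)
_UNITS: Dict[str, Tuple[str, float]] = {
    "m": ("length", 1.0), "mm": ("length", 1e-3), "um": ("length", 1e-6),
    "µm": ("length", 1e-6), "nm": ("length", 1e-9), "pm": ("length", 1e-12),
    "m^-1": ("inv_length", 1.0), "1/m": ("inv_length", 1.0),
    "nm^-1": ("inv_length", 1e9), "1/nm": ("inv_length", 1e9),
    "um^-1": ("inv_length", 1e6), "1/um": ("inv_length", 1e6),
    "J": ("energy", 1.0), "aJ": ("energy", 1e-18), "zJ": ("energy", 1e-21),
    "V": ("voltage", 1.0), "mV": ("voltage", 1e-3), "kV": ("voltage", 1e3),
    "S/m": ("conductivity", 1.0), "mS/m": ("conductivity", 1e-3),
    "uS/m": ("conductivity", 1e-6), "µS/m": ("conductivity", 1e-6),
    "Hz": ("frequency", 1.0), "kHz": ("frequency", 1e3),
    "MHz": ("frequency", 1e6), "GHz": ("frequency", 1e9),
    "K": ("temperature", 1.0),
    "Pa.s": ("viscosity", 1.0), "Pa*s": ("viscosity", 1.0),
    "mPa.s": ("viscosity", 1e-3), "mPa*s": ("viscosity", 1e-3), "cP": ("viscosity", 1e-3),
    "m^3/s": ("flow", 1.0), "ul/min": ("flow", 1e-9 / 60.0), "µl/min": ("flow", 1e-9 / 60.0),
    "ul/s": ("flow", 1e-9), "ml/min": ("flow", 1e-6 / 60.0),
    "s": ("time", 1.0), "ms": ("time", 1e-3), "min": ("time", 60.0), "h": ("time", 3600.0),
    "%": ("percent", 1.0),
}


def parse_quantity(raw: Union[str, int, float], dimension: str) -> float:
    """Parse ``"<number> <unit>"`` into an SI float of the given dimension.

    Raises ``ValueError`` with a message naming the problem (bad number,
    unknown unit, wrong dimension, missing unit on a dimensional value).
    """
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        raise ValueError(
            f"dimensional value {raw!r} must carry an explicit unit "
            f"(e.g. '{raw} <{dimension} unit>')"
        )
    if not isinstance(raw, str):
        raise ValueError(f"cannot parse quantity from {raw!r}")
    parts = raw.split()
    if len(parts) != 2:
        raise ValueError(f"expected '<number> <unit>', got {raw!r}")
    num_s, unit = parts
    try:
        value = float(num_s)
    except ValueError:
        raise ValueError(f"bad number in quantity {raw!r}") from None
    if unit not in _UNITS:
        raise ValueError(f"unknown unit {unit!r} in {raw!r}")
    dim, factor = _UNITS[unit]
    if dim != dimension:
        raise ValueError(f"unit {unit!r} has dimension {dim!r}, expected {dimension!r}")
    return value * factor


def _fmt(value_si: float, canonical_unit: str) -> str:
    factor = _UNITS[canonical_unit][1]
    return f"{value_si / factor!r} {canonical_unit}"


# schema: section -> key -> (kind, default)
#   kind is a dimension name for unit-bearing quantities, or one of
#   "number", "int", "str" for plain entries.
_SCHEMA: Dict[str, Dict[str, Tuple[str, Any]]] = {
    "materials": {
        "plasma_epsilon_r": ("number", 78.0),
        "plasma_sigma": ("conductivity", "60.0 mS/m"),
        "cell_epsilon_r": ("number", 63.0),
        "cell_sigma": ("conductivity", "1.0 uS/m"),
    },
    "adhesion": {
        "hamaker": ("energy", "5.0 zJ"),
        "debye_kappa": ("inv_length", "0.159 nm^-1"),
        "temperature": ("temperature", "296.15 K"),
        "valency": ("int", 1),
        "zeta_cell": ("voltage", "-10.8 mV"),
        "zeta_wall": ("voltage", "-13.825 mV"),
    },
    "field": {
        "electrode_gap": ("length", "4.0 um"),
        "electrode_pitch": ("length", "30.0 um"),
        "gradient_model": ("str", "coplanar_idt"),
    },
    "operating": {
        "voltage": ("voltage", "20.0 V"),
        "frequency": ("frequency", "1.0 kHz"),
        "flow_rate": ("flow", "1.0 ul/min"),
    },
    "network": {
        "main_width": ("length", "100.0 um"),
        "depth": ("length", "80.0 um"),
        "branch_width": ("length", "15.0 um"),
        "n_branches": ("int", 50),
        "branch_length": ("length", "4.0 mm"),
        "station_spacing": ("length", "200.0 um"),
        "outlet_length": ("length", "1.0 mm"),
        "viscosity": ("viscosity", "1.2 mPa.s"),
    },
    "blood": {
        "haematocrit": ("percent", "25.0 %"),
        "max_cells": ("int", 10_000),
        "near_wall_occupancy": ("number", 0.35),
    },
    "simulation": {
        "duration": ("time", "60.0 s"),
        "dt": ("time", "1.0 s"),
    },
    "transport": {
        "h_capture": ("length", "10.0 nm"),
        "clog_fraction": ("number", 0.8),
        "aggregation_factor": ("number", 3.0),
        "core_entry_factor": ("number", 0.5),
        "barrier_scale": ("number", 1000.0),
        "debris_diameter": ("length", "0.5 um"),
        "lysis_threshold": ("voltage", "20.0 V"),
        "lysis_hazard_per_volt_s": ("number", 0.002),
    },
    "noise": {
        "cv": ("number", 0.10),
        "replicates": ("int", 3),
    },
}

_CANONICAL_UNIT: Dict[str, str] = {
    "length": "um", "inv_length": "nm^-1", "energy": "zJ", "voltage": "V",
    "conductivity": "S/m", "frequency": "Hz", "temperature": "K",
    "viscosity": "Pa.s", "flow": "ul/min", "time": "s", "percent": "%",
}


@dataclass
class RunConfig:
    """Fully validated, SI-converted run configuration."""

    seed: int
    plasma: DielectricMaterial
    cell: DielectricMaterial
    adhesion: AdhesionParams
    field: FieldModel
    network: ChannelNetwork
    sim_params: SimulationParams
    haematocrit_pct: float
    max_cells: int
    near_wall_occupancy: float
    voltage: float
    frequency: float
    duration: float
    dt: float
    noise_cv: float
    noise_replicates: int
    raw: Dict[str, Any]

    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(raw: Dict[str, Any]) -> str:
    """SHA-256 of the canonical YAML form of a config dict."""
    canon = yaml.safe_dump(raw, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _validate(data: Dict[str, Any]) -> Tuple[Dict[str, Dict[str, Any]], List[str]]:
    errors: List[str] = []
    out: Dict[str, Dict[str, Any]] = {}
    if not isinstance(data, dict):
        return {}, ["top level of the config must be a mapping"]
    extra_top = set(data) - set(_SCHEMA) - {"seed"}
    for k in sorted(extra_top):
        errors.append(f"unknown section {k!r}")
    if "seed" not in data:
        errors.append("missing required key 'seed'")
    elif not isinstance(data["seed"], int) or isinstance(data["seed"], bool):
        errors.append(f"'seed' must be an integer, got {data['seed']!r}")

    for section, keys in _SCHEMA.items():
        given = data.get(section, {})
        if given is None:
            given = {}
        if not isinstance(given, dict):
            errors.append(f"section {section!r} must be a mapping")
            given = {}
        for k in sorted(set(given) - set(keys)):
            errors.append(f"unknown key {section}.{k}")
        sec_out: Dict[str, Any] = {}
        for key, (kind, default) in keys.items():
            raw = given.get(key, default)
            try:
                if kind == "number":
                    if isinstance(raw, bool) or not isinstance(raw, (int, float)):
                        raise ValueError(f"must be a number, got {raw!r}")
                    sec_out[key] = float(raw)
                elif kind == "int":
                    if isinstance(raw, bool) or not isinstance(raw, int):
                        raise ValueError(f"must be an integer, got {raw!r}")
                    sec_out[key] = int(raw)
                elif kind == "str":
                    if not isinstance(raw, str):
                        raise ValueError(f"must be a string, got {raw!r}")
                    sec_out[key] = raw
                else:
                    sec_out[key] = parse_quantity(raw, kind)
            except ValueError as e:
                errors.append(f"{section}.{key}: {e}")
        out[section] = sec_out
    return out, errors


def load_config(source: Union[str, Path, Dict[str, Any], None] = None) -> RunConfig:
    """Load and validate a config from a YAML path, a dict, or ``None``.

    ``None`` is rejected (a seed is always required); the minimal valid
    config is ``{"seed": <int>}``, which applies every default.

    Raises
    ------
    ConfigError
        Listing every validation failure.
    """
    if source is None:
        data: Dict[str, Any] = {}
    elif isinstance(source, dict):
        data = copy.deepcopy(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    si, errors = _validate(data)
    if errors:
        raise ConfigError(errors)

    m, a, f, o, nw, bl, sm, tr, nz = (
        si["materials"], si["adhesion"], si["field"], si["operating"],
        si["network"], si["blood"], si["simulation"], si["transport"], si["noise"],
    )
    try:
        cfg = RunConfig(
            seed=int(data["seed"]),
            plasma=DielectricMaterial(m["plasma_epsilon_r"], m["plasma_sigma"]),
            cell=DielectricMaterial(m["cell_epsilon_r"], m["cell_sigma"]),
            adhesion=AdhesionParams(
                hamaker_A=a["hamaker"],
                debye_kappa=a["debye_kappa"],
                temperature_T=a["temperature"],
                valency_z=a["valency"],
                zeta_particle=a["zeta_cell"],
                zeta_wall=a["zeta_wall"],
                eps_medium=m["plasma_epsilon_r"],
            ),
            field=FieldModel(
                voltage_amplitude=o["voltage"],
                frequency=o["frequency"],
                electrode_gap_g=f["electrode_gap"],
                electrode_pitch_p=f["electrode_pitch"],
                gradient_scale_model=f["gradient_model"],
            ),
            network=ChannelNetwork(
                main_width=nw["main_width"],
                depth=nw["depth"],
                branch_width=nw["branch_width"],
                n_branches=nw["n_branches"],
                branch_length=nw["branch_length"],
                inlet_flow=o["flow_rate"],
                fluid_viscosity=nw["viscosity"],
                station_spacing=nw["station_spacing"],
                outlet_length=nw["outlet_length"],
            ),
            sim_params=SimulationParams(
                h_capture=tr["h_capture"],
                clog_fraction=tr["clog_fraction"],
                aggregation_factor=tr["aggregation_factor"],
                core_entry_factor=tr["core_entry_factor"],
                barrier_scale=tr["barrier_scale"],
                debris_diameter=tr["debris_diameter"],
                lysis_threshold_v=tr["lysis_threshold"],
                lysis_hazard_per_volt_s=tr["lysis_hazard_per_volt_s"],
            ),
            haematocrit_pct=bl["haematocrit"],
            max_cells=bl["max_cells"],
            near_wall_occupancy=bl["near_wall_occupancy"],
            voltage=o["voltage"],
            frequency=o["frequency"],
            duration=sm["duration"],
            dt=sm["dt"],
            noise_cv=nz["cv"],
            noise_replicates=nz["replicates"],
            raw=_canonical_raw(int(data["seed"]), si),
        )
    except ConfigError:
        raise
    except Exception as e:  # dataclass invariant violations
        raise ConfigError([str(e)]) from e
    return cfg


def _canonical_raw(seed: int, si: Dict[str, Dict[str, Any]]) -> Dict[str, Any]:
    raw: Dict[str, Any] = {"seed": seed}
    for section, keys in _SCHEMA.items():
        sec: Dict[str, Any] = {}
        for key, (kind, _default) in keys.items():
            v = si[section][key]
            if kind in ("number", "int", "str"):
                sec[key] = v
            else:
                sec[key] = _fmt(v, _CANONICAL_UNIT[kind])
        raw[section] = sec
    return raw


def dump_config(cfg: RunConfig, path: Union[str, Path, None] = None) -> str:
    """Serialise a :class:`RunConfig` back to canonical YAML text."""
    text = yaml.safe_dump(cfg.raw, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
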