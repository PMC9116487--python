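"""Config files, trajectory tables, and reproducibility manifests.

Model configs are YAML with sections ``variables``, ``equations``, ``events``,
``noise``, ``theta`` (see :func:`spec_to_dict` for the full schema).
Trajectories are delimited text (TSV by default) with a ``time`` column plus
one column per variable, full float precision, and a JSON sidecar manifest
carrying everything needed to reproduce the run bit-exactly: seed, step
size, config hash, and the complete event and noise logs.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .estimation import ObservedSeries
from .model import (ModelSpec, PowerLawTerm, Regime, RegimeSet, VariableSpec,
                    validate_model)
from .solver import Trajectory
from .stochastic import EventProcess, StochasticModifier

__all__ = [
    "ConfigError",
    "spec_to_dict",
    "spec_from_dict",
    "read_model_config",
    "write_model_config",
    "config_hash",
    "RunManifest",
    "write_trajectory",
    "read_trajectory",
    "read_series",
    "write_series",
]

PathLike = Union[str, Path]


class ConfigError(ValueError):
    """Schema violation in a model config; the message names the bad key."""


def _term_to_dict(t: PowerLawTerm) -> dict:
    d: dict = {"sign": int(t.sign), "rate": float(t.rate_constant),
               "exponents": {k: float(v) for k, v in t.exponents.items()}}
    if t.delay:
        d["delay"] = {k: float(v) for k, v in t.delay.items()}
    if t.offset:
        d["offset"] = {k: float(v) for k, v in t.offset.items()}
    if t.noise_id:
        d["noise"] = t.noise_id
    return d


def _term_from_dict(d: dict, where: str) -> PowerLawTerm:
    if not isinstance(d, dict):
        raise ConfigError(f"{where}: term must be a mapping, got {type(d).__name__}")
    unknown = set(d) - {"sign", "rate", "exponents", "delay", "offset", "noise"}
    if unknown:
        raise ConfigError(f"{where}: unknown term keys {sorted(unknown)}")
    if "rate" not in d:
        raise ConfigError(f"{where}: term is missing 'rate'")
    for key in ("exponents", "delay", "offset"):
        val = d.get(key, {})
        if not isinstance(val, dict):
            raise ConfigError(f"{where}: {key!r} must map variable names to numbers")
        for k, v in val.items():
            if not isinstance(v, (int, float)):
                raise ConfigError(f"{where}: {key}[{k!r}] is not a number")
    return PowerLawTerm(rate_constant=float(d["rate"]),
                        exponents={k: float(v) for k, v in d.get("exponents", {}).items()},
                        sign=int(d.get("sign", 1)),
                        delay={k: float(v) for k, v in d.get("delay", {}).items()},
                        noise_id=d.get("noise"),
                        offset={k: float(v) for k, v in d.get("offset", {}).items()})


def spec_to_dict(spec: ModelSpec) -> dict:
    """Plain-data (YAML-serializable) form of a model spec."""
    equations = {}
    for var, eq in spec.equations.items():
        if isinstance(eq, RegimeSet):
            block: dict = {"switch": eq.switch_variable, "low": eq.low, "high": eq.high}
            for part in ("below", "middle", "above"):
                reg: Regime = getattr(eq, part)
                block[part] = [_term_to_dict(t) for t in reg.terms]
                if reg.label:
                    block[f"{part}_label"] = reg.label
            equations[var] = {"regimes": block}
        else:
            equations[var] = {"terms": [_term_to_dict(t) for t in eq]}
    events = []
    for p in spec.event_processes:
        e: dict = {"target": p.target, "mode": p.mode}
        if p.mode == "table":
            e["table"] = [[float(t), float(v)] for t, v in p.table]
        elif p.mode == "renewal":
            e.update(rate=p.rate, magnitude={"mu": p.magnitude_mu,
                                             "sigma": p.magnitude_sigma,
                                             "lower": p.magnitude_lower})
        else:
            e.update(probability_variable=p.probability_variable,
                     magnitude={"mu": p.magnitude_mu,
                                "sd_variable": p.sd_variable,
                                "lower": p.magnitude_lower})
        events.append(e)
    noise = []
    for m in spec.noise_modifiers:
        n: dict = {"id": m.id, "distribution": m.distribution, "refresh": m.refresh,
                   "target": m.target}
        if m.distribution == "uniform_pm":
            n["fraction"] = m.fraction
        else:
            n.update(mu=m.mu, sigma=m.sigma)
            if m.lower is not None:
                n["lower"] = m.lower
        if m.variable:
            n["variable"] = m.variable
        noise.append(n)
    out = {
        "name": spec.name,
        "theta": float(spec.step_size),
        "time_unit": spec.time_unit,
        "variables": [{k: val for k, val in asdict(v_).items() if val != ""}
                      for v_ in spec.variables],
        "equations": equations,
    }
    if events:
        out["events"] = events
    if noise:
        out["noise"] = noise
    if spec.max_delay:
        out["max_delay"] = float(spec.max_delay)
    if spec.clamp_nonpositive_bases:
        out["clamp_nonpositive_bases"] = True
    if spec.metadata:
        out["metadata"] = spec.metadata
    return out


def spec_from_dict(d: dict, validate: bool = True) -> ModelSpec:
    if not isinstance(d, dict):
        raise ConfigError("config root must be a mapping")
    for req in ("variables", "equations", "theta"):
        if req not in d:
            raise ConfigError(f"config is missing required section {req!r}")
    variables = []
    for i, v in enumerate(d["variables"]):
        try:
            variables.append(VariableSpec(name=v["name"], role=v.get("role", "dependent"),
                                          initial_value=float(v.get("initial_value", 0.0)),
                                          description=v.get("description", "")))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"variables[{i}]: {exc}") from exc

    equations: dict = {}
    for var, eq in d["equations"].items():
        where = f"equations[{var!r}]"
        if not isinstance(eq, dict) or not ({"terms", "regimes"} & set(eq)):
            raise ConfigError(f"{where}: expected a 'terms' list or a 'regimes' block")
        if "regimes" in eq:
            r = eq["regimes"]
            for req in ("switch", "low", "high", "below", "middle", "above"):
                if req not in r:
                    raise ConfigError(f"{where}.regimes: missing {req!r}")
            def _regime(part: str) -> Regime:
                return Regime([_term_from_dict(t, f"{where}.{part}[{i}]")
                               for i, t in enumerate(r[part])],
                              label=r.get(f"{part}_label", ""))
            equations[var] = RegimeSet(
                switch_variable=r["switch"], low=float(r["low"]), high=float(r["high"]),
                below=_regime("below"), middle=_regime("middle"), above=_regime("above"))
        else:
            equations[var] = [_term_from_dict(t, f"{where}.terms[{i}]")
                              for i, t in enumerate(eq["terms"])]

    events = []
    for i, e in enumerate(d.get("events", [])):
        where = f"events[{i}]"
        try:
            mode = e.get("mode", "table")
            if mode == "table":
                events.append(EventProcess(e["target"], "table",
                                           table=[(float(t), float(v)) for t, v in e["table"]]))
            elif mode == "renewal":
                mag = e.get("magnitude", {})
                events.append(EventProcess(e["target"], "renewal", rate=float(e["rate"]),
                                           magnitude_mu=float(mag.get("mu", 0.5)),
                                           magnitude_sigma=float(mag.get("sigma", 0.25)),
                                           magnitude_lower=float(mag.get("lower", 0.0))))
            elif mode == "state_coupled":
                mag = e.get("magnitude", {})
                events.append(EventProcess(e["target"], "state_coupled",
                                           probability_variable=e["probability_variable"],
                                           magnitude_mu=float(mag.get("mu", 0.5)),
                                           sd_variable=mag.get("sd_variable"),
                                           magnitude_lower=float(mag.get("lower", 0.0))))
            else:
                raise ConfigError(f"{where}: unknown mode {mode!r}")
        except ConfigError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc

    noise = []
    for i, n in enumerate(d.get("noise", [])):
        try:
            noise.append(StochasticModifier(
                id=n["id"], distribution=n.get("distribution", "normal"),
                fraction=float(n.get("fraction", 0.0)),
                mu=float(n.get("mu", 1.0)), sigma=float(n.get("sigma", 0.0)),
                lower=(float(n["lower"]) if "lower" in n else None),
                refresh=int(n.get("refresh", 1)),
                target=n.get("target", "term"), variable=n.get("variable")))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"noise[{i}]: {exc}") from exc

    spec = ModelSpec(name=d.get("name", "unnamed"), variables=variables,
                     equations=equations, step_size=float(d["theta"]),
                     event_processes=events, noise_modifiers=noise,
                     time_unit=d.get("time_unit", "arbitrary"),
                     max_delay=d.get("max_delay"),
                     clamp_nonpositive_bases=bool(d.get("clamp_nonpositive_bases", False)),
                     metadata=d.get("metadata", {}))
    return validate_model(spec) if validate else spec


def read_model_config(path: PathLike) -> ModelSpec:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    try:
        return spec_from_dict(data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_model_config(spec: ModelSpec, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def config_hash(spec: ModelSpec) -> str:
    canon = yaml.safe_dump(spec_to_dict(spec), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to reproduce a simulation run bit-exactly."""

    model: str
    config_hash: str
    seed: Optional[int]
    theta: float
    t0: float
    t_end: float
    software_version: str = ""
    timestamp: str = ""
    event_log: list = field(default_factory=list)
    noise_log: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_run(cls, spec: ModelSpec, traj: Trajectory) -> "RunManifest":
        from . import __version__
        m = traj.metadata
        return cls(model=spec.name, config_hash=config_hash(spec),
                   seed=m.get("seed"), theta=m["theta"], t0=m["t0"],
                   t_end=m["t_end"], software_version=__version__,
                   timestamp=_time.strftime("%Y-%m-%dT%H:%M:%S"),
                   event_log=traj.event_log, noise_log=traj.noise_log)


def write_trajectory(traj: Trajectory, path: PathLike, fmt: str = "tsv",
                     spec: Optional[ModelSpec] = None) -> None:
    """Write a trajectory table plus a ``<path>.meta.json`` manifest sidecar."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    df = traj.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    manifest = (RunManifest.from_run(spec, traj) if spec is not None else None)
    side = {"metadata": _jsonable(traj.metadata),
            "event_log": _jsonable(traj.event_log),
            "noise_log": _jsonable(traj.noise_log)}
    if manifest is not None:
        side["manifest"] = _jsonable(asdict(manifest))
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(side, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_trajectory(path: PathLike) -> Trajectory:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path}: trajectory file lacks a 'time' column")
    cols = [c for c in df.columns if c != "time"]
    meta_path = Path(str(path) + ".meta.json")
    metadata, events, noise = {}, [], []
    if meta_path.exists():
        side = json.loads(meta_path.read_text())
        metadata = side.get("metadata", {})
        events = side.get("event_log", [])
        noise = side.get("noise_log", [])
    return Trajectory(df["time"].to_numpy(), df[cols].to_numpy(), cols,
                      metadata=metadata, event_log=events, noise_log=noise)


def read_series(path: PathLike) -> ObservedSeries:
    """Read an observed time-series table (time column + one per variable)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path}: series file lacks a 'time' column")
    return ObservedSeries.from_frame(df)


def write_series(series: ObservedSeries, path: PathLike, fmt: str = "tsv") -> None:
    sep = "\t" if fmt == "tsv" else ","
    series.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")
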