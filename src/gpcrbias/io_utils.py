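"""Configuration files, output writing, and provenance plumbing.

A single structured config file (YAML, of which JSON is a subset) holds the
model structure, parameter overrides, protocol, readout and fit settings.
Unknown keys are rejected by name; array-valued parameters are validated
against the model structure before any computation runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitConfig
from .functional_readout import ReadoutParams
from .model_core import ModelSpec, ParameterSet, default_parameters
from .simulation import CRCurve, Protocol, Trajectory

__all__ = ["RunConfig", "load_config", "save_config", "write_outputs",
           "trajectory_frame", "crcurve_frame"]

log = logging.getLogger("gpcrbias")


@dataclass
class RunConfig:
    """Validated bundle of everything a run needs."""

    spec: ModelSpec
    params: ParameterSet
    protocol: Protocol
    readout: ReadoutParams
    fit: FitConfig
    seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"

    def to_dict(self) -> Dict[str, Any]:
        def arr(v):
            return v.tolist() if isinstance(v, np.ndarray) else v

        pd_ = {f.name: arr(getattr(self.params, f.name)) for f in fields(self.params)}
        fit = dataclasses.asdict(self.fit)
        fit["free_params"] = list(fit["free_params"])
        fit["bounds"] = {k: list(v) for k, v in fit["bounds"].items()}
        fit["default_bounds"] = list(fit["default_bounds"])
        return {
            "model": {"n_active": self.spec.n_active, "n_gprot": self.spec.n_gprot,
                      "ligand_mode": self.spec.ligand_mode},
            "parameters": pd_,
            "protocol": dataclasses.asdict(self.protocol),
            "readout": dataclasses.asdict(self.readout),
            "fit": fit,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def provenance(self) -> Dict[str, Any]:
        return {"version": __version__, "config_hash": self.config_hash,
                "seed": self.seed}


def _check_keys(section: Dict[str, Any], allowed: List[str], where: str) -> None:
    for k in section:
        if k not in allowed:
            raise ValueError(f"unknown key {k!r} in config section {where!r} "
                             f"(allowed: {sorted(allowed)})")


def _build_dataclass(cls, section: Dict[str, Any], where: str):
    names = [f.name for f in fields(cls)]
    _check_keys(section, names, where)
    kwargs = dict(section)
    if cls is FitConfig:
        if "free_params" in kwargs:
            kwargs["free_params"] = tuple(kwargs["free_params"])
        if "bounds" in kwargs:
            kwargs["bounds"] = {k: tuple(v) for k, v in kwargs["bounds"].items()}
        if "default_bounds" in kwargs:
            kwargs["default_bounds"] = tuple(kwargs["default_bounds"])
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a config file, filling defaults.

    A minimal config needs only the ``model`` section (or nothing at all for
    the stock two-pathway system); everything else defaults.  Unknown keys
    anywhere raise a ``ValueError`` naming the offending key; array-valued
    parameter overrides are shape-checked against the model structure.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ValueError(f"could not parse {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, ["model", "parameters", "protocol", "readout", "fit",
                      "seed", "output_dir", "log_level"], "<root>")

    model_sec = raw.get("model", {})
    _check_keys(model_sec, ["n_active", "n_gprot", "ligand_mode"], "model")
    spec = ModelSpec(**model_sec)

    params = default_parameters(spec)
    overrides = raw.get("parameters", {})
    allowed = [f.name for f in fields(params)]
    _check_keys(overrides, allowed, "parameters")
    for k, v in overrides.items():
        cur = getattr(params, k)
        setattr(params, k, np.asarray(v, dtype=float)
                if isinstance(cur, np.ndarray) else float(v))
    try:
        params.validate(spec)
    except ValueError as e:
        raise ValueError(f"invalid parameters in {path}: {e}") from e

    protocol = _build_dataclass(Protocol, raw.get("protocol", {}), "protocol")
    readout = _build_dataclass(ReadoutParams, raw.get("readout", {}), "readout")
    fit = _build_dataclass(FitConfig, raw.get("fit", {}), "fit")
    return RunConfig(spec=spec, params=params, protocol=protocol, readout=readout,
                     fit=fit, seed=int(raw.get("seed", 0)),
                     output_dir=str(raw.get("output_dir", "out")),
                     log_level=str(raw.get("log_level", "INFO")))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# output writing

def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    df = pd.DataFrame(traj.y, columns=[f"{n} (M)" for n in traj.species.names])
    df.insert(0, "time (s)", traj.t)
    return df


def crcurve_frame(curves: Dict[int, CRCurve]) -> pd.DataFrame:
    first = next(iter(curves.values()))
    df = pd.DataFrame({"ligand_concentration (M)": first.concentrations})
    for pw, cr in sorted(curves.items()):
        unit = "s" if cr.feature.endswith("_time") else "M"
        df[f"aGTP{pw} {cr.feature} ({unit})"] = cr.response
    return df


def write_outputs(results: Dict[str, pd.DataFrame], out_dir: str | Path,
                  provenance: Optional[Dict[str, Any]] = None) -> pd.DataFrame:
    """Write result tables as CSV plus a checksummed manifest.

    ``results`` maps a base filename (no extension) to a DataFrame.  Returns
    the manifest (file, type, sha256) which is also written as
    ``manifest.csv``; provenance, if given, is written as
    ``provenance.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in results.items():
        fp = out / f"{name}.csv"
        df.to_csv(fp, index=False, float_format="%.17g")
        digest = hashlib.sha256(fp.read_bytes()).hexdigest()
        rows.append({"file": fp.name, "type": "csv", "sha256": digest})
        log.info("wrote %s (%d rows)", fp, len(df))
    manifest = pd.DataFrame(rows).sort_values("file").reset_index(drop=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    if provenance is not None:
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                        sort_keys=True))
    return manifest
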