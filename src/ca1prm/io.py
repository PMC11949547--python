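"""Configuration loading/validation and result serialization.

Configs and structured results are JSON (human-diffable); tabular batch
outputs are CSV.  Every result document embeds the seed, the package
version and the ModelParams fingerprint needed to regenerate it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (CellType, ModelParams, WeightSet, MASK_EDGES, MASK,
                    parse_edge, edge_key)
from .simulate import SimConfig
from .ga import GAConfig

__all__ = ["RunConfig", "load_config", "validate_config",
            "save_json", "load_json", "weights_to_csv", "weights_from_csv"]

_KNOWN_TOP_KEYS = {"model", "sim", "ga", "experiments", "output_dir",
                   "log_level"}
_KNOWN_MODEL_KEYS = {"cells", "tau_ms", "weights", "baseline_stim"}
_KNOWN_CELL_KEYS = {"alpha", "r0", "ie", "beta"}
_KNOWN_SIM_KEYS = {"dt", "duration", "transient_discard", "seed"}
_KNOWN_GA_KEYS = {"target_count", "mutation_count_mean", "factor_range",
                  "primary_power_fraction", "pv_bic_ratio_min",
                  "cck_min_rate", "secondary_theta_fraction",
                  "cluster_ratio_min", "max_evaluations", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration of one run."""

    model: ModelParams = field(default_factory=ModelParams)
    sim: SimConfig = field(default_factory=SimConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    experiments: dict = field(default_factory=dict)
    output_dir: str = "results"
    log_level: str = "INFO"


def validate_config(doc: dict) -> list:
    """All schema violations in ``doc`` (empty list when valid)."""
    errors = []
    if not isinstance(doc, dict):
        return ["configuration root must be a JSON object"]
    for key in doc:
        if key not in _KNOWN_TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    model = doc.get("model", {})
    for key in model:
        if key not in _KNOWN_MODEL_KEYS:
            errors.append(f"unknown model key {key!r}")
    for name, cell in model.get("cells", {}).items():
        try:
            CellType.from_name(name)
        except ValueError as e:
            errors.append(str(e))
            continue
        for key in cell:
            if key not in _KNOWN_CELL_KEYS:
                errors.append(f"unknown cell parameter {key!r} for {name}")
    for key, value in model.get("weights", {}).items():
        try:
            edge = parse_edge(key)
        except ValueError as e:
            errors.append(str(e))
            continue
        if edge not in MASK:
            errors.append(f"edge {key} is not a circuit connection")
            continue
        if MASK.is_excitatory(edge) and value < 0:
            errors.append(f"excitatory edge {key} has negative weight")
        if not MASK.is_excitatory(edge) and value > 0:
            errors.append(f"inhibitory edge {key} has positive weight")
    sim = doc.get("sim", {})
    for key in sim:
        if key not in _KNOWN_SIM_KEYS:
            errors.append(f"unknown sim key {key!r}")
    dt = sim.get("dt", 0.001)
    tau_ms = model.get("tau_ms", 5.0)
    if dt <= 0:
        errors.append("sim.dt must be positive")
    else:
        steps = (tau_ms / 1000.0) / dt
        if abs(steps - round(steps)) > 1e-9:
            errors.append(
                f"delay tau = {tau_ms} ms is not an integer multiple of "
                f"dt = {dt} s")
    ga = doc.get("ga", {})
    for key in ga:
        if key not in _KNOWN_GA_KEYS:
            errors.append(f"unknown ga key {key!r}")
    return errors


def load_config(path) -> RunConfig:
    """Load and validate a JSON configuration file.

    Missing fields fall back to the model's default parameter table
    (beta = 20 au, tau = 5 ms, alpha_PYR = 40 Hz, ...).  All schema
    violations are reported together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"configuration is not valid JSON: {e}") from e
    errors = validate_config(doc)
    if errors:
        raise ValueError("invalid configuration:\n  - "
                         + "\n  - ".join(errors))
    model = ModelParams.from_dict(doc.get("model", {}))
    sim = SimConfig(**doc.get("sim", {}))
    ga = GAConfig(**{k: (tuple(v) if k == "factor_range" else v)
                     for k, v in doc.get("ga", {}).items()})
    return RunConfig(model=model, sim=sim, ga=ga,
                     experiments=doc.get("experiments", {}),
                     output_dir=doc.get("output_dir", "results"),
                     log_level=doc.get("log_level", "INFO"))


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, CellType):
            return o.name
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return super().default(o)


def save_json(obj, path, *, seed=None, params: ModelParams | None = None):
    """Write a result document with provenance metadata."""
    from . import __version__
    doc = {"ca1prm_version": __version__}
    if seed is not None:
        doc["seed"] = seed
    if params is not None:
        doc["params_fingerprint"] = params.fingerprint()
    doc["result"] = obj
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, cls=_Encoder)
        fh.write("\n")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def weights_to_csv(rows, path, extra_columns=None):
    """Weight sets as CSV, one row per set, columns keyed "SRC->TGT".

    ``rows`` is a list of WeightSet or (WeightSet, dict-of-extras).
    """
    records = []
    for row in rows:
        ws, extra = row if isinstance(row, tuple) else (row, {})
        rec = {edge_key(e): ws[e] for e in MASK_EDGES}
        rec.update(extra or {})
        records.append(rec)
    df = pd.DataFrame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def weights_from_csv(path) -> list:
    df = pd.read_csv(path)
    keys = [edge_key(e) for e in MASK_EDGES]
    missing = [k for k in keys if k not in df.columns]
    if missing:
        raise ValueError(f"weights CSV missing columns: {missing}")
    return [WeightSet({k: row[k] for k in keys})
            for _, row in df.iterrows()]
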