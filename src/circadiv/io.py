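"""Readers/writers for the pipeline's CSV schemas and YAML configuration.

Cell table columns: cell_id, lineage_id, parent_id, condition,
birth_time_h, division_time_h (empty if censored), birth_length_um,
division_length_um (empty if censored), censored (0/1).
Trace table columns: cell_id, time_h, length_um.

Every file written by the pipeline carries a provenance comment line
(config hash, seed, package version); readers skip '#' comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CouplingFunction, SizeControlParams
from .light import ElongationModel, LightProfile
from .simulate import CELL_COLUMNS, TRACE_COLUMNS, SimConfig

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_trace_table",
    "write_trace_table",
    "load_config",
    "config_hash",
    "provenance_line",
]


class SchemaError(ValueError):
    """Raised when an input table does not match the pipeline schema."""


def provenance_line(seed=None, cfg_hash=None) -> str:
    parts = [f"circadiv v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return "# provenance: " + " ".join(parts)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_cell_table(cells: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, cfg_hash) + "\n")
        cells.to_csv(fh, index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell table; censored rows may have empty division fields."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path} missing columns: {missing}")
    if len(df) == 0:
        return df
    for col in ("birth_length_um", "division_length_um"):
        if (df[col].dropna() <= 0).any():
            raise SchemaError(f"non-positive lengths in column {col}")
    obs = df[df["censored"] == 0]
    bad = obs["division_time_h"] < obs["birth_time_h"]
    if bad.any():
        raise SchemaError(f"{int(bad.sum())} cells with division_time_h < birth_time_h")
    if obs["division_time_h"].isna().any() or obs["division_length_um"].isna().any():
        raise SchemaError("uncensored cells must have division time and length")
    return df


def write_trace_table(traces: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, cfg_hash) + "\n")
        traces.to_csv(fh, index=False)


def read_trace_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table {path} missing columns: {missing}")
    return df


# -- configuration -----------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML pipeline config and build the typed components.

    Recognized sections: light (LightProfile kwargs), elongation
    (ElongationModel kwargs), size_control (SizeControlParams kwargs),
    coupling ('flat', 'bump', explicit {knot_times, log_values}, or
    'infer'), sim (SimConfig kwargs), scenario, analysis options.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = {"raw": raw, "hash": config_hash(raw)}
    cfg["scenario"] = raw.get("scenario", "clockdel_constant")
    cfg["seed"] = int(raw.get("seed", 0))
    cfg["outdir"] = raw.get("outdir", "results")
    if "light" in raw:
        cfg["profile"] = LightProfile(**raw["light"])
    if "elongation" in raw:
        cfg["model"] = ElongationModel(**raw["elongation"])
    if "size_control" in raw:
        cfg["params"] = SizeControlParams(**raw["size_control"])
    sim_kw = dict(raw.get("sim", {}))
    sim_kw.setdefault("seed", cfg["seed"])
    cfg["sim"] = SimConfig(**sim_kw)
    coup = raw.get("coupling", None)
    if isinstance(coup, dict) and "knot_times" in coup:
        cfg["coupling"] = CouplingFunction(
            np.asarray(coup["knot_times"], float), np.asarray(coup["log_values"], float)
        )
    else:
        cfg["coupling"] = coup  # 'flat' | 'bump' | 'infer' | None
    cfg["analysis"] = raw.get("analysis", {})
    return cfg
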