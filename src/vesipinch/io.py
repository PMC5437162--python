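"""Table writers/readers and configuration loading.

Sweep tables are written as CSV with a JSON metadata sidecar (parameters,
tier, tolerances, package version); phase maps as a CSV matrix plus a JSON
legend.  All writes round-trip losslessly (full float precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import MembraneParams, params_from_config
from .observables import PhaseMap

__all__ = ["write_sweep", "read_sweep", "write_phase_map", "load_config",
           "write_profile_table"]

_FLOAT_FMT = "%.17g"


def write_sweep(df: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    """Write a sweep table as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"format": "vesipinch-sweep", "version": 1}
    if metadata:
        meta.update(metadata)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=_jsonify))
    return path


def read_sweep(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, meta


def write_profile_table(table: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, table, fmt=_FLOAT_FMT, header="x R", comments="# ")
    return path


def write_phase_map(pm: PhaseMap, stem) -> list[Path]:
    """Write force matrix, category matrix and a JSON legend."""
    stem = Path(stem)
    paths = []
    for suffix, mat in (("force", pm.F), ("category", pm.category)):
        p = stem.with_name(stem.name + f".{suffix}.csv")
        pd.DataFrame(mat, index=pm.sig_grid, columns=pm.prs_grid).to_csv(
            p, float_format=_FLOAT_FMT)
        paths.append(p)
    legend = {
        "c0r": pm.c0r, "s_eval": pm.s_eval, "tier": pm.tier,
        "F_ref": pm.F_ref,
        "rows": "sig (Sigma R_m^2 / kappa)",
        "columns": "prs (DeltaP R_m^3 / kappa)",
        "categories": pm.legend(),
    }
    p = stem.with_name(stem.name + ".legend.json")
    p.write_text(json.dumps(legend, indent=2, default=_jsonify))
    paths.append(p)
    return paths


def load_config(path) -> MembraneParams:
    """Load a YAML or JSON configuration file into MembraneParams."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return params_from_config(cfg)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
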