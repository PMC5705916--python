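"""CSV/JSON serialization of trajectories, transfer series and scan tables.

Every table is written as RFC-4180-style CSV with a units-bearing header row
plus a JSON sidecar recording the fully resolved parameters (with provenance
flags), variant, and integrator diagnostics.  The model is deterministic:
the sidecar records that no randomness is involved.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd

from .experiments import ScanTable
from .model import STATE_FIELDS, STATE_UNITS
from .simulate import Trajectory, TransferSeries

__all__ = ["write_trajectory", "write_transfer_series", "write_scan_table",
           "sidecar_for"]


def _write_sidecar(path: Path, payload: Dict) -> Path:
    side = path.with_suffix(".json")
    payload = {"determinism": "model is deterministic; no RNG involved",
               **payload}
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str)
                    + "\n")
    return side


def sidecar_for(obj: Union[Trajectory, TransferSeries, ScanTable],
                extra: Optional[Dict] = None) -> Dict:
    """Build the JSON-serializable metadata for a result object."""
    meta: Dict = dict(extra or {})
    if isinstance(obj, Trajectory):
        meta.update({
            "kind": "trajectory",
            "variant": obj.variant.value,
            "parameters": obj.params.describe(),
            "integrator": obj.diagnostics,
            "n_points": int(obj.times.size),
        })
    elif isinstance(obj, TransferSeries):
        first = obj.trajectories[0]
        meta.update({
            "kind": "transfer_series",
            "variant": first.variant.value,
            "parameters": first.params.describe(),
            "protocol": {
                "batch_duration_h": obj.protocol.batch_duration,
                "dilution_fraction": obj.protocol.dilution_fraction,
                "n_transfers": obj.protocol.n_transfers,
                "fresh_medium_mM": obj.protocol.fresh_medium,
                "carry_spent_medium": obj.protocol.carry_spent_medium,
            },
            "integrator": [t.diagnostics for t in obj.trajectories],
        })
    elif isinstance(obj, ScanTable):
        meta.update({
            "kind": "scan_table",
            "parameter": obj.parameter,
            "grid": list(map(float, obj.grid)),
            "fixed": obj.fixed,
        })
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    return meta


def write_trajectory(traj: Trajectory, path: Union[str, Path],
                     extra: Optional[Dict] = None) -> Path:
    """Write one row per time point; returns the CSV path."""
    path = Path(path)
    df = traj.to_dataframe()
    df.columns = traj.csv_header()
    df.to_csv(path, index=False)
    _write_sidecar(path, sidecar_for(traj, extra))
    return path


def write_transfer_series(series: TransferSeries, path: Union[str, Path],
                          extra: Optional[Dict] = None) -> Path:
    """Write all transfers concatenated, with transfer index and summary."""
    path = Path(path)
    frames = []
    for k, traj in enumerate(series.trajectories, start=1):
        df = traj.to_dataframe()
        df.insert(0, "transfer", k)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.columns = (["transfer"] + ["time [h]"]
                   + [f"{n} [{STATE_UNITS[n]}]" for n in STATE_FIELDS])
    out.to_csv(path, index=False)
    summary_path = path.with_name(path.stem + "_summary.csv")
    summary = series.summary()
    summary.columns = [
        "transfer", "Ec_initial [cells/ml]", "Rp_initial [cells/ml]",
        "Ec_final [cells/ml]", "Rp_final [cells/ml]", "pct_Ec_final [%]"]
    summary.to_csv(summary_path, index=False)
    _write_sidecar(path, sidecar_for(series, extra))
    return path


_SCAN_UNITS = {
    "affinity_ratio": "K_A/K_AR",
    "R_A": "fmol/cell",
    "rp_to_ec_inoculum_ratio": "dimensionless",
    "final_Ec": "cells/ml",
    "final_Rp": "cells/ml",
    "final_pct_Ec": "%",
}


def write_scan_table(table: ScanTable, path: Union[str, Path],
                     extra: Optional[Dict] = None) -> Path:
    path = Path(path)
    df = table.to_dataframe()
    df.columns = [f"{c} [{_SCAN_UNITS[c]}]" if c in _SCAN_UNITS else c
                  for c in df.columns]
    df.to_csv(path, index=False)
    _write_sidecar(path, sidecar_for(table, extra))
    return path
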