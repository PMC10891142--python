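"""Artifact writers/readers: tidy CSV results, JSON summaries, HDF5 traces.

CSV is the canonical results format (stable column order, fixed float
formatting, so identical inputs yield byte-identical files); HDF5 is used
for voltage traces and state checkpoints.  Every result directory carries a
manifest with the schema version, package version and configuration hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SCHEMA_VERSION, config_hash
from .protocols import SimulationTrace

__all__ = ["write_trace_hdf5", "read_trace_hdf5", "write_trace_csv",
           "write_results"]

_RESULT_COLUMNS = ["motif", "variant", "T", "v_fr", "tau_d", "mode",
                   "pacing_cell", "g_loc", "g_long", "apd_m1", "apd_m2",
                   "delta_apd", "frac_pacing", "frac_response",
                   "regime_pacing", "regime_response", "error"]


def write_trace_hdf5(trace: SimulationTrace, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=trace.time)
        for name in ("v1", "v2", "vf1", "vf2"):
            v = getattr(trace, name)
            if v is not None:
                fh.create_dataset(name, data=v)
        fh.create_dataset("stim_times_m1", data=trace.stim_times_m1)
        fh.create_dataset("stim_times_m2", data=trace.stim_times_m2)
        fh.attrs["schema_version"] = SCHEMA_VERSION


def read_trace_hdf5(path) -> SimulationTrace:
    import h5py

    with h5py.File(path, "r") as fh:
        kw = {name: np.array(fh[name]) for name in ("v1", "v2", "vf1", "vf2")
              if name in fh}
        return SimulationTrace(time=np.array(fh["time"]),
                               stim_times_m1=np.array(fh["stim_times_m1"]),
                               stim_times_m2=np.array(fh["stim_times_m2"]),
                               **kw)


def write_trace_csv(trace: SimulationTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.6g")


def write_results(records: pd.DataFrame, outdir, config=None,
                  summary: dict | None = None, seed: int | None = None) -> dict:
    """Write results.csv (+ optional summary.json) and a manifest; return it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = records.copy()
    for col in _RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[[c for c in _RESULT_COLUMNS if c in df.columns]]
    csv_path = outdir / "results.csv"
    df.to_csv(csv_path, index=False, float_format="%.6g")

    from . import __version__

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "n_records": int(len(df)),
        "files": ["results.csv"],
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    if summary is not None:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
        manifest["files"].append("summary.json")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
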