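"""Readers and writers for the pipeline's file formats.

Responses travel as CSV (cell_id, direction_deg, response); ground truth and
mixture fits as JSON; traces as TIFF stacks or HDF5 with a JSON epoch-
metadata sidecar; run configuration as YAML.  Angles are degrees everywhere
on disk.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tuning import Trace, ResponseVector

RESPONSE_COLUMNS = ("cell_id", "direction_deg", "response")
SCHEMA_VERSION = 1


def read_responses(path) -> dict:
    """Read a response CSV into {cell_id: ResponseVector}."""
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table is missing column(s): {', '.join(missing)}")
    out = {}
    for cid, grp in df.groupby("cell_id", sort=True):
        out[cid] = ResponseVector(directions=grp["direction_deg"].to_numpy(),
                                  responses=grp["response"].to_numpy())
    return out


def write_results(profiles: dict, path) -> pd.DataFrame:
    """Write per-cell results CSV (cell_id, class, preferred_deg, dsi, osi, ...)."""
    rows = [dict(cell_id=cid, cell_class=p.cell_class,
                 preferred_deg=p.preferred_direction_deg, dsi=p.dsi, osi=p.osi,
                 fwhm_deg=p.fwhm_deg, r_squared=p.r_squared)
            for cid, p in profiles.items()]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_mixture(fit, path):
    payload = {
        "r_squared": fit.r_squared,
        "components": [dict(center_deg=c.center_deg, height=c.height,
                            concentration=c.concentration, fwhm_deg=c.fwhm_deg,
                            bounds_deg=list(c.bounds_deg))
                       for c in fit.components],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_trace_h5(trace: Trace, path):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=trace.values)
        f.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
    _write_epoch_sidecar(trace, Path(path).with_suffix(".json"))


def write_trace_tiff(trace: Trace, path):
    """Write the trace as a single-pixel TIFF stack (one frame per sample)."""
    import tifffile

    tifffile.imwrite(path, trace.values.astype(np.float32)[:, None, None])
    _write_epoch_sidecar(trace, Path(path).with_suffix(".json"))


def _write_epoch_sidecar(trace: Trace, path):
    meta = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "epoch_windows": [[s, e, lab] for s, e, lab in trace.epoch_windows],
        "interepoch_windows": [list(w) for w in trace.interepoch_windows],
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trace_h5(path) -> Trace:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][...]
        fs = float(f.attrs["sampling_rate_hz"])
    with open(Path(path).with_suffix(".json")) as fh:
        meta = json.load(fh)
    return Trace(values=values, sampling_rate_hz=fs,
                 epoch_windows=[tuple(w) for w in meta["epoch_windows"]],
                 interepoch_windows=[tuple(w) for w in meta["interepoch_windows"]])


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(out_dir, config: dict, outputs: list):
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": config,
        "config_hash": config_hash(config),
        "outputs": [str(p) for p in outputs],
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
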