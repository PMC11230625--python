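"""Readers and writers for the package's text formats.

Connectomes travel as CSV/TSV square matrices with a sidecar label list
(one label per line); events as BIDS-style TSV (onset, duration,
trial_type); seizure intervals and region statistics as TSV; simulation
time series as long-format TSV.  Every ``run_*`` CLI output directory
also receives a manifest recording the seed, configuration echo and
content hashes of the inputs, so artifacts are regenerable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eeg import EEGTrace, SeizureInterval, StimulationBlock
from .network import Connectome, RegionStats, SimulationResult

__all__ = [
    "load_connectome", "save_connectome",
    "load_events", "save_events",
    "load_intervals", "save_intervals",
    "load_motion", "save_motion",
    "load_eeg", "save_eeg",
    "save_timeseries", "save_region_stats",
    "write_manifest",
]


def _delim(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def load_connectome(matrix_path, labels_path, delays_path=None) -> Connectome:
    """Square weight matrix (CSV/TSV, no header) + one label per line."""
    weights = np.loadtxt(matrix_path, delimiter=_delim(matrix_path))
    labels = [ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()]
    delays = None
    if delays_path is not None:
        delays = np.loadtxt(delays_path, delimiter=_delim(delays_path))
    return Connectome(weights=weights, labels=labels, delays=delays)


def save_connectome(conn: Connectome, matrix_path, labels_path, delays_path=None):
    np.savetxt(matrix_path, conn.weights, delimiter=_delim(matrix_path), fmt="%.10g")
    Path(labels_path).write_text("\n".join(conn.labels) + "\n")
    if delays_path is not None and conn.delays is not None:
        np.savetxt(delays_path, conn.delays, delimiter=_delim(delays_path), fmt="%.10g")


def save_events(blocks, path):
    """BIDS-style events table: onset, duration, trial_type."""
    pd.DataFrame(
        [{"onset": b.onset, "duration": b.duration,
          "trial_type": b.label if b.label else "n/a"} for b in blocks]
    ).to_csv(path, sep="\t", index=False)


def load_events(path):
    df = pd.read_csv(path, sep="\t")
    return [
        StimulationBlock(onset=float(r.onset), duration=float(r.duration),
                         label=None if r.trial_type == "n/a" else str(r.trial_type))
        for r in df.itertuples()
    ]


def save_intervals(intervals, path):
    pd.DataFrame([{"start": iv.start, "end": iv.end} for iv in intervals]).to_csv(
        path, sep="\t", index=False
    )


def load_intervals(path):
    df = pd.read_csv(path, sep="\t")
    return [SeizureInterval(float(r.start), float(r.end)) for r in df.itertuples()]


MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_deg", "rot_y_deg", "rot_z_deg"]


def save_motion(motion, path):
    df = pd.DataFrame(np.asarray(motion, dtype=float), columns=MOTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def load_motion(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion table is missing columns: {missing}")
    return df[MOTION_COLUMNS]


def save_eeg(trace: EEGTrace, data_path, sidecar_path=None):
    """Single-column numeric text plus a YAML sidecar with fs/units."""
    np.savetxt(data_path, trace.samples, fmt="%.8g")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            yaml.safe_dump({"fs_hz": trace.fs, "units": "uV",
                            "channel": trace.channel, "t0_s": trace.t0}, fh)


def load_eeg(data_path, sidecar_path=None, fs: float | None = None) -> EEGTrace:
    samples = np.loadtxt(data_path)
    meta = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
    fs = fs if fs is not None else float(meta.get("fs_hz", 1024.0))
    return EEGTrace(samples=samples, fs=fs, channel=meta.get("channel", "EEG"),
                    t0=float(meta.get("t0_s", 0.0)))


def save_timeseries(result: SimulationResult, path, variables=("nu_e",),
                    decimate: int = 1):
    """Long-format TSV: time, region, variable, value."""
    rows = []
    t = result.time[::decimate]
    for var in variables:
        arr = getattr(result, var)[:, ::decimate]
        for i, label in enumerate(result.labels):
            rows.append(pd.DataFrame({
                "time_s": t, "region": label, "variable": var, "value": arr[i],
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def save_region_stats(stats: RegionStats, path):
    stats.table.to_csv(path, sep="\t", index=False)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for blk in iter(lambda: fh.read(1 << 20), b""):
            h.update(blk)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, seed, config: dict, inputs=(), outputs=()):
    """Record stage provenance: seed, config echo, input/output hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _hash_file(p) for p in inputs},
        "outputs": {str(p): _hash_file(p) for p in outputs},
    }
    path = out_dir / f"manifest_{stage}.yaml"
    tmp = path.with_suffix(".yaml.tmp")
    with open(tmp, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    tmp.rename(path)
    return path
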