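"""On-disk formats: per-molecule trace tables, manifests and results.

All delimited files use one fixed dialect: UTF-8, tab-separated, header
row, '.' decimal point, intensities printed at six decimals.  A dataset is
either a directory of per-molecule tables plus a JSON manifest carrying
the acquisition parameters, seeds and ground truth, or a single
hierarchical (HDF5) container with one group per molecule and the same
manifest as a root attribute.  Every artifact carries a schema version
and readers reject unknown major versions.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import IntensityTrace, TraceSet

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_dataset_h5",
    "read_dataset_h5",
    "write_trace",
    "read_trace",
    "write_trajectory",
    "write_idealized",
    "write_dwells",
]

SCHEMA_VERSION = "1.0"
_FLOAT_FMT = "%.6f"


def write_trace(trace: IntensityTrace, path: Path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(trace.n_frames),
            "donor": trace.donor,
            "acceptor": trace.acceptor,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_trace(path: Path, frame_interval: float) -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    return IntensityTrace(
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy(),
        frame_interval=frame_interval,
        molecule_id=Path(path).stem,
    )


def write_dataset(ts: TraceSet, outdir) -> Path:
    """Write a trace set as a directory of tables plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(ts.manifest)
    manifest["schema_version"] = SCHEMA_VERSION
    manifest["molecules"] = []
    for trace in ts.traces:
        fname = f"{trace.molecule_id}.tsv"
        write_trace(trace, outdir / fname)
        gt = {
            k: v
            for k, v in trace.ground_truth.items()
            if isinstance(v, (int, float, str, bool))
        }
        manifest["molecules"].append(
            {"molecule_id": trace.molecule_id, "replicate": trace.replicate,
             "file": fname, "ground_truth": gt}
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def read_dataset(path) -> TraceSet:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    major = str(manifest.get("schema_version", "0")).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(f"unsupported schema version {manifest.get('schema_version')!r}")
    dt = 1.0 / manifest["frame_rate"]
    traces = []
    missing = []
    for entry in manifest["molecules"]:
        fpath = path / entry["file"]
        if not fpath.exists():
            missing.append(entry["molecule_id"])
            continue
        trace = read_trace(fpath, dt)
        trace.molecule_id = entry["molecule_id"]
        trace.replicate = int(entry["replicate"])
        trace.ground_truth = dict(entry.get("ground_truth", {}))
        traces.append(trace)
    if missing:
        raise ValueError(f"manifest lists missing trace files: {missing}")
    return TraceSet(traces, {k: v for k, v in manifest.items() if k != "molecules"})


def write_dataset_h5(ts: TraceSet, path) -> Path:
    """Write a trace set as a single hierarchical container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = dict(ts.manifest)
    manifest["schema_version"] = SCHEMA_VERSION
    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
        for trace in ts.traces:
            grp = fh.create_group(trace.molecule_id)
            grp.create_dataset("donor", data=np.round(trace.donor, 6))
            grp.create_dataset("acceptor", data=np.round(trace.acceptor, 6))
            grp.attrs["replicate"] = trace.replicate
            gt = {k: v for k, v in trace.ground_truth.items()
                  if isinstance(v, (int, float, str, bool))}
            grp.attrs["ground_truth"] = json.dumps(gt, sort_keys=True)
    return path


def read_dataset_h5(path) -> TraceSet:
    with h5py.File(path, "r") as fh:
        manifest = json.loads(fh.attrs["manifest"])
        major = str(manifest.get("schema_version", "0")).split(".")[0]
        if major != SCHEMA_VERSION.split(".")[0]:
            raise ValueError(f"unsupported schema version {manifest.get('schema_version')!r}")
        dt = 1.0 / manifest["frame_rate"]
        traces = []
        for name in sorted(fh):
            grp = fh[name]
            trace = IntensityTrace(
                donor=grp["donor"][()],
                acceptor=grp["acceptor"][()],
                frame_interval=dt,
                molecule_id=name,
                replicate=int(grp.attrs["replicate"]),
            )
            trace.ground_truth = json.loads(grp.attrs.get("ground_truth", "{}"))
            traces.append(trace)
    return TraceSet(traces, manifest)


def write_trajectory(traj, path: Path) -> None:
    """State path as a 3-column table (state, t_enter, t_exit)."""
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9f")


def write_idealized(itraces, path: Path) -> None:
    rows = []
    for it in itraces:
        for d in it.dwells:
            rows.append(
                {
                    "molecule_id": it.molecule_id,
                    "replicate": it.replicate,
                    "mu": d.mu,
                    "sigma": d.sigma,
                    "t_start": d.t_start,
                    "t_end": d.t_end,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_dwells(dist, path: Path) -> None:
    pd.DataFrame({"dwell_s": dist.dwells}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
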