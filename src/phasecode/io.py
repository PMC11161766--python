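"""File formats: response tables (TSV), trial streams (HDF5), manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .stats import validate_response_table

HDF5_LAYOUT_VERSION = "1"


def write_response_table(table: pd.DataFrame, path):
    validate_response_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_response_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_response_table(table)
    return table


def write_neural_dataset(data: dict, path, seed=None):
    """HDF5 layout: /streams/<name>, /responses/<labeling>, /times."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = HDF5_LAYOUT_VERSION
        f.attrs["package_version"] = __version__
        f.attrs["sfreq"] = float(data["sfreq"])
        if seed is not None:
            f.attrs["seed"] = int(seed)
        f.create_dataset("times", data=np.asarray(data["times"]))
        g = f.create_group("streams")
        for name, arr in data["streams"].items():
            g.create_dataset(name, data=arr, compression="gzip",
                             compression_opts=1)
        g = f.create_group("responses")
        for name, arr in data["responses"].items():
            g.create_dataset(name, data=np.asarray(arr, dtype=np.int8))


def read_neural_dataset(path) -> dict:
    with h5py.File(path, "r") as f:
        if f.attrs.get("layout_version") != HDF5_LAYOUT_VERSION:
            raise ValueError("unknown HDF5 layout version")
        return {
            "sfreq": float(f.attrs["sfreq"]),
            "times": f["times"][()],
            "streams": {k: f["streams"][k][()] for k in f["streams"]},
            "responses": {k: f["responses"][k][()] for k in f["responses"]},
        }


def write_trace(trace, table_path, crossings_path=None):
    """Export a simulation trace: long activation table + crossing record.

    The table has columns (time_ms, level, node, activation); crossings go
    to JSON as a list of {level, node, time_ms, activation}.
    """
    frames = []
    for level, act in trace.activation.items():
        ids = trace.node_ids[level]
        for i, node in enumerate(ids):
            frames.append(pd.DataFrame({
                "time_ms": trace.times, "level": level, "node": node,
                "activation": act[i]}))
    pd.concat(frames, ignore_index=True).to_csv(table_path, sep="\t",
                                                index=False)
    if crossings_path is not None:
        record = [
            {"level": level, "node": trace.node_ids[level][node],
             "time_ms": t, "activation": a}
            for level, node, t, a in trace.crossings]
        Path(crossings_path).write_text(json.dumps(record, indent=2) + "\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per workflow run."""

    command: str
    config: dict
    seeds: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path):
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str)
                        + "\n")
        return path
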