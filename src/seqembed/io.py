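"""Plain-text dataset I/O.

Sequences are headerless comma-delimited matrices, one row per time step;
frame labels are one integer per line; a JSON manifest ties pairs together.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import SequencePair

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_labels",
    "read_labels",
    "write_dataset",
    "load_dataset",
]


def write_sequence(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(matrix), delimiter=",", fmt="%.17g")


def read_sequence(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_labels(path, labels) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def read_labels(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).ravel()


def write_dataset(pairs: list[SequencePair], out_dir) -> Path:
    """Write every pair's X/Y as CSV plus a manifest.json; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, p in enumerate(pairs):
        x_name, y_name = f"seq{i:03d}_x.csv", f"seq{i:03d}_y.csv"
        write_sequence(out / x_name, p.X)
        write_sequence(out / y_name, p.Y)
        entries.append({
            "x_path": x_name, "y_path": y_name, "type_id": p.type_id,
            "Te": p.Te, "Td": p.Td, "M": p.M, "onehot_width": p.onehot_width,
        })
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"sequences": entries}, indent=2))
    return manifest


def load_dataset(data_dir) -> list[SequencePair]:
    data = Path(data_dir)
    manifest = json.loads((data / "manifest.json").read_text())
    pairs = []
    for e in manifest["sequences"]:
        pairs.append(SequencePair(
            X=read_sequence(data / e["x_path"]),
            Y=read_sequence(data / e["y_path"]),
            type_id=e["type_id"],
            onehot_width=e.get("onehot_width", 0),
        ))
    return pairs
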