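"""Plain-text readers and writers shared by all pipeline stages.

Every format is line-oriented so results can be checked with independent
tooling: label trajectories are one integer per line, feature trajectories
and projections are whitespace-separated numeric columns with ``#`` header
lines, count/transition matrices are sparse (row, col, value) triplets, and
manifests are ``key: value`` text.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

__all__ = [
    "read_labels",
    "write_labels",
    "read_columnar",
    "write_columnar",
    "read_manifest",
    "write_manifest",
    "read_sparse_matrix",
    "write_sparse_matrix",
    "read_pdb_structure",
    "file_sha256",
]


def write_labels(path, labels) -> None:
    """Write an integer state-label trajectory, one label per line."""
    labels = np.asarray(labels, dtype=int)
    np.savetxt(path, labels, fmt="%d")


def read_labels(path) -> np.ndarray:
    out = np.loadtxt(path, dtype=int, ndmin=1)
    return out


def write_columnar(path, values, header: str | None = None) -> None:
    """Write a frames-by-features numeric matrix, one frame per row."""
    values = np.asarray(values, dtype=float)
    np.savetxt(path, values, header=header or "", comments="# ")


def read_columnar(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)


def write_manifest(path, mapping: dict) -> None:
    lines = [f"{k}: {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> dict:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out


def write_sparse_matrix(path, matrix, header: dict | None = None) -> None:
    """Write a matrix as (row, col, value) triplets with ``# key=value`` header."""
    matrix = np.asarray(matrix)
    rows, cols = np.nonzero(matrix)
    with open(path, "w") as fh:
        fh.write(f"# shape={matrix.shape[0]},{matrix.shape[1]}\n")
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        for i, j in zip(rows, cols):
            fh.write(f"{i}\t{j}\t{matrix[i, j]!r}\n")


def read_sparse_matrix(path) -> tuple[np.ndarray, dict]:
    meta: dict[str, str] = {}
    triplets = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        else:
            i, j, v = line.split("\t")
            triplets.append((int(i), int(j), float(v)))
    n, m = (int(x) for x in meta.pop("shape").split(","))
    out = np.zeros((n, m))
    for i, j, v in triplets:
        out[i, j] = v
    if out.size and np.allclose(out, np.round(out)) and all(
        float(v).is_integer() for _, _, v in triplets
    ):
        out = out.astype(int)
    return out, meta


def read_pdb_structure(path):
    """Read a PDB file into a biotite AtomArray (or AtomArrayStack if multi-model)."""
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        structure = pdb.get_structure()
    except Exception as exc:  # biotite raises several parse error types
        raise ValueError(f"could not parse PDB file {path!r}: {exc}") from exc
    if structure.stack_depth() == 1:
        return structure[0]
    return structure


def file_sha256(path) -> str:
    digest = hashlib.sha256(Path(path).read_bytes())
    return digest.hexdigest()
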