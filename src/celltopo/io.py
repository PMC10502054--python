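"""Readers and writers for the pipeline's plain-text artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_positions", "read_positions", "load_sim_config",
           "PositionsParseError", "write_feature_matrix", "read_feature_matrix"]

_HEADER = "x,y,cell_type"


class PositionsParseError(ValueError):
    pass


def write_positions(path, positions: np.ndarray, type_tokens) -> None:
    """Write a labeled point cloud as ``x,y,cell_type`` at full float
    precision so a read round-trips bit-identically."""
    positions = np.asarray(positions, dtype=float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for (x, y), tok in zip(positions, type_tokens):
            fh.write(f"{float(x)!r},{float(y)!r},{tok}\n")


def read_positions(path):
    """Read a positions table; returns ``(positions, type_tokens)``."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols != _HEADER.split(","):
            raise PositionsParseError(
                f"{path}:1: expected header '{_HEADER}', got {header!r}")
        xs, ys, toks = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise PositionsParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise PositionsParseError(
                    f"{path}:{lineno}: non-numeric coordinate") from exc
            toks.append(parts[2])
    return np.column_stack([xs, ys]) if xs else np.empty((0, 2)), toks


def load_sim_config(path) -> dict:
    """Simulation configuration from JSON or YAML, as a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_feature_matrix(path, matrix: np.ndarray, provenance=None) -> None:
    """Delimited feature matrix plus a JSON sidecar describing the block
    layout (channel, homology dimension, featurization, length)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=",",
               fmt="%.17g")
    if provenance is not None:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(
            [list(p) for p in provenance], indent=1))


def read_feature_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
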