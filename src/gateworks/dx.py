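"""Minimal OpenDX volumetric I/O for regular scalar grids."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_dx(path: str | Path, origin: np.ndarray, spacing: float,
             values: np.ndarray, comment: str = "") -> None:
    """Write a scalar field on a regular isotropic grid in OpenDX format."""
    values = np.asarray(values, dtype=float)
    nx, ny, nz = values.shape
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.6e} {origin[1]:.6e} {origin[2]:.6e}\n")
        fh.write(f"delta {spacing:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {spacing:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {spacing:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        flat = values.ravel(order="C")  # z fastest, DX convention
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path: str | Path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read an OpenDX scalar field; returns (origin, spacing, values)."""
    counts = origin = None
    deltas: list[list[float]] = []
    data: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1"):
                counts = [int(x) for x in s.split()[-3:]]
            elif s.startswith("origin"):
                origin = np.array([float(x) for x in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(x) for x in s.split()[1:4]])
            elif "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
            elif n_items is not None and len(data) < n_items:
                try:
                    data.extend(float(x) for x in s.split())
                except ValueError:
                    pass
    if counts is None or origin is None or n_items is None:
        raise ValueError(f"{path}: not a parseable OpenDX scalar grid")
    spacing = float(deltas[0][0]) if deltas else 1.0
    values = np.array(data[:n_items]).reshape(counts, order="C")
    return origin, spacing, values
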