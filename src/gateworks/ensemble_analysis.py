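"""Conformational clustering and residue-interaction traces.

Pairwise RMSD matrices (optionally after optimal rigid superposition) feed the
greedy neighbor-count clustering of Daura et al.: the frame with the most
neighbors within the cutoff becomes a cluster center, it and its neighbors are
removed, and the step repeats. A 0.25 nm cutoff on all protein atoms is the
conventional choice for equilibrium trajectories. Distance units follow the
clustering convention (nm); coordinates stay in Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Ensemble, Structure, select

__all__ = [
    "ClusterResult",
    "pairwise_rmsd",
    "daura_cluster",
    "contains_frame",
    "residue_min_distance_trace",
    "salt_bridge_groups",
]

A_TO_NM = 0.1

#: Default interaction atoms for an Arg–Glu salt bridge: guanidinium nitrogens
#: against carboxylate oxygens.
ARG_NITROGENS = ("NH1", "NH2", "NE")
GLU_OXYGENS = ("OE1", "OE2")


@dataclass
class ClusterResult:
    """Disjoint clusters ordered by decreasing size (ties: lower center index)."""

    clusters: list[dict]   # {"center": int, "members": list[int]} (members incl. center)
    cutoff: float          # nm

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            members = set(c["members"])
            if c["center"] not in members:
                raise ValueError("cluster center must be among its members")
            if members & seen:
                raise ValueError("clusters must be disjoint")
            seen |= members
        sizes = [len(c["members"]) for c in self.clusters]
        if any(a < b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("clusters must be ordered by decreasing size")


def _superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def pairwise_rmsd(ensemble: Ensemble, selection: Sequence[int] | None = None,
                  superpose: bool = True) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix in nm.

    With ``superpose`` the optimal least-squares rotation/translation (Kabsch,
    unit weights) is removed before measuring; otherwise raw coordinates are
    compared. Superposition needs at least three non-collinear atoms.
    """
    idx = (np.arange(len(ensemble.topology)) if selection is None
           else np.asarray(selection, dtype=int))
    if idx.size == 0:
        raise ValueError("selection must be non-empty")
    if superpose and idx.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    frames = ensemble.frames[:, idx, :]
    n = len(frames)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if superpose:
                r = _superposed_rmsd(frames[i], frames[j])
            else:
                r = float(np.sqrt(np.mean(np.sum(
                    (frames[i] - frames[j]) ** 2, axis=1))))
            out[i, j] = out[j, i] = r
    return out * A_TO_NM


def daura_cluster(rmsd: np.ndarray, cutoff: float = 0.25) -> ClusterResult:
    """Greedy neighbor-count clustering of a distance matrix (nm).

    Repeatedly promotes the frame with the most unassigned neighbors within
    ``cutoff`` to a cluster center (ties broken by the lowest frame index) and
    removes it with its neighbors, until every frame is assigned.
    """
    rmsd = np.asarray(rmsd, dtype=float)
    n = rmsd.shape[0]
    if rmsd.shape != (n, n) or not np.allclose(rmsd, rmsd.T):
        raise ValueError("rmsd must be a square symmetric matrix")
    if not np.allclose(np.diag(rmsd), 0.0):
        raise ValueError("rmsd must have a zero diagonal")
    neighbors = rmsd <= cutoff
    unassigned = np.ones(n, dtype=bool)
    clusters = []
    while np.any(unassigned):
        counts = (neighbors & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(neighbors[center] & unassigned)[0]
        clusters.append({"center": center, "members": members.tolist()})
        unassigned[members] = False
    clusters.sort(key=lambda c: (-len(c["members"]), c["center"]))
    return ClusterResult(clusters, cutoff)


def contains_frame(result: ClusterResult, frame: int,
                   which: str = "dominant") -> bool:
    """Whether *frame* belongs to the dominant (largest) cluster."""
    if which != "dominant":
        raise ValueError("only the 'dominant' cluster query is supported")
    if not result.clusters:
        return False
    top = result.clusters[0]
    return frame in top["members"] or frame == top["center"]


def residue_min_distance_trace(ensemble: Ensemble,
                               groupA: Sequence[int],
                               groupB: Sequence[int]) -> np.ndarray:
    """Per-frame minimum distance (Å) over all cross pairs of two atom groups."""
    ia = np.asarray(groupA, dtype=int)
    ib = np.asarray(groupB, dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("atom groups must be non-empty")
    a = ensemble.frames[:, ia, :]
    b = ensemble.frames[:, ib, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    return d.reshape(len(d), -1).min(axis=1)


def salt_bridge_groups(structure: Structure,
                       arg: tuple[str, int], glu: tuple[str, int],
                       arg_names: Sequence[str] = ARG_NITROGENS,
                       glu_names: Sequence[str] = GLU_OXYGENS,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Atom index groups for an Arg–Glu salt-bridge distance trace.

    Defaults to the side-chain nitrogens of the arginine against the
    carboxylate oxygens of the glutamate; the reported distance is the group
    minimum, flagged as such in output metadata by the pipeline.
    """
    ga = select(structure, names=list(arg_names), chains=[arg[0]], resids=[arg[1]])
    gb = select(structure, names=list(glu_names), chains=[glu[0]], resids=[glu[1]])
    missing = []
    if ga.size == 0:
        missing.append(f"{arg[0]}:{arg[1]} atoms {list(arg_names)}")
    if gb.size == 0:
        missing.append(f"{glu[0]}:{glu[1]} atoms {list(glu_names)}")
    if missing:
        raise ValueError("missing salt-bridge atoms: " + "; ".join(missing))
    return ga, gb
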