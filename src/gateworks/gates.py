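"""Two-gate geometric order parameters for MFS-like transporters.

The cytoplasmic gate is tracked by the closest-contact Cα–Cα residue pair of
transmembrane helices 4 and 10, the periplasmic gate by that of helices 1 and 7
(for LacY: E126–C333 and I32–N245). The pair is frozen on a reference structure
and the same pair's Cα–Cα distance is then followed across frames, giving one
(d_cyt, d_peri) point per conformation. An occluded conformation keeps
d_cyt below ~13 Å and d_peri below ~8 Å simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import Ensemble, Structure, select

__all__ = [
    "HelixRange",
    "GatePair",
    "StateThresholds",
    "derive_gate_pair",
    "gate_distance",
    "order_parameter_trace",
    "classify_state",
    "state_space_summary",
    "StateSpaceSummary",
    "mfs_gate_pairs",
    "gate_pair_for",
    "lacy_helix_ranges",
]

STATES = ("occluded", "cytoplasmic_open", "periplasmic_open", "leak")


@dataclass(frozen=True)
class HelixRange:
    """A contiguous residue range (inclusive) on one chain."""

    chain: str
    first_resid: int
    last_resid: int

    def __post_init__(self) -> None:
        if self.first_resid > self.last_resid:
            raise ValueError("first_resid must be <= last_resid")

    @property
    def resids(self) -> range:
        return range(self.first_resid, self.last_resid + 1)


@dataclass(frozen=True)
class GatePair:
    """A frozen pair of Cα anchors defining one gate order parameter."""

    gate: str                    # "cytoplasmic" | "periplasmic"
    resA: tuple[str, int]        # (chain, resid)
    resB: tuple[str, int]
    derived_from: str = ""

    def __post_init__(self) -> None:
        if self.gate not in ("cytoplasmic", "periplasmic"):
            raise ValueError("gate must be 'cytoplasmic' or 'periplasmic'")
        if self.resA == self.resB:
            raise ValueError("gate anchors must differ")


@dataclass(frozen=True)
class StateThresholds:
    """State-classification cutoffs (Å); defaults follow the occluded-state bounds."""

    cyt_occluded_max: float = 13.0
    peri_occluded_max: float = 8.0

    def __post_init__(self) -> None:
        if not (self.cyt_occluded_max > 0 and self.peri_occluded_max > 0):
            raise ValueError("thresholds must be positive")


def _ca_positions(structure: Structure, rng: HelixRange) -> tuple[list[int], np.ndarray]:
    """Resids (sorted) and Cα coordinates found for a helix range."""
    idx = select(structure, names=["CA"], chains=[rng.chain],
                 resids=list(rng.resids))
    pairs = sorted((structure.atoms[i].resid, i) for i in idx)
    resids = [r for r, _ in pairs]
    coords = np.array([structure.atoms[i].xyz for _, i in pairs])
    return resids, coords


def derive_gate_pair(reference: Structure, helixA: HelixRange, helixB: HelixRange,
                     gate: str) -> GatePair:
    """Freeze the closest-contact Cα–Cα pair of two helices on a reference.

    The full cross distance matrix of the two helices' Cα atoms is minimized;
    exact ties are broken by the lower resid on helix A, then on helix B.
    """
    residsA, ca_A = _ca_positions(reference, helixA)
    residsB, ca_B = _ca_positions(reference, helixB)
    for rng, found in ((helixA, residsA), (helixB, residsB)):
        missing = sorted(set(rng.resids) - set(found))
        if not found:
            raise ValueError(
                f"no Cα atoms in range {rng}; missing residues {missing}"
            )
    dm = cdist(ca_A, ca_B)
    best = np.min(dm)
    ia, ib = np.argwhere(dm == best)[0]  # rows/cols sorted by resid -> tie rule
    return GatePair(
        gate=gate,
        resA=(helixA.chain, residsA[ia]),
        resB=(helixB.chain, residsB[ib]),
        derived_from=reference.label,
    )


def _anchor_ca(structure: Structure, anchor: tuple[str, int]) -> np.ndarray:
    chain, resid = anchor
    idx = select(structure, names=["CA"], chains=[chain], resids=[resid])
    if idx.size == 0:
        raise ValueError(f"anchor Cα {chain}:{resid} not present")
    return structure.atoms[int(idx[0])].xyz


def gate_distance(structure: Structure, pair: GatePair) -> float:
    """Euclidean Cα–Cα distance (Å) of a gate pair in one conformation."""
    a = _anchor_ca(structure, pair.resA)
    b = _anchor_ca(structure, pair.resB)
    return float(np.linalg.norm(a - b))


def order_parameter_trace(ensemble: Ensemble, cyt_pair: GatePair,
                          peri_pair: GatePair,
                          thresholds: StateThresholds = StateThresholds(),
                          ) -> pd.DataFrame:
    """Per-frame (d_cyt, d_peri) series with state labels.

    Columns: ``frame``, ``d_cyt``, ``d_peri``, ``state``.
    """
    topo = ensemble.topology
    idx = {}
    for key, pair in (("cA", cyt_pair.resA), ("cB", cyt_pair.resB),
                      ("pA", peri_pair.resA), ("pB", peri_pair.resB)):
        sel = select(topo, names=["CA"], chains=[pair[0]], resids=[pair[1]])
        if sel.size == 0:
            raise ValueError(f"anchor Cα {pair[0]}:{pair[1]} not in topology")
        idx[key] = int(sel[0])
    f = ensemble.frames
    d_cyt = np.linalg.norm(f[:, idx["cA"]] - f[:, idx["cB"]], axis=1)
    d_peri = np.linalg.norm(f[:, idx["pA"]] - f[:, idx["pB"]], axis=1)
    states = [classify_state(c, p, thresholds) for c, p in zip(d_cyt, d_peri)]
    return pd.DataFrame({
        "frame": np.arange(ensemble.n_frames),
        "d_cyt": d_cyt,
        "d_peri": d_peri,
        "state": states,
    })


def classify_state(d_cyt: float, d_peri: float,
                   thr: StateThresholds = StateThresholds()) -> str:
    """Assign one of four quadrant states to a (d_cyt, d_peri) point.

    ``occluded``: both gates below their cutoffs; ``cytoplasmic_open`` /
    ``periplasmic_open``: exactly that gate at or above its cutoff; ``leak``:
    both open — a state a functional alternating-access transporter must avoid.
    """
    if d_cyt < 0 or d_peri < 0:
        raise ValueError("distances must be non-negative")
    cyt_open = d_cyt >= thr.cyt_occluded_max
    peri_open = d_peri >= thr.peri_occluded_max
    if cyt_open and peri_open:
        return "leak"
    if cyt_open:
        return "cytoplasmic_open"
    if peri_open:
        return "periplasmic_open"
    return "occluded"


@dataclass
class StateSpaceSummary:
    """Occupancy summary of labeled order-parameter series."""

    boxes: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    histogram: np.ndarray
    cyt_edges: np.ndarray
    peri_edges: np.ndarray


def state_space_summary(traces: Mapping[str, pd.DataFrame | np.ndarray],
                        bins: int = 20) -> StateSpaceSummary:
    """Min/max box per labeled series plus a pooled 2D histogram of all frames."""
    if not traces:
        raise ValueError("need at least one series")
    boxes = {}
    pooled = []
    for label, tr in traces.items():
        if isinstance(tr, pd.DataFrame):
            pts = tr[["d_cyt", "d_peri"]].to_numpy()
        else:
            pts = np.asarray(tr, dtype=float).reshape(-1, 2)
        boxes[label] = (
            (float(pts[:, 0].min()), float(pts[:, 0].max())),
            (float(pts[:, 1].min()), float(pts[:, 1].max())),
        )
        pooled.append(pts)
    allpts = np.vstack(pooled)
    hist, cyt_edges, peri_edges = np.histogram2d(
        allpts[:, 0], allpts[:, 1], bins=bins)
    return StateSpaceSummary(boxes, hist, cyt_edges, peri_edges)


# ---------------------------------------------------------------------------
# bundled reference tables
# ---------------------------------------------------------------------------

def mfs_gate_pairs() -> pd.DataFrame:
    """Closest-contact gate residue pairs for twelve MFS transporters."""
    with resources.files("gateworks.data").joinpath("mfs_gate_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def gate_pair_for(transporter: str, gate: str, chain: str = "A") -> GatePair:
    """Gate pair for a named transporter from the bundled table.

    The bundled table carries residue numbers only; ``chain`` defaults to the
    first protein chain of typical single-chain deposits.
    """
    df = mfs_gate_pairs()
    row = df[(df.transporter == transporter) & (df.gate == gate)]
    if row.empty:
        raise KeyError(f"no bundled {gate} gate pair for {transporter!r}")
    r = row.iloc[0]
    return GatePair(gate=gate, resA=(chain, int(r.resid_a)),
                    resB=(chain, int(r.resid_b)), derived_from=transporter)


def lacy_helix_ranges() -> dict[str, HelixRange]:
    """Reconstructed LacY TM helix ranges (approximate, overridable)."""
    with resources.files("gateworks.data").joinpath("lacy_helices.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return {
        r.helix: HelixRange(r.chain, int(r.first_resid), int(r.last_resid))
        for r in df.itertuples()
    }
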