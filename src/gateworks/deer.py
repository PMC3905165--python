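"""DEER spin–spin distance distributions by rotamer-library convolution.

A weighted library of spin-label rotamers is rigidly attached to the backbone
frame (N, Cα, C) of each labeled residue, rotamers clashing with the protein
are discarded (nearest heavy-atom approach below the cutoff, 2 Å by default),
and the weighted distances between all surviving rotamer pairs of the two
sites are histogrammed into a normalized distance distribution. Ensembles are
averaged frame by frame with equal weights, which convolves label flexibility
with the conformational spread of the structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structio import Ensemble, Structure, select
from .synthetic import RotamerLibrary

__all__ = [
    "LabelSite",
    "PlacedRotamers",
    "DistanceDistribution",
    "default_bins",
    "attach_rotamers",
    "clash_filter",
    "site_excluded_indices",
    "pair_distribution",
    "ensemble_distribution",
]

logger = logging.getLogger(__name__)

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class LabelSite:
    """A spin-labeled residue and its steric clash cutoff (Å)."""

    chain: str
    resid: int
    clash_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not self.clash_cutoff > 0:
            raise ValueError("clash_cutoff must be positive")


@dataclass
class PlacedRotamers:
    """Rotamers expressed in the structure frame with renormalized weights."""

    site: LabelSite
    rotamer_coords: np.ndarray   # (n_rot, n_atoms, 3)
    weights: np.ndarray          # sum to 1 when non-empty
    spin_positions: np.ndarray   # (n_rot, 3)

    @property
    def empty(self) -> bool:
        return len(self.weights) == 0


@dataclass
class DistanceDistribution:
    """Binned probability over spin–spin distance (Å)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    empty: bool = False   # no surviving rotamer pair anywhere

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("need len(probabilities) == len(bin_edges) - 1")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.probabilities))


def default_bins() -> np.ndarray:
    """0–80 Å in 1 Å bins, the usual DEER display range."""
    return np.arange(0.0, 81.0, 1.0)


def _site_frame(structure: Structure, site: LabelSite,
                anchor_names: tuple[str, str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame (origin at Cα) from the N, Cα, C anchors."""
    pos = {}
    for name in anchor_names:
        idx = select(structure, names=[name], chains=[site.chain],
                     resids=[site.resid])
        if idx.size == 0:
            raise ValueError(
                f"site {site.chain}:{site.resid} lacks anchor atom {name}")
        pos[name] = structure.atoms[int(idx[0])].xyz
    n, ca, c = (pos[a] for a in anchor_names)
    e1 = n - ca
    e1 = e1 / np.linalg.norm(e1)
    v = c - ca
    e3 = np.cross(e1, v)
    nrm = np.linalg.norm(e3)
    if nrm < 1e-9:
        raise ValueError(
            f"site {site.chain}:{site.resid}: collinear anchor atoms")
    e3 = e3 / nrm
    e2 = np.cross(e3, e1)
    return ca, np.column_stack([e1, e2, e3])


def attach_rotamers(structure: Structure, site: LabelSite,
                    library: RotamerLibrary) -> PlacedRotamers:
    """Rigid-body transform of the library onto the site's backbone frame."""
    origin, R = _site_frame(structure, site, library.anchor_names)
    local = library.coords                     # (n_rot, n_atoms, 3)
    coords = origin + local @ R.T
    ri = [library.atom_names.index(n) for n in library.reporter_names]
    spins = 0.5 * (coords[:, ri[0], :] + coords[:, ri[1], :])
    return PlacedRotamers(site, coords, library.weights.copy(), spins)


def site_excluded_indices(structure: Structure, site: LabelSite) -> np.ndarray:
    """All atoms of the labeled residue, excluded from clash tests.

    The site is conceptually mutated to the label: its side chain is replaced
    and the label linker necessarily passes its own backbone, so the whole
    residue is ignored (a superset of the required side-chain exclusion).
    """
    return select(structure, chains=[site.chain], resids=[site.resid])


def clash_filter(placed: PlacedRotamers, structure: Structure,
                 excluded: np.ndarray | None = None) -> PlacedRotamers:
    """Drop rotamers whose atoms approach a protein heavy atom below the cutoff.

    ``excluded`` holds protein atom indices ignored in the test; it defaults to
    (and must at least contain) the labeled residue's own side-chain atoms.
    Hydrogens are ignored. Surviving weights are renormalized; a fully clashed
    site is returned as a flagged empty result rather than an error.
    """
    if excluded is None:
        excluded = site_excluded_indices(structure, placed.site)
    excluded_set = set(int(i) for i in np.asarray(excluded).ravel())
    keep_atoms = [i for i, a in enumerate(structure.atoms)
                  if a.element != "H" and i not in excluded_set]
    if not keep_atoms or placed.empty:
        return placed
    tree = cKDTree(structure.coords[keep_atoms])
    cutoff = placed.site.clash_cutoff
    n_rot, n_atoms, _ = placed.rotamer_coords.shape
    d, _ = tree.query(placed.rotamer_coords.reshape(-1, 3), k=1)
    nearest = d.reshape(n_rot, n_atoms).min(axis=1)
    survive = nearest >= cutoff  # a clash is an approach strictly below cutoff
    if not np.any(survive):
        return PlacedRotamers(placed.site,
                              placed.rotamer_coords[:0],
                              placed.weights[:0],
                              placed.spin_positions[:0])
    w = placed.weights[survive]
    return PlacedRotamers(placed.site,
                          placed.rotamer_coords[survive],
                          w / w.sum(),
                          placed.spin_positions[survive])


def pair_distribution(placedA: PlacedRotamers, placedB: PlacedRotamers,
                      bin_edges: np.ndarray | None = None) -> DistanceDistribution:
    """Weighted histogram of all spin–spin distances between two sites.

    Pair weights are independent products w_A·w_B. An empty site yields an
    all-zero flagged distribution; otherwise the total mass is normalized to 1.
    """
    edges = default_bins() if bin_edges is None else np.asarray(bin_edges, float)
    if placedA.empty or placedB.empty:
        return DistanceDistribution(edges, np.zeros(len(edges) - 1), empty=True)
    d = cdist(placedA.spin_positions, placedB.spin_positions).ravel()
    w = np.outer(placedA.weights, placedB.weights).ravel()
    hist, _ = np.histogram(d, bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        logger.warning("pair_distribution: all %d distances outside bins", d.size)
        return DistanceDistribution(edges, hist, empty=True)
    return DistanceDistribution(edges, hist / total)


def ensemble_distribution(ensemble: Ensemble, siteA: LabelSite, siteB: LabelSite,
                          library: RotamerLibrary,
                          bin_edges: np.ndarray | None = None,
                          stride: int = 1,
                          apply_clash_filter: bool = True) -> DistanceDistribution:
    """Equal-weight average of per-frame distributions over an ensemble.

    Frames in which either site loses all rotamers to clashes are skipped and
    counted in the log; if every frame is empty the result is flagged empty.
    """
    edges = default_bins() if bin_edges is None else np.asarray(bin_edges, float)
    acc = np.zeros(len(edges) - 1)
    n_used = n_skipped = 0
    for f in range(0, ensemble.n_frames, stride):
        frame = ensemble.frame_structure(f)
        pa = attach_rotamers(frame, siteA, library)
        pb = attach_rotamers(frame, siteB, library)
        if apply_clash_filter:
            pa = clash_filter(pa, frame)
            pb = clash_filter(pb, frame)
        dist = pair_distribution(pa, pb, edges)
        if dist.empty:
            n_skipped += 1
            continue
        acc += dist.probabilities
        n_used += 1
    if n_skipped:
        logger.info("ensemble_distribution: skipped %d empty frames", n_skipped)
    if n_used == 0:
        return DistanceDistribution(edges, acc, empty=True)
    return DistanceDistribution(edges, acc / n_used)
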