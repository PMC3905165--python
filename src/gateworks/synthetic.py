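"""Synthetic membrane-protein-like fixtures.

The generators emulate the geometric features the analyses rely on, not the
physics: a two-domain helical bundle with independently tunable cytoplasmic and
periplasmic gate openings, linear transition ensembles with Gaussian noise, a
toy Brownian soft-ratchet sampler driven by an RMSD progress variable, small
weighted spin-label rotamer libraries, and Poisson-sampled cavity waters.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structio import Atom, Ensemble, Structure, StructureError

__all__ = [
    "BundleSpec",
    "SoftRatchetConfig",
    "RotamerLibrary",
    "make_bundle",
    "bundle_anchors",
    "make_transition",
    "soft_ratchet_sample",
    "make_rotamer_library",
    "fill_cavity_waters",
]

#: Maximum outward displacement (Å) of a fully open gate's helix ends.
MAX_SPLAY = 8.0

# ideal alpha-helix geometry
_HELIX_RADIUS = 2.3      # Å, Calpha helical radius
_TWIST = np.deg2rad(100.0)  # per residue


@dataclass
class BundleSpec:
    """Parameters of the synthetic two-domain helix bundle.

    ``gate_cyt`` and ``gate_peri`` are opening fractions in [0, 1]: 0 leaves the
    corresponding face packed (occluded geometry), 1 splays the two domains
    apart by ``max_splay`` each at that face.
    """

    n_helices_per_domain: int = 6
    helix_length: int = 20          # residues
    rise_per_residue: float = 1.5   # Å
    bundle_radius: float = 9.0      # Å
    gate_cyt: float = 0.0
    gate_peri: float = 0.0
    max_splay: float = MAX_SPLAY    # Å
    taper: float = 5.0              # Å inward pinch of helix termini (steric gates)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gate_cyt <= 1.0 and 0.0 <= self.gate_peri <= 1.0):
            raise ValueError("gate opening fractions must lie in [0, 1]")
        if self.n_helices_per_domain < 2:
            raise ValueError("need at least 2 helices per domain")


@dataclass
class SoftRatchetConfig:
    """Toy soft-ratchet sampler settings.

    ``delta_phi`` is the softness scale of the acceptance rule
    ``p = exp(-delta/delta_phi)`` for steps that increase the RMSD progress
    variable; 1e-4 Å behaves as a soft ratchet and 1e-6 Å as a nearly hard one.
    """

    delta_phi: float = 1e-4   # Å
    step_sigma: float = 0.05  # Å per coordinate per step
    max_steps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.delta_phi > 0 and self.step_sigma > 0):
            raise ValueError("delta_phi and step_sigma must be positive")


@dataclass
class RotamerLibrary:
    """Discrete weighted spin-label rotamers in a canonical side-chain frame.

    ``anchor_names`` are the three backbone atoms that define the attachment
    frame; the spin position of each rotamer is the midpoint of the two
    ``reporter_names`` atoms.
    """

    rotamers: list[dict]               # {"local_coords": (n_atoms,3), "weight": float}
    atom_names: list[str]
    anchor_names: tuple[str, str, str] = ("N", "CA", "C")
    reporter_names: tuple[str, str] = ("N1", "O1")

    def __post_init__(self) -> None:
        w = np.array([r["weight"] for r in self.rotamers], dtype=float)
        if len(w) == 0 or np.any(w <= 0):
            raise ValueError("rotamer weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("rotamer weights must sum to 1")
        for r in self.rotamers:
            r["local_coords"] = np.asarray(r["local_coords"], dtype=float)
            if r["local_coords"].shape != (len(self.atom_names), 3):
                raise ValueError("every rotamer must share atom_names")
        if not set(self.reporter_names) <= set(self.atom_names):
            raise ValueError("reporter atoms missing from atom_names")

    @property
    def weights(self) -> np.ndarray:
        return np.array([r["weight"] for r in self.rotamers], dtype=float)

    @property
    def coords(self) -> np.ndarray:
        """(n_rotamers, n_atoms, 3) stack of local coordinates."""
        return np.stack([r["local_coords"] for r in self.rotamers])


# ---------------------------------------------------------------------------
# helix bundle
# ---------------------------------------------------------------------------

def _helix_curve(t: np.ndarray, axis_xy: np.ndarray, phase: float,
                 rise: float, length: int) -> np.ndarray:
    """Points on an ideal helix; *t* is the (fractional) residue index."""
    z = (t - (length - 1) / 2.0) * rise
    ang = phase + t * _TWIST
    x = axis_xy[0] + _HELIX_RADIUS * np.cos(ang)
    y = axis_xy[1] + _HELIX_RADIUS * np.sin(ang)
    return np.column_stack([x, y, z])


def _splay(z: np.ndarray, gate_cyt: float, gate_peri: float,
           half_len: float, max_splay: float) -> np.ndarray:
    """Outward displacement magnitude as a function of z (0 at the midplane)."""
    s = np.zeros_like(z)
    below = z < 0
    s[below] = gate_cyt * max_splay * np.minimum(-z[below] / half_len, 1.0)
    above = ~below
    s[above] = gate_peri * max_splay * np.minimum(z[above] / half_len, 1.0)
    return s


def make_bundle(spec: BundleSpec) -> Structure:
    """Build the two-domain helix bundle.

    Domain A (chain A) occupies azimuth (-90°, 90°), domain B (chain B) the
    opposite half. The helices taper inward toward both termini (``taper``), so
    with both gate fractions at zero the central cavity is sterically pinched
    shut at the two faces — the occluded geometry. Gate opening splays domain A
    along +x and domain B along -x, with the displacement ramping from zero at
    the membrane midplane (z = 0) to its maximum at the helix termini — so the
    cytoplasmic (z < 0) and periplasmic (z > 0) faces open independently. Gate
    anchor residues (the terminal Cα of the interface helix of each domain) are
    recorded in the structure label.
    """
    n, L = spec.n_helices_per_domain, spec.helix_length
    half_len = (L - 1) * spec.rise_per_residue / 2.0
    atoms: list[Atom] = []
    for dom, (chain, theta0, splay_dir) in enumerate(
        [("A", -np.pi / 2, np.array([1.0, 0.0, 0.0])),
         ("B", np.pi / 2, np.array([-1.0, 0.0, 0.0]))]
    ):
        for h in range(n):
            theta = theta0 + np.pi * (h + 0.5) / n
            axis_xy = spec.bundle_radius * np.array([np.cos(theta), np.sin(theta)])
            phase = theta + np.pi  # Calpha ring roughly facing the bundle axis
            for r in range(L):
                resid = h * L + r + 1
                t = float(r)
                # backbone atoms sampled along the helix curve; O and CB stick out
                pos = {
                    "N": _helix_curve(np.array([t - 0.35]), axis_xy, phase,
                                      spec.rise_per_residue, L)[0],
                    "CA": _helix_curve(np.array([t]), axis_xy, phase,
                                       spec.rise_per_residue, L)[0],
                    "C": _helix_curve(np.array([t + 0.35]), axis_xy, phase,
                                      spec.rise_per_residue, L)[0],
                }
                ca = pos["CA"]
                out = ca - np.array([axis_xy[0], axis_xy[1], ca[2]])
                out = out / np.linalg.norm(out)
                pos["O"] = pos["C"] + 1.23 * out
                pos["CB"] = ca + 1.53 * out
                u_axis = np.array([np.cos(theta), np.sin(theta), 0.0])
                for name, xyz in pos.items():
                    z = np.array([xyz[2]])
                    pinch = spec.taper * min(abs(xyz[2]) / half_len, 1.0)
                    s = _splay(z, spec.gate_cyt, spec.gate_peri, half_len,
                               spec.max_splay)[0]
                    xyz = xyz - pinch * u_axis + s * splay_dir
                    el = name[0]
                    atoms.append(Atom(name=name, element=el, resname="ALA",
                                      resid=resid, chain=chain, xyz=xyz,
                                      vdw_radius={"N": 1.55, "O": 1.52}.get(el, 1.70)))
    anchors = bundle_anchors(spec)
    label = (
        f"bundle gate_cyt={spec.gate_cyt:g} gate_peri={spec.gate_peri:g} "
        f"cyt_anchors={anchors['cytoplasmic'][0][0]}:{anchors['cytoplasmic'][0][1]}"
        f"|{anchors['cytoplasmic'][1][0]}:{anchors['cytoplasmic'][1][1]} "
        f"peri_anchors={anchors['periplasmic'][0][0]}:{anchors['periplasmic'][0][1]}"
        f"|{anchors['periplasmic'][1][0]}:{anchors['periplasmic'][1][1]}"
    )
    return Structure(atoms, label=label)


def bundle_anchors(spec: BundleSpec) -> dict[str, tuple[tuple[str, int], tuple[str, int]]]:
    """Gate anchor residues of :func:`make_bundle` output.

    One designated interface helix per domain contributes its terminal residue
    on each face: the bottom (z < 0) terminus anchors the cytoplasmic gate, the
    top terminus the periplasmic gate.
    """
    n, L = spec.n_helices_per_domain, spec.helix_length
    # interface helices: last helix of domain A and first of domain B sit on
    # either side of the +y interface
    a_first = (n - 1) * L + 1   # chain A, helix n-1
    b_first = 1                 # chain B, helix 0
    return {
        "cytoplasmic": (("A", a_first), ("B", b_first)),
        "periplasmic": (("A", a_first + L - 1), ("B", b_first + L - 1)),
    }


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def _check_shared_topology(a: Structure, b: Structure) -> None:
    if len(a) != len(b) or any(
        (x.chain, x.resid, x.name) != (y.chain, y.resid, y.name)
        for x, y in zip(a.atoms, b.atoms)
    ):
        raise StructureError("start and end structures do not share a topology")


def make_transition(start: Structure, end: Structure, n_frames: int,
                    noise_sigma: float = 0.0, seed: int = 0) -> Ensemble:
    """Linear coordinate interpolation from *start* to *end* plus isotropic noise."""
    _check_shared_topology(start, end)
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    a, b = start.coords, end.coords
    lam = np.linspace(0.0, 1.0, n_frames)
    frames = a[None] * (1 - lam)[:, None, None] + b[None] * lam[:, None, None]
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    return Ensemble(start, frames)


def _fit_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Best-fit (rotation + translation) RMSD between two coordinate sets."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    _, rssd = Rotation.align_vectors(tc, mc)
    return float(rssd / np.sqrt(len(mobile)))


def soft_ratchet_sample(start: Structure, target: Structure,
                        cfg: SoftRatchetConfig,
                        progress_atoms: Sequence[int]) -> Ensemble:
    """Brownian sampler ratcheted toward *target* along an RMSD progress variable.

    Proposals perturb every coordinate with Gaussian noise of ``step_sigma``;
    the progress variable φ is the best-fit RMSD of ``progress_atoms`` to the
    target, refit at every accepted step. A proposal with δ = φ_new − φ_old ≤ 0
    is always accepted, otherwise with probability exp(−δ/delta_phi), so φ is
    non-increasing in expectation. Sampling stops at ``max_steps`` proposals or
    once φ < 0.5 Å. Accepted frames (including the start) are returned.
    """
    _check_shared_topology(start, target)
    idx = np.asarray(progress_atoms, dtype=int)
    if idx.size == 0:
        raise ValueError("progress_atoms must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    coords = start.coords
    tgt = target.coords[idx]
    phi = _fit_rmsd(coords[idx], tgt)
    frames = [coords.copy()]
    for _ in range(cfg.max_steps):
        if phi < 0.5:
            break
        prop = coords + rng.normal(0.0, cfg.step_sigma, size=coords.shape)
        phi_new = _fit_rmsd(prop[idx], tgt)
        delta = phi_new - phi
        if delta <= 0 or rng.random() < np.exp(-delta / cfg.delta_phi):
            coords, phi = prop, phi_new
            frames.append(coords.copy())
    return Ensemble(start, np.stack(frames))


# ---------------------------------------------------------------------------
# rotamer libraries and waters
# ---------------------------------------------------------------------------

def make_rotamer_library(n_rotamers: int, arm_length: float = 6.0,
                         seed: int = 0) -> RotamerLibrary:
    """Random articulated-arm rotamers with Dirichlet weights.

    Each rotamer is a short chain of five pseudo-atoms leaving the anchor frame
    origin, mimicking a flexible nitroxide-label linker; the last two atoms are
    the reporter pair whose midpoint serves as the spin position.
    """
    if n_rotamers < 1:
        raise ValueError("n_rotamers must be >= 1")
    rng = np.random.default_rng(seed)
    atom_names = ["S1", "C1", "C2", "N1", "O1"]
    seg = arm_length / (len(atom_names) - 1)
    rotamers = []
    weights = rng.dirichlet(np.ones(n_rotamers))
    for w in weights:
        # grow roughly along the Cβ direction of the backbone frame (the
        # bisector opposite N and C), as a real side-chain label would
        direction = np.array([-0.35, -0.94, 0.0])
        direction /= np.linalg.norm(direction)
        pos = np.zeros(3)
        coords = []
        for _ in atom_names:
            coords.append(pos.copy())
            kick = rng.normal(0.0, 0.5, size=3)
            direction = direction + kick
            direction /= np.linalg.norm(direction)
            pos = pos + seg * direction
        rotamers.append({"local_coords": np.array(coords), "weight": float(w)})
    return RotamerLibrary(rotamers, atom_names)


def fill_cavity_waters(structure: Structure | None,
                       region: tuple[Sequence[float], Sequence[float]],
                       number_density: float, seed: int = 0,
                       exclusion_radius: float = 2.6) -> np.ndarray:
    """Poisson-sample water-oxygen positions in an axis-aligned box.

    Candidate positions within ``exclusion_radius`` (Å, water–heavy-atom
    contact) of any protein atom are rejected, so the realized count follows
    density × accessible volume. Returns an (n, 3) array of positions.
    """
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("region box is degenerate")
    if number_density < 0:
        raise ValueError("number_density must be >= 0")
    rng = np.random.default_rng(seed)
    volume = float(np.prod(hi - lo))
    n = rng.poisson(number_density * volume)
    if n == 0:
        return np.empty((0, 3))
    pts = rng.uniform(lo, hi, size=(n, 3))
    if structure is not None:
        tree = cKDTree(structure.coords)
        d, _ = tree.query(pts, k=1)
        pts = pts[d >= exclusion_radius]
    return pts
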