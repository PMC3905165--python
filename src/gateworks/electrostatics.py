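"""Implicit-membrane Poisson–Boltzmann electrostatics of a solvated ion.

The position-resolved electrostatic free energy of a Born ion (a charged
spherical cavity of radius *a*) in a protein/membrane/water dielectric
environment is computed as

    W_elec(r) = G(protein + ion at r) − G(protein) − G(ion in bulk),

where each G is a reaction-field energy from a two-solve scheme (heterogeneous
dielectric minus uniform vacuum on identical grids), so grid self-energies
cancel by construction. The linearized Poisson–Boltzmann equation

    ∇·(ε ∇φ) − κ̄² φ = −4π k_e ρ

is discretized with a 7-point finite-difference stencil, harmonic averaging of
ε across cell faces (sub-sampled along edges that cross a dielectric
boundary), trilinear charge spreading and Debye–Hückel outer boundary
conditions, and solved by preconditioned conjugate gradients with a three-level
focusing schedule. Units: Å, elementary charges, kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.constants as const
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import LinearOperator, cg
from scipy.spatial import cKDTree

from .structio import MembraneFrame, Structure

__all__ = [
    "COULOMB_KJ",
    "KCAL_TO_KJ",
    "BornIon",
    "DielectricModel",
    "FocusingSchedule",
    "BornLandscape",
    "DielectricAssigner",
    "born_radius",
    "proton_born_ion",
    "debye_length",
    "build_dielectric_map",
    "cavity_points",
    "solve_lpb",
    "potential_at",
    "charge_energy",
    "reaction_field_energy",
    "born_landscape",
    "LPBConvergenceError",
]

#: e²·N_A / (4π ε₀) in kJ·Å·mol⁻¹·e⁻² — Coulomb constant in working units.
COULOMB_KJ = (const.e ** 2 * const.Avogadro
              / (4.0 * math.pi * const.epsilon_0) * 1e10 / 1e3)

KCAL_TO_KJ = 4.184


class LPBConvergenceError(RuntimeError):
    """Raised when the iterative LPB solve fails to reach the residual target."""

    def __init__(self, residual: float, maxiter: int):
        super().__init__(
            f"LPB solver did not converge within {maxiter} iterations "
            f"(relative residual {residual:.3e})"
        )
        self.residual = residual


@dataclass(frozen=True)
class BornIon:
    """A Born ion: point charge q (e) in a spherical cavity of radius a (Å)."""

    charge: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("Born radius must be positive")


def born_radius(q: float, dG_solv_kcal: float, eps_exterior: float = 80.0) -> float:
    """Effective Born radius (Å) from a hydration free energy (kcal/mol).

    Inverts the Born solvation expression: a = −166 Å·kcal/mol · q² / ΔG*_solv
    · (1 − 1/ε_ext). The hydration free energy must be negative (favorable).
    """
    if q == 0:
        raise ValueError("charge must be non-zero")
    if dG_solv_kcal >= 0:
        raise ValueError("hydration free energy must be negative (unphysical input)")
    if eps_exterior <= 1:
        raise ValueError("exterior dielectric must exceed 1")
    return -166.0 * q * q / dG_solv_kcal * (1.0 - 1.0 / eps_exterior)


def proton_born_ion(dG_solv_kcal: float = -110.4, eps_exterior: float = 80.0) -> BornIon:
    """Born model of a solvated proton from the oxonium hydration free energy."""
    return BornIon(charge=1.0, radius=born_radius(1.0, dG_solv_kcal, eps_exterior))


@dataclass(frozen=True)
class DielectricModel:
    """Dielectric environment: water, protein interior, implicit membrane slab.

    The membrane is a hydrophobic core of ``core_thickness`` centered on the
    midplane flanked by two headgroup layers of ``headgroup_thickness`` each.
    """

    eps_water: float = 80.0
    eps_protein: float = 10.0
    eps_core: float = 2.0
    eps_headgroup: float = 20.0
    core_thickness: float = 33.5       # Å
    headgroup_thickness: float = 6.5   # Å
    ionic_strength: float = 0.1        # mol/L
    temperature: float = 298.15        # K

    def __post_init__(self) -> None:
        for eps in (self.eps_water, self.eps_protein, self.eps_core,
                    self.eps_headgroup):
            if eps < 1:
                raise ValueError("dielectric constants must be >= 1")
        if self.core_thickness <= 0 or self.headgroup_thickness <= 0:
            raise ValueError("membrane thicknesses must be positive")


def debye_length(model: DielectricModel) -> float:
    """Debye screening length (Å) in the bulk-water region; inf at zero salt."""
    if model.ionic_strength <= 0:
        return math.inf
    lam_sq = (model.eps_water * const.epsilon_0 * const.k
              * model.temperature
              / (2.0 * const.Avogadro * const.e ** 2
                 * model.ionic_strength * 1e3))
    return math.sqrt(lam_sq) * 1e10


@dataclass(frozen=True)
class FocusingSchedule:
    """Ordered focusing levels: (cubic box edge in Å, grid points per axis)."""

    levels: tuple[tuple[float, int], ...] = ((120.0, 65), (60.0, 65), (30.0, 65))

    def __post_init__(self) -> None:
        edges = [e for e, _ in self.levels]
        if any(b >= a for a, b in zip(edges, edges[1:])):
            raise ValueError("box edges must strictly decrease")
        if any(n % 2 == 0 or n < 5 for _, n in self.levels):
            raise ValueError("grid points per axis must be odd and >= 5")

    @classmethod
    def desk_scale(cls) -> "FocusingSchedule":
        return cls()

    @classmethod
    def full_scale(cls) -> "FocusingSchedule":
        return cls(((250.0, 129), (100.0, 129), (50.0, 129)))


@dataclass
class BornLandscape:
    """Electrostatic free energy of the ion per probe position (kJ/mol)."""

    points: np.ndarray
    W_elec: np.ndarray
    flags: np.ndarray  # True where the point sits in an ε < ε_water voxel

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.W_elec = np.asarray(self.W_elec, dtype=float)
        if len(self.points) != len(self.W_elec):
            raise ValueError("points and W_elec must have equal length")
        if not np.all(np.isfinite(self.W_elec)):
            raise ValueError("W_elec must be finite")


# ---------------------------------------------------------------------------
# dielectric environment
# ---------------------------------------------------------------------------

class DielectricAssigner:
    """Maps points to dielectric and screening values.

    Assignment precedence (highest first): ion cavity (ε = 1) >
    solvent-accessible interior (ε = ε_water) > protein (ε = ε_protein) >
    membrane headgroup > membrane core > bulk water. Mobile-ion screening κ̄²
    is non-zero only in ε = ε_water regions (ion exclusion elsewhere).
    """

    def __init__(self, model: DielectricModel,
                 structure: Structure | None = None,
                 membrane: MembraneFrame | None = MembraneFrame(),
                 solvent_points: np.ndarray | None = None,
                 solvent_radius: float = 1.4,
                 probe: float = 1.4,
                 ion_center: Sequence[float] | None = None,
                 ion_radius: float = 0.0,
                 uniform_eps: float | None = None):
        self.model = model
        self.membrane = membrane
        self.probe = probe
        self.solvent_radius = solvent_radius
        self.uniform_eps = uniform_eps
        self.ion_center = (None if ion_center is None
                           else np.asarray(ion_center, dtype=float))
        self.ion_radius = float(ion_radius)
        self._atom_tree = None
        self._vdw = None
        if structure is not None:
            self._atom_tree = cKDTree(structure.coords)
            self._vdw = structure.vdw_radii
            self._max_reach = float(self._vdw.max()) + probe
        self._solv_tree = (None if solvent_points is None or len(solvent_points) == 0
                           else cKDTree(np.asarray(solvent_points, dtype=float)))
        self.lambda_debye = math.inf if uniform_eps is not None else debye_length(model)
        self.eps_bulk = uniform_eps if uniform_eps is not None else model.eps_water

    @classmethod
    def vacuum(cls, model: DielectricModel | None = None) -> "DielectricAssigner":
        """Uniform ε = 1, no screening — the reference of the two-solve scheme."""
        return cls(model or DielectricModel(), membrane=None, uniform_eps=1.0)

    def _membrane_depth(self, pts: np.ndarray) -> np.ndarray:
        ax = self.membrane.axis_index
        return np.abs(pts[:, ax] - self.membrane.midplane_offset)

    def _in_protein(self, pts: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(pts), dtype=bool)
        hits = self._atom_tree.query_ball_point(pts, self._max_reach)
        coords = self._atom_tree.data
        for i, idx in enumerate(hits):
            if not idx:
                continue
            idx = np.asarray(idx)
            d = np.linalg.norm(coords[idx] - pts[i], axis=1)
            if np.any(d <= self._vdw[idx] + self.probe):
                mask[i] = True
        return mask

    def eps_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.uniform_eps is not None:
            eps = np.full(len(pts), float(self.uniform_eps))
        else:
            m = self.model
            eps = np.full(len(pts), m.eps_water)
            if self.membrane is not None:
                depth = self._membrane_depth(pts)
                half_core = m.core_thickness / 2.0
                eps[depth < half_core] = m.eps_core
                head = (depth >= half_core) & (
                    depth < half_core + m.headgroup_thickness)
                eps[head] = m.eps_headgroup
            if self._atom_tree is not None:
                eps[self._in_protein(pts)] = m.eps_protein
            if self._solv_tree is not None:
                d, _ = self._solv_tree.query(pts, k=1)
                eps[d <= self.solvent_radius] = m.eps_water
        if self.ion_center is not None and self.ion_radius > 0:
            d = np.linalg.norm(pts - self.ion_center, axis=1)
            eps[d < self.ion_radius] = 1.0
        return eps

    def kappa2_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.uniform_eps is not None or not math.isfinite(self.lambda_debye):
            return np.zeros(len(pts))
        eps = self.eps_at(pts)
        k2 = np.zeros(len(pts))
        solvent = eps == self.model.eps_water
        k2[solvent] = self.model.eps_water / self.lambda_debye ** 2
        return k2

    def with_ion(self, center: Sequence[float], radius: float) -> "DielectricAssigner":
        """A copy of this environment with an ion cavity carved at *center*."""
        new = DielectricAssigner.__new__(DielectricAssigner)
        new.__dict__.update(self.__dict__)
        new.ion_center = np.asarray(center, dtype=float)
        new.ion_radius = float(radius)
        return new


def build_dielectric_map(structure: Structure | None, model: DielectricModel,
                         origin: Sequence[float], spacing: float,
                         shape: tuple[int, int, int],
                         solvent_points: np.ndarray | None = None,
                         membrane: MembraneFrame | None = MembraneFrame(),
                         ) -> tuple["ScalarField3D", "ScalarField3D", DielectricAssigner]:
    """Node-centered ε and κ̄² fields on a regular grid, plus the assigner.

    Raises if the grid does not cover the structure with a probe-width margin.
    """
    from .pathways import ScalarField3D

    origin = np.asarray(origin, dtype=float)
    hi = origin + spacing * (np.array(shape) - 1)
    if structure is not None:
        c = structure.coords
        need_lo, need_hi = c.min(axis=0) - 1.4, c.max(axis=0) + 1.4
        if np.any(origin > need_lo) or np.any(hi < need_hi):
            raise ValueError(
                f"grid [{origin}, {hi}] too small; structure needs "
                f"[{need_lo}, {need_hi}]"
            )
    assigner = DielectricAssigner(model, structure=structure, membrane=membrane,
                                  solvent_points=solvent_points)
    axes = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    eps = assigner.eps_at(grid).reshape(shape)
    k2 = assigner.kappa2_at(grid).reshape(shape)
    eps_f = ScalarField3D(origin, spacing, eps, semantics="dielectric")
    k2_f = ScalarField3D(origin, spacing, k2, semantics="screening")
    return eps_f, k2_f, assigner


# ---------------------------------------------------------------------------
# cavity points
# ---------------------------------------------------------------------------

def cavity_points(structure: Structure | None,
                  bounds: tuple[Sequence[float], Sequence[float]],
                  spacing: float = 1.0, probe: float = 1.4) -> np.ndarray:
    """Lattice points where a probe sphere fits without touching any atom.

    Points on a regular lattice of ``spacing`` within ``bounds`` are kept when
    the clearance to every atom (center distance minus vdW radius) is at least
    ``probe``. With no structure the full lattice is returned.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("bounds box is degenerate")
    axes = [np.arange(lo[d], hi[d] + 1e-9, spacing) for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if structure is None:
        return pts
    coords = structure.coords
    radii = structure.vdw_radii
    keep = np.ones(len(pts), dtype=bool)
    chunk = 4096
    for i in range(0, len(pts), chunk):
        block = pts[i:i + chunk]
        d = np.linalg.norm(block[:, None, :] - coords[None, :, :], axis=2)
        clearance = (d - radii[None, :]).min(axis=1)
        keep[i:i + chunk] = clearance >= probe
    return pts[keep]


# ---------------------------------------------------------------------------
# FD-LPB solver
# ---------------------------------------------------------------------------

def _face_eps(assigner: DielectricAssigner, axes: list[np.ndarray],
              eps_nodes: np.ndarray, axis: int, n_samples: int) -> np.ndarray:
    """Harmonic-mean ε on faces normal to *axis*.

    Faces whose two endpoint nodes share one ε value take it directly; edges
    that cross a dielectric boundary are sub-sampled at ``n_samples`` interior
    points and averaged harmonically (series combination of the segments).
    """
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    e_lo = eps_nodes[tuple(sl_lo)]
    e_hi = eps_nodes[tuple(sl_hi)]
    face = 2.0 / (1.0 / e_lo + 1.0 / e_hi)
    mixed = e_lo != e_hi
    if np.any(mixed):
        idx = np.argwhere(mixed)
        h = axes[axis][1] - axes[axis][0]
        base = np.stack([axes[0][idx[:, 0]], axes[1][idx[:, 1]],
                         axes[2][idx[:, 2]]], axis=1)
        frac = (np.arange(n_samples) + 0.5) / n_samples
        samples = np.repeat(base, n_samples, axis=0)
        samples[:, axis] += np.tile(frac, len(base)) * h
        eps_s = assigner.eps_at(samples).reshape(len(base), n_samples)
        face[tuple(idx.T)] = 1.0 / np.mean(1.0 / eps_s, axis=1)
    return face


def _spread_charges(charges: Sequence[tuple[float, Sequence[float]]],
                    origin: np.ndarray, spacing: float,
                    shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear assignment of point charges to grid nodes (returns charge, e)."""
    q_grid = np.zeros(shape)
    for q, pos in charges:
        rel = (np.asarray(pos, dtype=float) - origin) / spacing
        base = np.floor(rel).astype(int)
        frac = rel - base
        if np.any(base < 0) or np.any(base + 1 >= np.array(shape)):
            raise ValueError(f"charge at {pos} lies outside the grid")
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((frac[0] if dx else 1 - frac[0])
                         * (frac[1] if dy else 1 - frac[1])
                         * (frac[2] if dz else 1 - frac[2]))
                    q_grid[base[0] + dx, base[1] + dy, base[2] + dz] += q * w
    return q_grid


def _dh_boundary(points: np.ndarray,
                 charges: Sequence[tuple[float, Sequence[float]]],
                 eps_bulk: float, lam: float) -> np.ndarray:
    """Debye–Hückel screened monopole potential of all charges (kJ/mol/e)."""
    phi = np.zeros(len(points))
    for q, pos in charges:
        d = np.linalg.norm(points - np.asarray(pos, dtype=float), axis=1)
        d = np.maximum(d, 1e-6)
        decay = np.exp(-d / lam) if math.isfinite(lam) else 1.0
        phi += COULOMB_KJ * q * decay / (eps_bulk * d)
    return phi


def _solve_level(assigner: DielectricAssigner,
                 charges: Sequence[tuple[float, Sequence[float]]],
                 center: np.ndarray, edge: float, n: int,
                 boundary: Callable[[np.ndarray], np.ndarray],
                 rtol: float, maxiter: int, n_edge_samples: int) -> tuple:
    spacing = edge / (n - 1)
    origin = center - edge / 2.0
    axes = [origin[d] + spacing * np.arange(n) for d in range(3)]
    nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    eps_nodes = assigner.eps_at(nodes.reshape(-1, 3)).reshape(n, n, n)
    k2_nodes = assigner.kappa2_at(nodes.reshape(-1, 3)).reshape(n, n, n)
    faces = [_face_eps(assigner, axes, eps_nodes, ax, n_edge_samples)
             for ax in range(3)]
    q_grid = _spread_charges(charges, origin, spacing, (n, n, n))
    rho = 4.0 * math.pi * COULOMB_KJ * q_grid / spacing ** 3

    # Dirichlet boundary values on the outer shell
    phi = np.zeros((n, n, n))
    shell = np.zeros((n, n, n), dtype=bool)
    shell[0, :, :] = shell[-1, :, :] = True
    shell[:, 0, :] = shell[:, -1, :] = True
    shell[:, :, 0] = shell[:, :, -1] = True
    phi[shell] = boundary(nodes[shell])

    m = n - 2  # interior nodes per axis
    inner = (slice(1, -1),) * 3

    def lap_coeffs():
        """Per-interior-node stencil coefficients from the face ε arrays."""
        fx, fy, fz = faces
        w = {
            "xm": fx[:-1, 1:-1, 1:-1], "xp": fx[1:, 1:-1, 1:-1],
            "ym": fy[1:-1, :-1, 1:-1], "yp": fy[1:-1, 1:, 1:-1],
            "zm": fz[1:-1, 1:-1, :-1], "zp": fz[1:-1, 1:-1, 1:],
        }
        return {k: v / spacing ** 2 for k, v in w.items()}

    w = lap_coeffs()
    diag = (sum(w.values()) + k2_nodes[inner]).ravel()

    def idx3(i, j, k):
        return (i * m + j) * m + k

    rows, cols, vals = [], [], []
    ii, jj, kk = np.meshgrid(np.arange(m), np.arange(m), np.arange(m),
                             indexing="ij")
    flat = idx3(ii, jj, kk).ravel()
    rows.append(flat)
    cols.append(flat)
    vals.append(diag)
    for key, (di, dj, dk) in {
        "xm": (-1, 0, 0), "xp": (1, 0, 0),
        "ym": (0, -1, 0), "yp": (0, 1, 0),
        "zm": (0, 0, -1), "zp": (0, 0, 1),
    }.items():
        ni, nj, nk = ii + di, jj + dj, kk + dk
        inside = ((ni >= 0) & (ni < m) & (nj >= 0) & (nj < m)
                  & (nk >= 0) & (nk < m))
        rows.append(flat[inside.ravel()])
        cols.append(idx3(ni[inside], nj[inside], nk[inside]))
        vals.append(-w[key][inside])
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m ** 3, m ** 3),
    )

    b = rho[inner].copy()
    # boundary neighbors move to the RHS
    b[0, :, :] += w["xm"][0, :, :] * phi[0, 1:-1, 1:-1]
    b[-1, :, :] += w["xp"][-1, :, :] * phi[-1, 1:-1, 1:-1]
    b[:, 0, :] += w["ym"][:, 0, :] * phi[1:-1, 0, 1:-1]
    b[:, -1, :] += w["yp"][:, -1, :] * phi[1:-1, -1, 1:-1]
    b[:, :, 0] += w["zm"][:, :, 0] * phi[1:-1, 1:-1, 0]
    b[:, :, -1] += w["zp"][:, :, -1] * phi[1:-1, 1:-1, -1]
    b = b.ravel()

    if not np.any(b):
        x = np.zeros(m ** 3)
    else:
        d_inv = 1.0 / A.diagonal()
        M = LinearOperator(A.shape, matvec=lambda v: d_inv * v)
        x, info = cg(A, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
        if info != 0:
            res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
            raise LPBConvergenceError(res, maxiter)
    phi[inner] = x.reshape(m, m, m)
    return phi, origin, spacing, axes


def solve_lpb(assigner: DielectricAssigner,
              charges: Sequence[tuple[float, Sequence[float]]],
              schedule: FocusingSchedule = FocusingSchedule(),
              center: Sequence[float] | None = None,
              rtol: float = 1e-6, maxiter: int = 20000,
              n_edge_samples: int = 9) -> "ScalarField3D":
    """Focused FD-LPB solve; returns the finest-level potential (kJ/mol/e).

    The coarsest level takes Debye–Hückel monopole boundary values; each finer
    level takes boundary values interpolated from the previous solution.
    """
    from .pathways import ScalarField3D

    if center is None:
        if charges:
            center = np.mean([np.asarray(p, float) for _, p in charges], axis=0)
        else:
            center = np.zeros(3)
    center = np.asarray(center, dtype=float)

    boundary: Callable[[np.ndarray], np.ndarray] = (
        lambda pts: _dh_boundary(pts, charges, assigner.eps_bulk,
                                 assigner.lambda_debye)
    )
    phi = origin = spacing = axes = None
    for edge, n in schedule.levels:
        phi, origin, spacing, axes = _solve_level(
            assigner, charges, center, edge, n, boundary, rtol, maxiter,
            n_edge_samples)
        interp = RegularGridInterpolator(axes, phi, bounds_error=False,
                                         fill_value=None)
        boundary = lambda pts, _f=interp: _f(pts)  # noqa: E731
    field = ScalarField3D(origin, spacing, phi, semantics="potential")
    return field


def potential_at(field: "ScalarField3D", points: np.ndarray) -> np.ndarray:
    """Trilinear sample of a potential field at arbitrary points."""
    shape = field.values.shape
    axes = [field.origin[d] + field.spacing * np.arange(shape[d])
            for d in range(3)]
    interp = RegularGridInterpolator(axes, field.values)
    return interp(np.asarray(points, dtype=float).reshape(-1, 3))


def charge_energy(field: "ScalarField3D",
                  charges: Sequence[tuple[float, Sequence[float]]]) -> float:
    """Grid electrostatic energy ½ Σ q φ(r_q) in kJ/mol."""
    if not charges:
        return 0.0
    qs = np.array([q for q, _ in charges])
    pts = np.array([p for _, p in charges], dtype=float)
    return float(0.5 * np.sum(qs * potential_at(field, pts)))


def reaction_field_energy(assigner: DielectricAssigner,
                          charges: Sequence[tuple[float, Sequence[float]]],
                          schedule: FocusingSchedule = FocusingSchedule(),
                          center: Sequence[float] | None = None,
                          **solver_kw) -> float:
    """Two-solve reaction-field energy (kJ/mol).

    Solves once in the heterogeneous environment and once in uniform vacuum
    (ε = 1, no screening) on identical grids; the difference of ½ Σ q φ terms
    cancels the grid self-energy exactly by construction.
    """
    if not charges:
        return 0.0
    phi_full = solve_lpb(assigner, charges, schedule, center, **solver_kw)
    vac = DielectricAssigner.vacuum(assigner.model)
    phi_vac = solve_lpb(vac, charges, schedule, center, **solver_kw)
    return charge_energy(phi_full, charges) - charge_energy(phi_vac, charges)


def born_landscape(structure: Structure | None, ion: BornIon,
                   model: DielectricModel,
                   schedule: FocusingSchedule = FocusingSchedule(),
                   points: np.ndarray | None = None,
                   membrane: MembraneFrame | None = MembraneFrame(),
                   solvent_points: np.ndarray | None = None,
                   bulk_reference_point: Sequence[float] | None = None,
                   **solver_kw) -> BornLandscape:
    """Position-resolved electrostatic free energy of the ion (kJ/mol).

    For each probe point r: W(r) = G(protein+ion at r) − G(protein) −
    G(ion in bulk). All G terms are reaction-field energies; the protein term
    is evaluated on the same ion-centered grids so that protein self-energies
    cancel, and the bulk ion reference is computed once in a pure-water
    environment. Points lying in ε < ε_water voxels are flagged (desolvation
    regime) but still reported.
    """
    if points is None:
        raise ValueError("probe points are required (e.g. from cavity_points)")
    points = np.asarray(points, dtype=float).reshape(-1, 3)

    env = DielectricAssigner(model, structure=structure, membrane=membrane,
                             solvent_points=solvent_points)
    # bulk reference: ion alone in pure water
    bulk = DielectricAssigner(model, structure=None, membrane=None)
    ref_pos = (np.zeros(3) if bulk_reference_point is None
               else np.asarray(bulk_reference_point, dtype=float))
    g_ion = reaction_field_energy(
        bulk.with_ion(ref_pos, ion.radius), [(ion.charge, ref_pos)],
        schedule, center=ref_pos, **solver_kw)

    prot_charges = ([] if structure is None else
                    [(float(q), xyz) for q, xyz in
                     zip(structure.charges, structure.coords)])

    W = np.empty(len(points))
    flags = env.eps_at(points) < model.eps_water
    for i, r in enumerate(points):
        with_ion = env.with_ion(r, ion.radius)
        g_pi = reaction_field_energy(
            with_ion, prot_charges + [(ion.charge, r)], schedule,
            center=r, **solver_kw)
        g_p = (reaction_field_energy(env, prot_charges, schedule, center=r,
                                     **solver_kw)
               if prot_charges else 0.0)
        W[i] = g_pi - g_p - g_ion
    return BornLandscape(points, W, flags)
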