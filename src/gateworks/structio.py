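"""Structure and ensemble I/O.

Coordinates are in Å throughout. PDB reading/writing is delegated to :mod:`gemmi`;
PQR files (the whitespace dialect written by pdb2pqr) are read through MDAnalysis.
Multi-model PDB is the canonical trajectory format at desk scale: an
:class:`Ensemble` is an ordered stack of coordinate frames over one topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "MembraneFrame",
    "StructureError",
    "read_structure",
    "read_ensemble",
    "read_pqr",
    "write_structure",
    "write_ensemble",
    "write_pqr",
    "select",
    "default_vdw_radius",
]


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure files."""


#: Van der Waals radii in Å (Bondi 1964 plus common extensions); used whenever
#: the input format does not carry per-atom radii.
_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31,
}
_DEFAULT_VDW = 1.70


def default_vdw_radius(element: str) -> float:
    """Return the bundled vdW radius for *element* (Å), falling back to 1.7 Å."""
    return _VDW_RADII.get(element.upper().strip(), _DEFAULT_VDW)


@dataclass
class Atom:
    """One atom: identity, position (Å), vdW radius (Å) and optional charge (e)."""

    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: np.ndarray
    vdw_radius: float
    charge: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"atom {self.name}: xyz must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise StructureError(f"atom {self.name}: vdw_radius must be > 0")


@dataclass
class Structure:
    """An ordered collection of atoms forming a single conformation."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("structure must contain at least one atom")
        keys = [(a.chain, a.resid, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise StructureError(f"duplicate atom identity {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å (a copy)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Return a copy of this structure carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            Atom(a.name, a.element, a.resname, a.resid, a.chain, xyz,
                 a.vdw_radius, a.charge)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.label if label is None else label)


@dataclass
class Ensemble:
    """Frames of one topology; ``frames[i]`` is an (N, 3) array in Å."""

    topology: Structure
    frames: np.ndarray
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise StructureError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{len(self.topology)}-atom topology"
            )
        if self.frames.shape[0] < 1:
            raise StructureError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        """Structure for frame *i* (topology with that frame's coordinates)."""
        return self.topology.with_coords(self.frames[i])


@dataclass
class MembraneFrame:
    """Orientation of the implicit membrane: normal axis and midplane offset (Å)."""

    normal_axis: str = "z"
    midplane_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.normal_axis not in ("x", "y", "z"):
            raise ValueError("normal_axis must be one of 'x', 'y', 'z'")

    @property
    def axis_index(self) -> int:
        return "xyz".index(self.normal_axis)


# ---------------------------------------------------------------------------
# PDB through gemmi
# ---------------------------------------------------------------------------

def _gemmi_models(path: str | Path):
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records found")
    return st


def _model_atoms(model, label: str) -> list[Atom]:
    atoms: list[Atom] = []
    seen: set[tuple[str, int, str]] = set()
    for chain in model:
        for res in chain:
            for at in res:
                el = at.element.name if at.element else ""
                if not el or el == "X":
                    el = "".join(c for c in at.name if c.isalpha())[:1] or "C"
                key = (chain.name, res.seqid.num, at.name)
                if key in seen:
                    # altloc duplicates: keep the first occurrence, as crystal-
                    # lographic convention for highest occupancy listed first
                    continue
                seen.add(key)
                atoms.append(Atom(
                    name=at.name,
                    element=el.upper(),
                    resname=res.name,
                    resid=res.seqid.num,
                    chain=chain.name,
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    vdw_radius=default_vdw_radius(el),
                ))
    if not atoms:
        raise StructureError(f"{label}: model contains no atoms")
    return atoms


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model of multi-model files).

    Van der Waals radii are assigned from the bundled element table since PDB
    carries none.
    """
    st = _gemmi_models(path)
    if len(st) > 1:
        warnings.warn(
            f"{path}: {len(st)} models present; using the first model only",
            stacklevel=2,
        )
    return Structure(_model_atoms(st[0], str(path)), label=Path(path).stem)


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB file as an :class:`Ensemble` (one frame per MODEL)."""
    st = _gemmi_models(path)
    topo = Structure(_model_atoms(st[0], str(path)), label=Path(path).stem)
    frames = np.empty((len(st), len(topo), 3))
    frames[0] = topo.coords
    for m in range(1, len(st)):
        atoms = _model_atoms(st[m], f"{path} model {m + 1}")
        if len(atoms) != len(topo):
            raise StructureError(
                f"{path}: model {m + 1} has {len(atoms)} atoms, "
                f"model 1 has {len(topo)}"
            )
        for a, b in zip(topo.atoms, atoms):
            if (a.chain, a.resid, a.name) != (b.chain, b.resid, b.name):
                raise StructureError(
                    f"{path}: model {m + 1} atom ordering differs from model 1 "
                    f"at {(b.chain, b.resid, b.name)}"
                )
        frames[m] = np.array([a.xyz for a in atoms])
    return Ensemble(topo, frames)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-conformation fixed-width PDB file."""
    _write_pdb_models(structure, structure.coords[None, :, :], path)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    _write_pdb_models(ensemble.topology, ensemble.frames, path)


def _write_pdb_models(topology: Structure, frames: np.ndarray, path: str | Path) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = topology.label or "gateworks"
    for f, coords in enumerate(frames):
        model = gemmi.Model(f + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        for atom, xyz in zip(topology.atoms, coords):
            ch = chain_map.get(atom.chain)
            if ch is None:
                model.add_chain(gemmi.Chain(atom.chain))
                ch = model[len(chain_map)]
                chain_map[atom.chain] = ch
            if len(ch) == 0 or ch[len(ch) - 1].seqid.num != atom.resid:
                res = gemmi.Residue()
                res.name = atom.resname
                res.seqid = gemmi.SeqId(atom.resid, " ")
                ch.add_residue(res)
            res = ch[len(ch) - 1]
            at = gemmi.Atom()
            at.name = atom.name
            at.element = gemmi.Element(atom.element.capitalize())
            at.pos = gemmi.Position(*xyz)
            at.occ = 1.0
            res.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> Structure:
    """Read a PQR file; per-atom charge and radius are taken from the file."""
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="PQR", topology_format="PQR")
        except (ValueError, IndexError, OSError) as exc:
            raise StructureError(f"cannot parse PQR file {path}: {exc}") from exc
    if not hasattr(u.atoms, "charges") or not hasattr(u.atoms, "radii"):
        raise StructureError(f"{path}: PQR file lacks charge/radius columns")
    atoms = []
    for at in u.atoms:
        el = "".join(c for c in at.name if c.isalpha())[:1] or "C"
        chain = getattr(at, "chainID", "") or getattr(at, "segid", "") or "A"
        radius = float(at.radius)
        atoms.append(Atom(
            name=at.name, element=el.upper(), resname=at.resname,
            resid=int(at.resid), chain=str(chain)[:1] or "A",
            xyz=at.position.astype(float),
            vdw_radius=radius if radius > 0 else default_vdw_radius(el),
            charge=float(at.charge),
        ))
    return Structure(atoms, label=path.stem)


def write_pqr(structure: Structure, path: str | Path) -> None:
    """Write the whitespace PQR dialect (name, res, chain, xyz, charge, radius)."""
    with open(path, "w") as fh:
        fh.write("REMARK written by gateworks\n")
        for i, a in enumerate(structure.atoms, start=1):
            fh.write(
                f"ATOM {i:6d} {a.name:<4s} {a.resname:<4s} {a.chain:1s} "
                f"{a.resid:5d} {a.xyz[0]:10.4f} {a.xyz[1]:10.4f} {a.xyz[2]:10.4f} "
                f"{a.charge:8.4f} {a.vdw_radius:7.4f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select(
    structure: Structure,
    names: Iterable[str] | None = None,
    resids: Iterable[int] | None = None,
    resnames: Iterable[str] | None = None,
    chains: Iterable[str] | None = None,
) -> np.ndarray:
    """Return atom indices matching the query, in atom order.

    Fields combine conjunctively; the values within one field disjunctively.
    An empty query selects every atom.
    """
    names_s = set(names) if names is not None else None
    resids_s = set(resids) if resids is not None else None
    resnames_s = set(resnames) if resnames is not None else None
    chains_s = set(chains) if chains is not None else None
    idx = [
        i for i, a in enumerate(structure.atoms)
        if (names_s is None or a.name in names_s)
        and (resids_s is None or a.resid in resids_s)
        and (resnames_s is None or a.resname in resnames_s)
        and (chains_s is None or a.chain in chains_s)
    ]
    return np.array(idx, dtype=int)
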