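"""Macromolecular structure container, PDB/mmCIF input/output and
crystallographic symmetry expansion.

The in-memory model is deliberately small: an ordered hierarchy of
chains -> residues -> atoms plus the unit cell and the space-group
operators, which is everything the downstream geometric analyses need.
File parsing, writing and the space-group operator table are delegated
to :mod:`gemmi`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "ParseError",
    "read_structure",
    "write_structure",
    "expand_symmetry",
    "orthogonalization_matrix",
]


class StructureError(ValueError):
    """Raised for malformed structures or unsatisfiable requests."""


class ParseError(StructureError):
    """Raised when an input file cannot be read under the named dialect."""


@dataclass
class Atom:
    """A single atom: label, element, orthogonal coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue identified by 3-letter code and author sequence number.

    Non-standard residues (e.g. the helix-promoting "AIB",
    2-aminoisobutyric acid) and capping groups ("ACE", "NH2") are
    ordinary residues here.
    """

    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.name}{self.seq_id}: no atom named {name!r}")

    def has_atoms(self, *names: str) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    def add_atom(self, atom: Atom) -> None:
        if any(a.name == atom.name for a in self.atoms):
            raise StructureError(
                f"residue {self.name}{self.seq_id}: duplicate atom name {atom.name!r}"
            )
        self.atoms.append(atom)


@dataclass
class Structure:
    """Ordered chains of residues plus optional cell and symmetry operators.

    ``sym_ops`` holds (rotation, translation) pairs acting on fractional
    coordinates; when a space group is present the identity operator is
    first.
    """

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    name: str = ""

    # -- iteration helpers -------------------------------------------------
    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def coords(self) -> np.ndarray:
        """All atomic coordinates as an (N, 3) array (atom order)."""
        arr = [a.coords for a in self.atoms()]
        return np.array(arr) if arr else np.empty((0, 3))

    def get_residue(self, chain_id: str, seq_id: int) -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.seq_id == seq_id:
                return res
        raise StructureError(f"no residue {seq_id} in chain {chain_id!r}")

    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly moved deep copy (cartesian rotation + translation)."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for atom in out.atoms():
            atom.coords = R @ atom.coords + t
        return out


# ---------------------------------------------------------------------------
# reading


def _gemmi():
    import gemmi

    return gemmi


def _space_group_ops(hm_symbol: str) -> list[tuple[np.ndarray, np.ndarray]]:
    gemmi = _gemmi()
    sg = gemmi.SpaceGroup(hm_symbol)
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    # identity first
    ops.sort(key=lambda rt: 0 if (np.allclose(rt[0], np.eye(3)) and np.allclose(rt[1], 0)) else 1)
    return ops


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM and HETATM records are kept (metals included), author
    residue numbering is preserved, and alternate conformers are reduced
    to the highest-occupancy one (ties: first encountered).  Only model 1
    of multi-model files is read.
    """
    gemmi = _gemmi()
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format.lower()
    if fmt not in ("pdb", "mmcif", "auto"):
        raise StructureError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with record context
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    out = Structure(name=st.name or path.stem)
    cell = st.cell
    if cell and not (cell.a == cell.b == cell.c == 1.0):
        out.unit_cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    hm = st.spacegroup_hm
    if hm and out.unit_cell is not None:
        try:
            out.space_group = hm
            out.sym_ops = _space_group_ops(hm)
        except Exception:
            out.space_group = hm  # symbol kept; operators unavailable

    if len(st) == 0:
        return out
    model = st[0]
    for ch in model:
        for res in ch:
            r = Residue(name=res.name.strip(), seq_id=res.seqid.num, chain_id=ch.name)
            # altloc reduction: highest occupancy wins, tie -> first seen
            best: dict[str, object] = {}
            order: list[str] = []
            for at in res:
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                r.add_atom(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_iso=at.b_iso,
                        is_hetero=res.het_flag == "H",
                    )
                )
            if r.atoms:
                out.add_residue(r)
    return out


# ---------------------------------------------------------------------------
# writing


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write ``structure`` as a PDB file (coordinates to 3 decimals)."""
    gemmi = _gemmi()
    if structure.n_atoms() == 0:
        raise StructureError("refusing to write an empty structure")
    if structure.n_atoms() > 99999:
        raise StructureError("PDB format supports at most 99999 atoms")
    st = gemmi.Structure()
    st.name = structure.name or "minimet"
    if structure.unit_cell is not None:
        st.cell = gemmi.UnitCell(*structure.unit_cell)
    if structure.space_group:
        st.spacegroup_hm = structure.space_group
    model = gemmi.Model("1")
    for chain_id, residues in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            gres.het_flag = "H" if any(a.is_hetero for a in res.atoms) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# symmetry


def orthogonalization_matrix(
    cell: tuple[float, float, float, float, float, float],
) -> np.ndarray:
    """Fractional -> orthogonal matrix, PDB convention (a along x)."""
    a, b, c, alpha, beta, gamma = cell
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ]
    )


def expand_symmetry(structure: Structure, radius: float) -> list[Structure]:
    """Return all crystallographic symmetry mates with any atom within
    ``radius`` Angstrom of the input molecule.

    Unit-cell translations of -1, 0, +1 along each axis are combined with
    every space-group operator; the identity copy itself is excluded.
    Each mate is a rigid copy of the input (intra-mate distances are
    preserved exactly) and carries a descriptive ``name`` recording the
    operator and lattice shift.
    """
    if structure.unit_cell is None or not structure.sym_ops:
        raise StructureError("expand_symmetry requires a unit cell and symmetry operators")
    M = orthogonalization_matrix(structure.unit_cell)
    Minv = np.linalg.inv(M)
    xyz = structure.coords()
    if len(xyz) == 0:
        return []
    frac = xyz @ Minv.T
    tree = cKDTree(xyz)
    mates: list[Structure] = []
    for k, (rot, tran) in enumerate(structure.sym_ops):
        base = frac @ rot.T + tran
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                for sz in (-1, 0, 1):
                    shift = np.array([sx, sy, sz], float)
                    is_identity = (
                        k == 0
                        and np.allclose(rot, np.eye(3))
                        and np.allclose(tran + shift, 0.0)
                    )
                    if is_identity:
                        continue
                    cart = (base + shift) @ M.T
                    dmin = tree.query(cart, k=1)[0].min()
                    if dmin <= radius:
                        mate = structure.copy()
                        mate.name = f"{structure.name}|op{k}+({sx},{sy},{sz})"
                        for atom, new in zip(mate.atoms(), cart):
                            atom.coords = new
                        mates.append(mate)
    return mates
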