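"""Deterministic synthetic-structure and synthetic-measurement generators.

Every generator here produces a stand-in object: geometry built from
ideal internal coordinates or measurements drawn from the package's own
forward models, with seeded noise.  They emulate the study conditions
of a miniaturized tetrathiolate electron-transfer protein — an ideal
M(Cys)4 site, a C2-related pair of half-site fragments, fragment
libraries with planted gap-closing loops, 1:1 titrations, peak-current
tables and effective-g observations — so that every analysis module is
testable without any deposited data.  None of these objects are real
experimental structures; docstrings say so explicitly where a generator
mimics a specific experimental scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .biophys import (
    FARADAY,
    GAS_CONSTANT,
    ZfsParams,
    binding_signal_1to1,
    zfs_effective_g,
)
from .geometry_core import Transform, dihedral, superpose
from .loop_closure import ANCHOR_ATOMS, FragmentLibrary, StubPair
from .motif_annotator import CANONICAL_TURNS
from .structure_io import Atom, Residue, Structure, write_structure

__all__ = [
    "place_atom",
    "make_ideal_site",
    "backbone_from_dihedrals",
    "make_synthetic_template",
    "make_mini_library",
    "close_gap_loop",
    "make_synthetic_design_pair",
    "make_compact_globule",
    "make_crystal_contact_fixture",
    "make_measurements",
    "make_cv_trace",
    "METPSC1_LIKE_SEQUENCE",
]

# Ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
BOND_CB_SG = 1.810
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_SG = 114.0

# A 28-residue stand-in sequence (synthetic): consistent with the
# documented miniprotein constraints — Cys at 2/5/17/20, Ser3-Asp4,
# Ala7/22, Aib9/24 (one-letter B), Val12, the Gly14-Gly15 turn, the
# Tyr1/Tyr16 pseudo-symmetric pair (2 Tyr, 0 Trp), Asn19, Arg26, Ile27.
METPSC1_LIKE_SEQUENCE = "YCSDCKAEBKGVKGGYCSNCKAEBKRIE"

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "B": "AIB",
}


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement: the point d with |cd| =
    bond_length, angle(b,c,d) = bond_angle and dihedral(a,b,c,d) =
    torsion (degrees)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(bond_angle)
    tor = -math.radians(torsion)  # sign matches the IUPAC measurement convention
    d_local = bond_length * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# ideal metal site


def make_ideal_site(
    metal: str = "ZN",
    d: float = 2.34,
    torsions: tuple[float, float] = (180.0, 159.0),
    chi1_angles: tuple[float, float, float, float] = (180.0, 60.0, 180.0, 60.0),
    seq_ids: tuple[int, int, int, int] = (2, 5, 17, 20),
    chain_id: str = "A",
) -> Structure:
    """Exactly tetrahedral M(Cys)4 site (synthetic).

    The metal sits at the origin with four Sgamma at tetrahedral
    vertices, distance ``d``; vertices are ordered so that ligand k and
    ligand k+2 are related by the C2 axis along z.  Cbeta atoms realize
    the prescribed cross-dyad Sgamma-M-Sgamma-Cbeta torsions, and
    CA/N atoms realize the prescribed chi1 rotamers (defaults: the
    t/g+/t/g+ pattern of a rubredoxin-type site).
    """
    s3 = 1.0 / math.sqrt(3.0)
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, -1, 1], [-1, 1, -1]], float) * s3
    sg = verts * d
    metal_pos = np.zeros(3)
    st = Structure(name="ideal_site")
    n = 4
    half = n // 2
    cb = [None] * n
    for k in range(n):
        partner = (k + half) % n
        # torsion Sg(partner)-M-Sg(k)-Cb(k); same value for both members of a dyad pair
        tau = torsions[k % half]
        cb[k] = place_atom(sg[partner], metal_pos, sg[k], BOND_CB_SG, 107.0, tau)
    for k, seq in enumerate(seq_ids):
        res = Residue(name="CYS", seq_id=seq, chain_id=chain_id)
        ca = place_atom(metal_pos, sg[k], cb[k], BOND_CA_CB, ANGLE_CA_CB_SG, -60.0)
        npos = place_atom(sg[k], cb[k], ca, BOND_N_CA, ANGLE_N_CA_CB, chi1_angles[k])
        res.add_atom(Atom("N", "N", npos))
        res.add_atom(Atom("CA", "C", ca))
        res.add_atom(Atom("CB", "C", cb[k]))
        res.add_atom(Atom("SG", "S", sg[k]))
        st.add_residue(res)
    mres = Residue(name=metal.upper(), seq_id=99, chain_id=chain_id)
    mres.add_atom(Atom(metal.upper(), metal.capitalize(), metal_pos, is_hetero=True))
    st.add_residue(mres)
    return st


# ---------------------------------------------------------------------------
# backbone builder


def backbone_from_dihedrals(
    phi_psi_omega: list[tuple[float, float, float]],
    sequence: str | list[str] | None = None,
    chain_id: str = "A",
    start_seq: int = 1,
    with_cb: bool = True,
) -> Structure:
    """Polypeptide backbone built from ideal bond geometry and the given
    per-residue (phi, psi, omega) torsions.

    ``phi`` of the first residue and ``omega`` of the last are unused.
    Re-measured dihedrals reproduce the inputs to well under 1e-3
    degrees.  Cbeta atoms are added for non-Gly residues.
    """
    n = len(phi_psi_omega)
    if n == 0:
        return Structure(name="empty")
    if sequence is None:
        seq3 = ["ALA"] * n
    elif isinstance(sequence, str):
        if len(sequence) != n:
            raise ValueError(f"sequence length {len(sequence)} != {n} dihedral triples")
        seq3 = [_THREE[c.upper()] for c in sequence]
    else:
        if len(sequence) != n:
            raise ValueError("sequence length mismatch")
        seq3 = [s.upper() for s in sequence]

    st = Structure(name="backbone")
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords = [(N, CA, C)]
    for i in range(1, n):
        psi_prev = phi_psi_omega[i - 1][1]
        omega_prev = phi_psi_omega[i - 1][2]
        phi_i = phi_psi_omega[i][0]
        Np, CAp, Cp = coords[-1]
        Ni = place_atom(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CAi = place_atom(CAp, Cp, Ni, BOND_N_CA, ANGLE_C_N_CA, omega_prev)
        Ci = place_atom(Cp, Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append((Ni, CAi, Ci))
    for i, (Ni, CAi, Ci) in enumerate(coords):
        res = Residue(name=seq3[i], seq_id=start_seq + i, chain_id=chain_id)
        res.add_atom(Atom("N", "N", Ni))
        res.add_atom(Atom("CA", "C", CAi))
        res.add_atom(Atom("C", "C", Ci))
        psi_i = phi_psi_omega[i][1]
        O = place_atom(Ni, CAi, Ci, BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
        res.add_atom(Atom("O", "O", O))
        if with_cb and seq3[i] != "GLY":
            cb = place_atom(Ci, Ni, CAi, BOND_CA_CB, ANGLE_N_CA_CB, 122.6)
            res.add_atom(Atom("CB", "C", cb))
        st.add_residue(res)
    return st


def add_sidechain_sg(res: Residue, chi1: float) -> None:
    """Attach an SG atom to a Cys residue at the given chi1 torsion."""
    sg = place_atom(
        res.atom("N").coords, res.atom("CA").coords, res.atom("CB").coords,
        BOND_CB_SG, ANGLE_CA_CB_SG, chi1,
    )
    res.add_atom(Atom("SG", "S", sg))


# ---------------------------------------------------------------------------
# synthetic C2 template


def _half_site_dihedrals() -> list[tuple[float, float, float]]:
    """13-residue half-site profile: a strand lead-in, a metal-binding
    knuckle, a short helical stretch, a strand exit."""
    beta = (-120.0, 130.0, 180.0)
    knuckle = [(-60.0, -30.0, 180.0), (-90.0, 0.0, 180.0), (-120.0, 20.0, 180.0)]
    helix = (-60.0, -40.0, 180.0)
    return [beta, (-100.0, 120.0, 180.0)] + knuckle + [helix, helix, helix] + [
        (-70.0, -20.0, 180.0), (-130.0, 140.0, 180.0), beta, beta, (-100.0, 130.0, 180.0)
    ]


def _build_half_site(params: np.ndarray, d_metal_s: float, seq: str = "ACKKCGAEAAKLE"):
    """Half-site fragment for a target thiolate pair.

    ``params`` = phi/psi of the four knuckle residues (39-42) followed
    by the two Cys chi1 angles; the fragment is rigidly placed so its
    thiolate pair best matches the tetrahedral vertices t1/t2 of a metal
    at the origin.
    """
    from scipy.spatial.transform import Rotation

    s3 = 1.0 / math.sqrt(3.0)
    t1 = np.array([1, 1, 1]) * s3 * d_metal_s
    t2 = np.array([1, -1, -1]) * s3 * d_metal_s
    prof = list(_half_site_dihedrals())
    for k in range(4):
        prof[1 + k] = (params[2 * k], params[2 * k + 1], 180.0)
    for k in range((len(params) - 10) // 2):  # optional tail torsions, residues 44..
        prof[6 + k] = (params[10 + 2 * k], params[11 + 2 * k], 180.0)
    st = backbone_from_dihedrals(prof, seq, start_seq=38)
    cys = [r for r in st.chains["A"] if r.name == "CYS"]
    add_sidechain_sg(cys[0], params[8])
    add_sidechain_sg(cys[1], params[9])
    s1, s2 = cys[0].atom("SG").coords, cys[1].atom("SG").coords
    R, _ = Rotation.align_vectors(
        [t2 - t1, (t1 + t2) / 2],
        [s2 - s1, cys[0].atom("CB").coords - s1],
        weights=[10.0, 1.0],
    )
    Rm = R.as_matrix()
    mid_s, mid_t = (s1 + s2) / 2, (t1 + t2) / 2
    for a in st.atoms():
        a.coords = Rm @ (a.coords - mid_s) + mid_t
    return st, cys, (t1, t2)


def _half_site_params(d_metal_s: float) -> np.ndarray:
    """Knuckle torsions placing both thiolates exactly on their
    tetrahedral vertices while keeping every atom at least ~1.4 Angstrom
    off the twofold axis (so the C2 image does not clash).  Solved once
    by deterministic least squares and cached."""
    key = round(d_metal_s, 6)
    if key in _HALF_SITE_CACHE:
        return _HALF_SITE_CACHE[key]
    if key == round(_DEFAULT_D_METAL_S, 6):
        return _HALF_SITE_SOLVED

    def residual(p):
        st, cys, (t1, t2) = _build_half_site(p, d_metal_s)
        out = list((cys[0].atom("SG").coords - t1) * 3.0)
        out += list((cys[1].atom("SG").coords - t2) * 3.0)
        for a in st.atoms():
            rho = math.hypot(a.coords[0], a.coords[1])
            out.append(max(0.0, 1.4 - rho) * 4.0)
        # the C2 image of the fragment's C-terminus must land a
        # loop-bridgeable distance from the fragment's N-terminus
        chain = st.chains["A"]
        c_img = np.diag([-1.0, -1.0, 1.0]) @ chain[-1].atom("C").coords
        span = np.linalg.norm(c_img - chain[0].atom("N").coords)
        out.append((span - 7.0) * 0.5)
        return np.array(out)

    rng = np.random.default_rng(12345)
    p0 = np.concatenate(
        [
            np.array([-60, -30, -90, 0, -120, 20, -140, 130, 180, 60], float),
            np.array([-70, -25, -130, 140, -120, 130, -100, 125, -60, -40, -80, 60, -120, 140], float),
        ]
    )
    best = None
    for r in range(10):
        p = p0 + (rng.normal(0, 25, len(p0)) if r else 0.0)
        sol = least_squares(residual, p, max_nfev=3000)
        cost = float((sol.fun**2).sum())
        if best is None or cost < best[0]:
            best = (cost, sol.x)
        if best[0] < 1e-14:
            break
    _HALF_SITE_CACHE[key] = best[1]
    return best[1]


_HALF_SITE_CACHE: dict[float, np.ndarray] = {}

_DEFAULT_D_METAL_S = 2.30
# Frozen output of _half_site_params(2.30) (deterministic solve; verified
# against its targets in the test suite).
_HALF_SITE_SOLVED = np.array(
    [
        -133.710405, -23.36169, -109.663144, -0.007844, -109.806023, 78.022065,
        -44.802023, 153.21055, 204.053357, 11.10263, -139.445923, -49.186564,
        -135.833159, 118.329435, -162.137005, 109.082252, -110.62957, 126.829347,
        -20.777353, -72.332485, -121.259904, 6.914265, -128.009873, 173.676944,
    ]
)


def make_synthetic_template(
    seed: int = 0,
    jitter: float = 0.0,
    metal: str = "FE",
    d_metal_s: float = 2.30,
) -> Structure:
    """Synthetic stand-in for a rubredoxin-like template structure.

    A 13-residue fragment (author numbering 38-50, Cys at 39 and 42,
    CXXCX half-site at 39-43) is built from ideal internal coordinates
    with its knuckle torsions solved so the two thiolates sit exactly on
    tetrahedral vertices about a metal at the origin.  The second half
    (numbered 5-17, CXXCX at 6-10) is the exact C2 image about z,
    optionally jittered by Gaussian noise of ``jitter`` Angstrom
    (seeded) to make the twofold pseudo rather than exact.  The metal is
    included as a heteroatom.  This emulates the topology used for
    miniaturization; it is not a real protein structure.
    """
    rng = np.random.default_rng(seed)
    frag, cys, (t1, t2) = _build_half_site(_half_site_params(d_metal_s), d_metal_s)
    cys[0].atom("SG").coords = t1.copy()
    cys[1].atom("SG").coords = t2.copy()
    chain = frag.chains["A"]

    st = Structure(name="synthetic_template")
    c2 = np.diag([-1.0, -1.0, 1.0])
    import copy

    for res in chain:  # C2 image half first: author numbering 5..17
        r = copy.deepcopy(res)
        r.seq_id = res.seq_id - 33
        for atom in r.atoms:
            atom.coords = c2 @ atom.coords
            if jitter > 0:
                atom.coords = atom.coords + rng.normal(0.0, jitter, 3)
        st.add_residue(r)
    for res in chain:
        st.add_residue(copy.deepcopy(res))
    mres = Residue(name=metal.upper(), seq_id=60, chain_id="A")
    mres.add_atom(Atom(metal.upper(), metal.capitalize(), np.zeros(3), is_hetero=True))
    st.add_residue(mres)
    return st


# ---------------------------------------------------------------------------
# fragment libraries with planted loops


@dataclass
class PlantedLoop:
    stubs: StubPair
    source: str
    gap_length: int
    turn_type: str


_COIL_BASINS = (
    ((-150.0, -90.0), (100.0, 150.0)),  # broad beta
    ((-90.0, -55.0), (-50.0, -25.0)),  # broad alpha
)


def _coil_dihedrals(n: int, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    out = []
    for _ in range(n):
        (phlo, phhi), (pslo, pshi) = _COIL_BASINS[rng.integers(len(_COIL_BASINS))]
        out.append((rng.uniform(phlo, phhi), rng.uniform(pslo, pshi), 180.0))
    return out


def _turn_window_dihedrals(gap: int, turn_type: str | None, rng) -> list:
    """anchor + gap + anchor dihedral triples; for gap 4 the central
    pair carries canonical turn dihedrals when a type is given."""
    dh = _coil_dihedrals(gap + 2, rng)
    if gap == 4 and turn_type:
        phi2, psi2, phi3, psi3 = CANONICAL_TURNS[turn_type]
        dh[2] = (phi2, psi2, 180.0)
        dh[3] = (phi3, psi3, 180.0)
    return dh


def make_mini_library(
    out_dir: str | Path,
    n_structures: int = 20,
    planted_loops: list[tuple[int, str]] = ((4, "I'"),),
    seed: int = 0,
    decoy_length: int = 30,
    loop_sequences: list[str] | None = None,
) -> tuple[FragmentLibrary, list[PlantedLoop]]:
    """Write a small fragment library of random-coil decoys plus planted
    gap-closing windows, with companion stub pairs.

    Decoy dihedrals are drawn from broad beta/alpha basins (seeded), so
    accidental anchor matches at tight cutoffs are vanishingly rare.
    Each planted window is built from canonical dihedrals, stored under
    a random rigid motion, and its companion :class:`StubPair` is the
    window's two anchor residues at their original (pre-motion)
    coordinates — a search must recover the transform.  Same seed, same
    bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    index_lines = []
    planted: list[PlantedLoop] = []
    for i in range(n_structures):
        st = backbone_from_dihedrals(_coil_dihedrals(decoy_length, rng))
        st.name = f"decoy{i:03d}"
        fname = f"decoy{i:03d}.pdb"
        write_structure(st, out_dir / fname)
        index_lines.append(f"decoy{i:03d}\tA\t{fname}")
    import copy

    for j, (gap, turn_type) in enumerate(planted_loops):
        seq = None
        if loop_sequences and j < len(loop_sequences):
            seq = "A" + loop_sequences[j] + "A"
        window = backbone_from_dihedrals(
            _turn_window_dihedrals(gap, turn_type, rng), seq
        )
        window.name = f"plant{j:03d}"
        chain = window.chains["A"]
        stubs = StubPair(
            c_side=copy.deepcopy(chain[0]), n_side=copy.deepcopy(chain[-1])
        )
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        tf = Transform.about_axis(rng.normal(scale=5.0, size=3), axis, rng.uniform(0, 360))
        moved = window.transformed(tf.rotation, tf.translation + rng.normal(scale=10.0, size=3))
        fname = f"plant{j:03d}.pdb"
        write_structure(moved, out_dir / fname)
        index_lines.append(f"plant{j:03d}\tA\t{fname}")
        planted.append(
            PlantedLoop(stubs=stubs, source=f"plant{j:03d}", gap_length=gap,
                        turn_type=turn_type or "none")
        )
    (out_dir / "index.tsv").write_text("\n".join(index_lines) + "\n")
    return FragmentLibrary(out_dir / "index.tsv"), planted


def close_gap_loop(
    stubs: StubPair,
    gap_length: int = 4,
    seed: int = 0,
    n_restarts: int = 8,
    sequence: str | None = None,
) -> tuple[Structure, float]:
    """Numerically close a stub gap with a ``gap_length``-residue loop.

    Builds an anchor+loop+anchor window forward from the C-side anchor
    by internal coordinates and optimizes the free phi/psi torsions
    (omegas fixed trans) so the final residue's backbone matches the
    N-side anchor; several seeded restarts keep the best closure.
    Returns the window structure (anchor coordinates exact on the C
    side) and the achieved anchor RMSD.  Fixture machinery for planting
    solvable search problems, not an analytical closure method.
    """
    rng = np.random.default_rng(seed)
    target = np.array([stubs.n_side.atom(a).coords for a in ANCHOR_ATOMS])
    c_anchor = {a: stubs.c_side.atom(a).coords for a in ANCHOR_ATOMS}

    def build(params: np.ndarray):
        # params: psi0, (phi, psi) x gap, phi_last, psi_last
        N, CA, C = c_anchor["N"], c_anchor["CA"], c_anchor["C"]
        coords = [(N, CA, C)]
        psi_prev = params[0]
        k = 1
        for _ in range(gap_length + 1):
            phi_i = params[k]
            psi_i = params[k + 1]
            k += 2
            Np, CAp, Cp = coords[-1]
            Ni = place_atom(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, psi_prev)
            CAi = place_atom(CAp, Cp, Ni, BOND_N_CA, ANGLE_C_N_CA, 180.0)
            Ci = place_atom(Cp, Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, phi_i)
            coords.append((Ni, CAi, Ci))
            psi_prev = psi_i
        return coords

    def residual(params: np.ndarray) -> np.ndarray:
        coords = build(params)
        Ni, CAi, Ci = coords[-1]
        O = place_atom(Ni, CAi, Ci, BOND_C_O, ANGLE_CA_C_O, params[-1] + 180.0)
        got = np.array([Ni, CAi, Ci, O])
        return (got - target).ravel()

    n_par = 1 + 2 * (gap_length + 1)
    best = None
    for r in range(n_restarts):
        if r == 0 and gap_length == 4:
            phi2, psi2, phi3, psi3 = CANONICAL_TURNS["I'"]
            p0 = np.array([120.0, -120.0, 30.0, phi2, psi2, phi3, psi3, -100.0, 130.0, -120.0, 120.0])
            p0 = p0[:n_par] if len(p0) >= n_par else np.concatenate([p0, rng.uniform(-180, 180, n_par - len(p0))])
        else:
            p0 = rng.uniform(-180.0, 180.0, n_par)
        sol = least_squares(residual, p0, method="lm", max_nfev=2000)
        rmsd = float(np.sqrt((sol.fun**2).sum() / 4))
        if best is None or rmsd < best[1]:
            best = (sol.x, rmsd)
    params, rmsd = best
    coords = build(params)
    psis = [params[0]] + [params[2 + 2 * i] for i in range(gap_length + 1)]
    seq = sequence or ("A" + "G" * gap_length + "A")
    st = Structure(name="closure")
    for i, (Ni, CAi, Ci) in enumerate(coords):
        name = _THREE[seq[i].upper()] if i < len(seq) else "ALA"
        res = Residue(name=name, seq_id=i + 1, chain_id="A")
        res.add_atom(Atom("N", "N", np.asarray(Ni, float)))
        res.add_atom(Atom("CA", "C", np.asarray(CAi, float)))
        res.add_atom(Atom("C", "C", np.asarray(Ci, float)))
        O = place_atom(Ni, CAi, Ci, BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        res.add_atom(Atom("O", "O", O))
        st.add_residue(res)
    # C-side anchor O is known exactly
    st.chains["A"][0].atom("O").coords = np.asarray(c_anchor["O"], float).copy()
    return st, rmsd


# ---------------------------------------------------------------------------
# design-vs-experiment pair


def _miniprotein_dihedrals() -> list[tuple[float, float, float]]:
    """28-residue profile echoing the miniature fold's motif progression
    (strand / turn / strand / 3_10 / strand / I' turn, twice)."""
    half = [
        (-120.0, 130.0, 180.0), (-110.0, 125.0, 180.0),          # strand
        (-60.0, -35.0, 180.0), (-65.0, -30.0, 180.0),            # alpha-turn corner
        (-95.0, 5.0, 180.0),                                     # bulge-ish
        (-120.0, 130.0, 180.0), (-115.0, 125.0, 180.0),          # strand
        (-49.0, -26.0, 180.0), (-49.0, -26.0, 180.0), (-49.0, -26.0, 180.0),  # 3_10
        (-110.0, 120.0, 180.0), (-115.0, 130.0, 180.0),          # strand
    ]
    turn = [(60.0, 30.0, 180.0), (90.0, 0.0, 180.0)]             # I' center
    return half + turn + half + [(-120.0, 140.0, 180.0), (-110.0, 130.0, 180.0)]


def make_synthetic_design_pair(
    seed: int = 0, target_rmsd: float = 0.45
) -> tuple[Structure, Structure]:
    """Synthetic design-model / experimental-model pair.

    Builds a 28-residue backbone from the miniature fold's dihedral
    profile and a copy deformed by smooth, seeded backbone noise scaled
    so that the optimal-superposition backbone (N/CA/C/O) RMSD equals
    ``target_rmsd`` exactly.  A stand-in for comparing a designed model
    against a refined experimental structure; both members are
    synthetic.
    """
    rng = np.random.default_rng(seed)
    a = backbone_from_dihedrals(_miniprotein_dihedrals(), METPSC1_LIKE_SEQUENCE)
    a.name = "design_model_synthetic"
    b = a.copy()
    b.name = "xray_model_synthetic"
    atom_list = list(a.atoms())
    n = len(atom_list)
    noise = rng.normal(size=(n, 3))
    kernel = np.ones(9) / 9.0  # smooth along the chain: low-frequency deformation
    for k in range(3):
        noise[:, k] = np.convolve(noise[:, k], kernel, mode="same")
    P = np.array([at.coords for at in atom_list])
    bb = np.array([i for i, at in enumerate(atom_list) if at.name in ("N", "CA", "C", "O")])
    scale = target_rmsd / max(np.sqrt((noise**2).sum(axis=1).mean()), 1e-12)
    for _ in range(60):
        Q = P + scale * noise
        res = superpose(Q[bb], P[bb])  # calibrate on the backbone RMSD
        if abs(res.rmsd - target_rmsd) < 1e-9:
            break
        scale *= target_rmsd / res.rmsd
    for atom, q in zip(b.atoms(), res.transform.apply(Q)):
        atom.coords = q
    return a, b


# ---------------------------------------------------------------------------
# hydrodynamic stand-in


def make_compact_globule(
    n_residues: int = 28,
    seed: int = 0,
    heavy_atoms_per_residue: float = 7.8,
    residue_volume: float = 110.0,
) -> Structure:
    """Synthetic compact heavy-atom model at protein density.

    ``n_residues * heavy_atoms_per_residue`` pseudo-atoms are placed
    uniformly (seeded, minimum separation 1.0 Angstrom) inside a sphere
    whose volume is ``n_residues * residue_volume`` (cubic Angstrom, the
    mean residue volume of folded proteins).  A stand-in for the
    heavy-atom coordinates of a compact miniprotein in hydrodynamic
    calculations; not a real structure.
    """
    rng = np.random.default_rng(seed)
    n = int(round(n_residues * heavy_atoms_per_residue))
    radius = (3.0 * n_residues * residue_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < 1.0:
            continue
        pts.append(p)
    st = Structure(name="compact_globule_synthetic")
    per_res = 8
    for i, p in enumerate(pts):
        seq = i // per_res + 1
        try:
            res = st.get_residue("A", seq)
        except Exception:
            res = Residue(name="GLB", seq_id=seq, chain_id="A")
            st.add_residue(res)
        res.add_atom(Atom(f"C{i % per_res + 1}", "C", p))
    return st


# ---------------------------------------------------------------------------
# engineered crystal-contact fixture


def make_crystal_contact_fixture(
    oh_oh_distance: float = 3.32,
    salt_bridge_distance: float = 3.0,
    guanidine_sg_distance: float = 3.3,
    cell: tuple[float, float, float] = (30.0, 40.0, 50.0),
) -> Structure:
    """Engineered orthorhombic crystal fixture (synthetic).

    Places a minimal molecule (Tyr16, Asp4, Cys20, Arg26 side-chain
    atoms) in a C222(1) cell so that, by construction, a symmetry mate
    realizes: a Tyr-OH to mate Tyr-OH contact at ``oh_oh_distance``, an
    Arg guanidine to mate Asp carboxylate salt bridge at
    ``salt_bridge_distance``, and a mate-Arg guanidine to Cys Sgamma
    hydrogen bond at ``guanidine_sg_distance``.  Emulates the packing
    interactions described for the miniprotein crystal form.
    """
    from .structure_io import _space_group_ops, orthogonalization_matrix

    a, b, c = cell
    st = Structure(name="crystal_fixture_synthetic")
    st.unit_cell = (a, b, c, 90.0, 90.0, 90.0)
    st.space_group = "C 2 2 21"
    st.sym_ops = _space_group_ops(st.space_group)
    M = orthogonalization_matrix(st.unit_cell)
    Minv = np.linalg.inv(M)

    # the twofold (x, -y, -z): axis along x at y = z = 0
    rot = np.diag([1.0, -1.0, -1.0])
    tran = np.array([0.0, 0.0, 0.0])
    assert any(
        np.allclose(rot, R) and np.allclose(tran, t) for R, t in st.sym_ops
    ), "expected operator missing from C2221 table"

    def op_cart(p: np.ndarray) -> np.ndarray:
        return M @ (rot @ (Minv @ p) + tran)

    # Tyr OH on the y = oh/2, z = 0 line: its twofold image sits oh away along y
    oh = np.array([0.30 * a, oh_oh_distance / 2.0, 0.0])
    tyr = Residue(name="TYR", seq_id=16, chain_id="A")
    tyr.add_atom(Atom("OH", "O", oh))
    tyr.add_atom(Atom("CZ", "C", oh + np.array([-1.4, 0.0, 0.0])))
    st.add_residue(tyr)

    asp = Residue(name="ASP", seq_id=4, chain_id="A")
    od1 = np.array([0.22 * a, 0.12 * b, 0.18 * c])
    asp.add_atom(Atom("OD1", "O", od1))
    asp.add_atom(Atom("OD2", "O", od1 + np.array([0.0, 1.6, 1.6])))
    st.add_residue(asp)

    cys = Residue(name="CYS", seq_id=20, chain_id="A")
    sg = np.array([0.15 * a, 0.30 * b, 0.10 * c])
    cys.add_atom(Atom("SG", "S", sg))
    st.add_residue(cys)

    arg = Residue(name="ARG", seq_id=26, chain_id="A")
    # NH1 at the prescribed distance from the Asp mate's OD1
    nh1 = op_cart(od1) + np.array([salt_bridge_distance, 0.0, 0.0])
    # NH2 such that its own mate lands near the Cys SG: NH2 = op^-1(SG + offset)
    target = sg + np.array([0.0, guanidine_sg_distance, 0.0])
    nh2 = M @ (np.linalg.solve(rot, (Minv @ target) - tran))
    arg.add_atom(Atom("NH1", "N", nh1))
    arg.add_atom(Atom("NH2", "N", nh2))
    arg.add_atom(Atom("CZ", "C", (nh1 + nh2) / 2 + np.array([0.0, 0.0, 1.2])))
    st.add_residue(arg)
    return st


# ---------------------------------------------------------------------------
# synthetic measurements


def make_measurements(
    kind: str,
    truth: dict,
    noise: float = 0.0,
    seed: int = 0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Synthetic measurement tables from the package's forward models.

    ``kind="titration"``: exact 1:1 binding signal on a 0..2 equivalent
    ligand grid (truth: K_D, eps_complex, protein_total, baseline,
    pathlength).  ``kind="voltammogram"``: Randles-Sevcik peak currents
    over the 2.5-50 mV/s scan-rate range (truth: D, n, A, C, T).
    ``kind="geff_set"``: the sharp low-field effective-g markers (ground
    doublet g_y, top doublet g_z) at a given rhombicity (truth:
    e_over_d, g0).  ``noise`` is a relative Gaussian standard deviation
    applied with the seed; the table is written as CSV when ``path`` is
    given.
    """
    rng = np.random.default_rng(seed)
    if kind == "titration":
        P = truth.get("protein_total", 30e-6)
        path_len = truth.get("pathlength", 1.0)
        L = np.arange(0.0, 2.0 * P + 1e-12, 0.1 * P)
        sig = binding_signal_1to1(
            L, truth["K_D"], truth.get("eps_complex", 7730.0),
            truth.get("baseline", 0.0), P, path_len,
        )
        if noise > 0:
            sig = sig + rng.normal(0.0, noise * max(abs(sig).max(), 1e-12), len(sig))
        df = pd.DataFrame({"ligand_total_M": L, "absorbance": sig})
    elif kind == "voltammogram":
        n_el = truth.get("n", 1)
        A = truth.get("A", 0.0707)  # 3 mm diameter disc, cm^2
        C = truth.get("C", 8.0e-8)  # 80 uM in mol/cm^3
        T = truth.get("T", 288.15)
        rates = np.asarray(truth.get("scan_rates", [2.5e-3, 5e-3, 10e-3, 20e-3, 30e-3, 40e-3, 50e-3]))
        ip = 0.4463 * n_el * FARADAY * A * C * np.sqrt(
            n_el * FARADAY * rates * truth["D"] / (GAS_CONSTANT * T)
        )
        if noise > 0:
            ip = ip * (1.0 + rng.normal(0.0, noise, len(ip)))
        df = pd.DataFrame({"scan_rate_V_s": rates, "i_p_A": ip})
    elif kind == "geff_set":
        ed = truth["e_over_d"]
        g0 = truth.get("g0", 2.0023)
        g = zfs_effective_g(ZfsParams(S=2.5, D=1.0, E=ed, g0=g0))
        # the two sharp low-field markers: ground-doublet g_y, top-doublet g_z
        obs = np.array([g[0, 1], g[2, 2]])
        if noise > 0:
            obs = obs * (1.0 + rng.normal(0.0, noise, len(obs)))
        df = pd.DataFrame({"g_eff": obs})
    else:
        raise ValueError(f"unknown measurement kind {kind!r}")
    if path is not None:
        df.to_csv(path, index=False)
    return df


def make_cv_trace(
    e0_vs_ref: float,
    scan_rate: float = 0.02,
    delta_ep: float = 0.059,
    peak_current: float = 1e-6,
    e_window: float = 0.35,
    n_points: int = 400,
    noise: float = 0.0,
    seed: int = 0,
    reference_offset: float = 0.206,
):
    """Synthetic one-cycle voltammogram with a reversible couple.

    Bell-shaped anodic/cathodic waves centered ``delta_ep`` apart about
    ``e0_vs_ref`` (the default 59 mV separation is the Nernstian
    one-electron benchmark at 25 C).  Returns a
    :class:`~minimet.biophys.Voltammogram`.
    """
    from .biophys import Voltammogram

    rng = np.random.default_rng(seed)
    half = n_points // 2
    e_fwd = np.linspace(e0_vs_ref - e_window, e0_vs_ref + e_window, half)
    e_rev = e_fwd[::-1]
    width = 0.025

    def bell(E, center):
        return 1.0 / np.cosh((E - center) / width) ** 2

    i_fwd = peak_current * bell(e_fwd, e0_vs_ref + delta_ep / 2)
    i_rev = -peak_current * bell(e_rev, e0_vs_ref - delta_ep / 2)
    E = np.concatenate([e_fwd, e_rev])
    I = np.concatenate([i_fwd, i_rev])
    if noise > 0:
        I = I + rng.normal(0.0, noise * peak_current, len(I))
    return Voltammogram(potential=E, current=I, scan_rate=scan_rate,
                        reference_offset=reference_offset)
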