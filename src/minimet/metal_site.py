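"""First- and second-coordination-sphere analysis of M(Cys)4 centers.

A tetrathiolate site is described by its four M-S distances, six
S-M-S angles (ideal tetrahedron: arccos(-1/3) = 109.47 degrees), the
two Sgamma-M-Sgamma-Cbeta torsions across the pseudo-dyad, and the
cysteine chi1 rotamers.  The second sphere is the set of N-H...Sgamma
hydrogen bonds that tune the sulfur electron density (and with it the
redox potential); crystal-packing contacts with symmetry mates are
reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry_core import angle, chi1, chi1_class, dihedral, distance
from .motif_annotator import HBond, build_amide_hydrogen
from .structure_io import Atom, Residue, Structure, StructureError, expand_symmetry

__all__ = [
    "MetalSite",
    "MetalSiteReport",
    "ReferenceStats",
    "Contact",
    "RUBREDOXIN_ZN_REFERENCE",
    "TETRAHEDRAL_ANGLE",
    "find_metal_site",
    "first_shell_geometry",
    "detect_nh_s_hbonds",
    "crystal_contact_report",
    "compare_to_reference",
    "analyze_site",
]

TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...

NH_S_CRITERIA = {"d_NS_max": 3.6, "d_HS_max": 2.9, "angle_NHS_min": 120.0}

_SALT_BRIDGE_DONORS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
_SALT_BRIDGE_ACCEPTORS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_SIDECHAIN_DONORS = {
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "ARG": ("NE", "NH1", "NH2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}


@dataclass
class MetalSite:
    metal: Atom
    metal_residue: Residue
    ligands: list[tuple[Residue, Atom]]

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)


@dataclass
class ReferenceStats:
    """Survey statistics for M-S bond geometry (defaults: the
    ultrahigh-resolution Zn-rubredoxin survey values)."""

    mean_distance: float
    sd_distance: float
    mean_angle: float
    sd_angle: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.sd_distance < 0 or self.sd_angle < 0:
            raise ValueError("reference standard deviations must be non-negative")


RUBREDOXIN_ZN_REFERENCE = ReferenceStats(
    mean_distance=2.34,
    sd_distance=0.03,
    mean_angle=109.0,
    sd_angle=4.0,
    source="ultrahigh-resolution Zn-rubredoxin survey",
)


@dataclass
class Contact:
    atom: tuple[str, int, str, str]  # chain, seq, resname, atom
    mate_atom: tuple[str, int, str, str]
    mate_operator: str
    distance: float
    kind: str  # salt-bridge, h-bond, contact


@dataclass
class MetalSiteReport:
    metal_element: str
    metal_seq: tuple[str, int]
    ligand_ids: list[tuple[str, int, str]] = field(default_factory=list)
    distances: list[float] = field(default_factory=list)
    mean_distance: float = float("nan")
    sd_distance: float = float("nan")
    angles: list[float] = field(default_factory=list)
    mean_angle: float = float("nan")
    sd_angle: float = float("nan")
    torsions: list[float] = field(default_factory=list)
    tetrahedricity: float = float("nan")
    chi1_classes: dict[str, str] = field(default_factory=dict)
    nh_s_hbonds: list[HBond] = field(default_factory=list)
    sidechain_hbonds: list[HBond] = field(default_factory=list)
    crystal_contacts: list[Contact] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "metal": {"element": self.metal_element, "chain": self.metal_seq[0], "seq": self.metal_seq[1]},
            "ligands": [{"chain": c, "seq": s, "name": n} for c, s, n in self.ligand_ids],
            "distances": self.distances,
            "mean_distance": self.mean_distance,
            "sd_distance": self.sd_distance,
            "angles": self.angles,
            "mean_angle": self.mean_angle,
            "sd_angle": self.sd_angle,
            "torsions": self.torsions,
            "tetrahedricity": self.tetrahedricity,
            "chi1_classes": self.chi1_classes,
            "nh_s_hbonds": [vars(b) for b in self.nh_s_hbonds],
            "sidechain_hbonds": [vars(b) for b in self.sidechain_hbonds],
            "crystal_contacts": [vars(c) for c in self.crystal_contacts],
            "flags": self.flags,
        }
        return d


def find_metal_site(
    structure: Structure,
    metal_element: str,
    max_bond: float = 2.8,
    metal_seq: tuple[str, int] | None = None,
) -> MetalSite:
    """Locate the metal and its coordinating donor atoms.

    Ligands are sulfur/oxygen/nitrogen donor atoms (outside the metal's
    own residue) within ``max_bond`` Angstrom.  Multiple metal atoms of
    the requested element require an explicit ``metal_seq`` selector.
    """
    elem = metal_element.capitalize()
    metals = []
    for chain_id, chain in structure.chains.items():
        for res in chain:
            for atom in res.atoms:
                if atom.element.capitalize() == elem:
                    metals.append((res, atom))
    if metal_seq is not None:
        metals = [(r, a) for r, a in metals if (r.chain_id, r.seq_id) == tuple(metal_seq)]
    if not metals:
        raise StructureError(f"no {metal_element} atom found")
    if len(metals) > 1:
        raise StructureError(
            f"{len(metals)} {metal_element} atoms present; pass metal_seq to disambiguate"
        )
    metal_res, metal = metals[0]
    ligands = []
    for chain_id, chain in structure.chains.items():
        for res in chain:
            if res is metal_res:
                continue
            for atom in res.atoms:
                if atom.element.upper() in ("S", "O", "N") and distance(
                    atom.coords, metal.coords
                ) <= max_bond:
                    ligands.append((res, atom))
    ligands.sort(key=lambda ra: (ra[0].chain_id, ra[0].seq_id))
    return MetalSite(metal=metal, metal_residue=metal_res, ligands=ligands)


def first_shell_geometry(site: MetalSite) -> MetalSiteReport:
    """Distances, angles, cross-dyad torsions and tetrahedricity of a
    4-coordinate site.

    The two Sgamma-M-Sgamma-Cbeta torsions pair ligand k with ligand
    k + 2 in sequence order, the pseudo-dyad partner in a two-half-site
    fold.  Tetrahedricity is the RMS deviation of the six angles from
    the ideal 109.47 degrees.
    """
    report = MetalSiteReport(
        metal_element=site.metal.element,
        metal_seq=(site.metal_residue.chain_id, site.metal_residue.seq_id),
    )
    report.ligand_ids = [(r.chain_id, r.seq_id, a.name) for r, a in site.ligands]
    n = site.coordination_number
    if n != 4:
        report.flags.append(f"coordination number {n} (expected 4)")
    m = site.metal.coords
    report.distances = [distance(a.coords, m) for _, a in site.ligands]
    report.mean_distance = float(np.mean(report.distances)) if report.distances else float("nan")
    report.sd_distance = float(np.std(report.distances, ddof=1)) if n > 1 else float("nan")
    report.angles = [
        angle(site.ligands[i][1].coords, m, site.ligands[j][1].coords)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    if report.angles:
        report.mean_angle = float(np.mean(report.angles))
        report.sd_angle = float(np.std(report.angles, ddof=1)) if len(report.angles) > 1 else float("nan")
        report.tetrahedricity = float(
            np.sqrt(np.mean([(a - TETRAHEDRAL_ANGLE) ** 2 for a in report.angles]))
        )
    if n == 4:
        half = n // 2
        for k in range(half):
            res_a, atom_a = site.ligands[k]
            res_b, atom_b = site.ligands[k + half]
            if res_b.has_atoms("CB"):
                report.torsions.append(
                    dihedral(atom_a.coords, m, atom_b.coords, res_b.atom("CB").coords)
                )
    for res, _ in site.ligands:
        try:
            report.chi1_classes[f"{res.name}{res.seq_id}"] = chi1_class(chi1(res))
        except StructureError:
            pass
    return report


def detect_nh_s_hbonds(
    structure: Structure,
    sgamma_atoms: list[tuple[Residue, Atom]],
    criteria: dict | None = None,
) -> tuple[list[HBond], list[HBond]]:
    """N-H...Sgamma hydrogen bonds onto the given thiolate acceptors.

    Backbone amides use the full criteria (donor-acceptor distance,
    built-H-acceptor distance, N-H...S angle).  Side-chain donors
    (Asn/Gln amides, Arg guanidine, Ser/Thr/Tyr hydroxyls) use
    heavy-atom criteria only (distance plus antecedent-donor-acceptor
    angle >= 90 degrees), since their proton positions are rotatable.

    Returns (backbone bonds, side-chain bonds).
    """
    crit = dict(NH_S_CRITERIA)
    if criteria:
        crit.update(criteria)
    backbone: list[HBond] = []
    sidechain: list[HBond] = []
    accept = [(r, a) for r, a in sgamma_atoms]
    for chain_id, chain in structure.chains.items():
        for i, res in enumerate(chain):
            # backbone N-H
            h = None
            if res.has_atoms("H"):
                h = res.atom("H").coords
            elif i > 0:
                h = build_amide_hydrogen(chain[i - 1], res)
            if h is not None and res.has_atoms("N"):
                npos = res.atom("N").coords
                for ares, aatom in accept:
                    if ares is res:
                        continue
                    d_ns = distance(npos, aatom.coords)
                    if d_ns > crit["d_NS_max"]:
                        continue
                    d_hs = distance(h, aatom.coords)
                    if d_hs > crit["d_HS_max"]:
                        continue
                    if angle(npos, h, aatom.coords) < crit["angle_NHS_min"]:
                        continue
                    backbone.append(
                        HBond((chain_id, res.seq_id, "N"),
                              (ares.chain_id, ares.seq_id, aatom.name), d_ns)
                    )
            # side-chain donors, heavy-atom criteria
            for dname in _SIDECHAIN_DONORS.get(res.name, ()):
                if not res.has_atoms(dname):
                    continue
                dpos = res.atom(dname).coords
                antecedent = _donor_antecedent(res, dname)
                for ares, aatom in accept:
                    if ares is res:
                        continue
                    d = distance(dpos, aatom.coords)
                    if d > crit["d_NS_max"]:
                        continue
                    if antecedent is not None and angle(antecedent, dpos, aatom.coords) < 90.0:
                        continue
                    sidechain.append(
                        HBond((chain_id, res.seq_id, dname),
                              (ares.chain_id, ares.seq_id, aatom.name), d)
                    )
    return backbone, sidechain


def _donor_antecedent(res: Residue, donor_name: str) -> np.ndarray | None:
    antecedents = {
        "ND2": "CG", "NE2": "CD", "NE": "CD", "NH1": "CZ", "NH2": "CZ",
        "OG": "CB", "OG1": "CB", "OH": "CZ",
    }
    name = antecedents.get(donor_name)
    if name and res.has_atoms(name):
        return res.atom(name).coords
    return None


def crystal_contact_report(structure: Structure, radius: float = 4.0) -> list[Contact]:
    """Close contacts between the molecule and its crystallographic
    symmetry mates, classified as salt bridges, hydrogen bonds or
    generic contacts.

    A salt bridge is an Arg/Lys side-chain nitrogen within 4.0 Angstrom
    of an Asp/Glu carboxylate oxygen; an H-bond is any N/O/S pair within
    3.6 Angstrom; everything else within ``radius`` is a generic
    contact.  Requires the unit cell and symmetry operators.
    """
    if structure.unit_cell is None or not structure.sym_ops:
        raise StructureError("crystal_contact_report requires cell and symmetry operators")
    mates = expand_symmetry(structure, radius)
    atoms = []
    for chain_id, chain in structure.chains.items():
        for res in chain:
            for atom in res.atoms:
                if atom.element.upper() != "H":
                    atoms.append((chain_id, res, atom))
    contacts: list[Contact] = []
    for mate in mates:
        op = mate.name.split("|")[-1]
        mate_atoms = []
        for chain_id, chain in mate.chains.items():
            for res in chain:
                for atom in res.atoms:
                    if atom.element.upper() != "H":
                        mate_atoms.append((chain_id, res, atom))
        for chain_id, res, atom in atoms:
            for mchain, mres, matom in mate_atoms:
                d = distance(atom.coords, matom.coords)
                if d > radius:
                    continue
                kind = "contact"
                pair = ((res.name, atom.name), (mres.name, matom.name))
                if _is_salt_bridge(*pair) or _is_salt_bridge(*pair[::-1]):
                    kind = "salt-bridge"
                elif (
                    d <= 3.6
                    and atom.element.upper() in ("N", "O", "S")
                    and matom.element.upper() in ("N", "O", "S")
                ):
                    kind = "h-bond"
                contacts.append(
                    Contact(
                        atom=(chain_id, res.seq_id, res.name, atom.name),
                        mate_atom=(mchain, mres.seq_id, mres.name, matom.name),
                        mate_operator=op,
                        distance=d,
                        kind=kind,
                    )
                )
    contacts.sort(key=lambda c: c.distance)
    return contacts


def _is_salt_bridge(donor: tuple[str, str], acceptor: tuple[str, str]) -> bool:
    dres, datom = donor
    ares, aatom = acceptor
    return (
        datom in _SALT_BRIDGE_DONORS.get(dres, ())
        and aatom in _SALT_BRIDGE_ACCEPTORS.get(ares, ())
    )


def compare_to_reference(
    report: MetalSiteReport, ref: ReferenceStats = RUBREDOXIN_ZN_REFERENCE
) -> dict[str, float]:
    """z-scores of the site's distance/angle descriptors against survey
    statistics: z = (value - mean) / sd."""
    if ref.sd_distance <= 0 or ref.sd_angle <= 0:
        raise ValueError("reference standard deviations must be positive")
    out = {
        "mean_distance": (report.mean_distance - ref.mean_distance) / ref.sd_distance,
        "mean_angle": (report.mean_angle - ref.mean_angle) / ref.sd_angle,
    }
    for i, d in enumerate(report.distances):
        out[f"distance_{i}"] = (d - ref.mean_distance) / ref.sd_distance
    for i, a in enumerate(report.angles):
        out[f"angle_{i}"] = (a - ref.mean_angle) / ref.sd_angle
    return out


def analyze_site(
    structure: Structure,
    metal_element: str = "Zn",
    max_bond: float = 2.8,
    with_crystal_contacts: bool = False,
) -> MetalSiteReport:
    """One-call site analysis: first shell, second-sphere H-bonds and
    (optionally) crystal contacts."""
    site = find_metal_site(structure, metal_element, max_bond=max_bond)
    report = first_shell_geometry(site)
    sgammas = [(r, a) for r, a in site.ligands if a.element.upper() == "S"]
    report.nh_s_hbonds, report.sidechain_hbonds = detect_nh_s_hbonds(structure, sgammas)
    if with_crystal_contacts:
        report.crystal_contacts = crystal_contact_report(structure)
    return report
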