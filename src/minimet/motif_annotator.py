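"""Hydrogen-bond detection and secondary-structure motif assignment.

Backbone H-bonds use the classic electrostatic dipole model
(Kabsch-Sander): partial charges on N-H and C=O give

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

and a pair is bonded when E < -0.5 kcal/mol.  Amide hydrogens missing
from the file are built geometrically.  On top of the H-bond list the
module assigns the motif vocabulary needed for miniature scaffolds:
3_10-helix (consecutive i->i+3 bonds), isolated alpha-turns (i->i+4),
beta strands/bridges/bulges (ladder rules), and the classical beta-turn
types I/I'/II/II'/VIII/III/III' from the central phi/psi pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry_core import dihedral, distance
from .structure_io import Residue, Structure

__all__ = [
    "HBond",
    "TurnAssignment",
    "CANONICAL_TURNS",
    "build_amide_hydrogen",
    "assign_backbone_hbonds",
    "classify_beta_turn",
    "annotate_motifs",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0  # kcal/mol * Angstrom, dipole partial charges
_NEIGHBOR_CUTOFF = 5.2  # O..N prefilter, Angstrom

# canonical (phi_i+1, psi_i+1, phi_i+2, psi_i+2) of the classical types;
# primed types are exact mirror images of the unprimed ones
CANONICAL_TURNS: dict[str, tuple[float, float, float, float]] = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
    "III": (-60.0, -30.0, -60.0, -30.0),
    "III'": (60.0, 30.0, 60.0, 30.0),
}
TURN_TOLERANCE = 30.0  # degrees on each angle ...
TURN_TOLERANCE_ONE = 45.0  # ... with one angle allowed this far off
TURN_CA_MAX = 7.0  # Ca(i)-Ca(i+3) chain-reversal criterion, Angstrom


@dataclass
class HBond:
    """Donor -> acceptor hydrogen bond.

    ``donor``/``acceptor`` are (chain_id, seq_id, atom_name) triples.
    ``energy`` is the Kabsch-Sander electrostatic energy for
    backbone-backbone pairs and ``nan`` for geometric (side-chain)
    detections.
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    distance_da: float
    energy: float = float("nan")


@dataclass
class TurnAssignment:
    start_seq: int
    kind: str  # I, I', II, II', VIII, III, III', IV or "none"
    dihedrals: tuple[float, float, float, float] | None = None
    ca_distance: float = float("nan")
    deviation: float = float("nan")  # summed angular deviation from the canon


# ---------------------------------------------------------------------------
# amide hydrogens


def build_amide_hydrogen(prev_res: Residue, res: Residue) -> np.ndarray | None:
    """Geometric backbone amide H: 1.0 Angstrom from N along the
    external bisector of the C(prev)-N and CA-N bonds.

    Returns None for prolines (no amide H) or incomplete backbones.
    """
    if res.name == "PRO":
        return None
    if not (res.has_atoms("N", "CA") and prev_res.has_atoms("C")):
        return None
    n = res.atom("N").coords
    v1 = n - prev_res.atom("C").coords
    v2 = n - res.atom("CA").coords
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    h_dir = v1 + v2
    norm = np.linalg.norm(h_dir)
    if norm < 1e-6:
        return None
    return n + h_dir / norm


def _chain_backbone(chain: list[Residue]):
    """Per-residue backbone record with built H (None at N-termini/Pro)."""
    out = []
    for i, res in enumerate(chain):
        rec = {"res": res, "H": None}
        if res.has_atoms("H"):
            rec["H"] = res.atom("H").coords
        elif i > 0:
            rec["H"] = build_amide_hydrogen(chain[i - 1], res)
        out.append(rec)
    return out


def assign_backbone_hbonds(
    structure: Structure, energy_cutoff: float = HBOND_ENERGY_CUTOFF
) -> list[HBond]:
    """All backbone N-H...O=C hydrogen bonds with Kabsch-Sander energy
    below ``energy_cutoff``.

    Residues missing the carbonyl O are skipped; pairs closer than two
    residues along the same chain are excluded.
    """
    donors = []  # (chain, index, seq, N, H)
    acceptors = []  # (chain, index, seq, C, O)
    for chain_id, chain in structure.chains.items():
        recs = _chain_backbone(chain)
        for i, rec in enumerate(recs):
            res = rec["res"]
            if rec["H"] is not None and res.has_atoms("N"):
                donors.append((chain_id, i, res.seq_id, res.atom("N").coords, rec["H"]))
            if res.has_atoms("C", "O"):
                acceptors.append((chain_id, i, res.seq_id, res.atom("C").coords, res.atom("O").coords))
    bonds = []
    for dc, di, dseq, N, H in donors:
        for ac, ai, aseq, C, O in acceptors:
            if dc == ac and abs(di - ai) < 2:
                continue
            r_on = distance(O, N)
            if r_on > _NEIGHBOR_CUTOFF:
                continue
            e = _Q1Q2_F * (1 / r_on + 1 / distance(C, H) - 1 / distance(O, H) - 1 / distance(C, N))
            if e < energy_cutoff:
                bonds.append(HBond((dc, dseq, "N"), (ac, aseq, "O"), r_on, e))
    return bonds


# ---------------------------------------------------------------------------
# beta turns


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def classify_beta_turn(residues: list[Residue]) -> TurnAssignment:
    """Classify four consecutive residues as a beta-turn type.

    Requires phi/psi of the two central residues and the chain-reversal
    criterion Ca(i)-Ca(i+3) <= 7 Angstrom (otherwise kind="none").  The
    nearest canonical type with all four angles within +/-30 degrees
    (one allowed +/-45) wins; anything reversing the chain without a
    canonical match is type IV.  Types III/III' (3_10-like) are kept
    distinct from I/I'; on a near-tie the smaller summed deviation wins,
    with III'/III preferred only when psi(i+2) is more than 25 degrees
    from 0.
    """
    if len(residues) != 4:
        raise ValueError("classify_beta_turn expects exactly 4 residues")
    r1, r2, r3, r4 = residues
    ca_d = distance(r1.atom("CA").coords, r4.atom("CA").coords)
    if ca_d > TURN_CA_MAX:
        return TurnAssignment(start_seq=r1.seq_id, kind="none", ca_distance=ca_d)
    phi2 = dihedral(r1.atom("C").coords, r2.atom("N").coords, r2.atom("CA").coords, r2.atom("C").coords)
    psi2 = dihedral(r2.atom("N").coords, r2.atom("CA").coords, r2.atom("C").coords, r3.atom("N").coords)
    phi3 = dihedral(r2.atom("C").coords, r3.atom("N").coords, r3.atom("CA").coords, r3.atom("C").coords)
    psi3 = dihedral(r3.atom("N").coords, r3.atom("CA").coords, r3.atom("C").coords, r4.atom("N").coords)
    obs = (phi2, psi2, phi3, psi3)

    candidates = []
    for kind, canon in CANONICAL_TURNS.items():
        devs = [_angdiff(o, c) for o, c in zip(obs, canon)]
        within = sum(d <= TURN_TOLERANCE for d in devs)
        if within == 4 or (within == 3 and max(devs) <= TURN_TOLERANCE_ONE):
            candidates.append((kind, sum(devs)))
    if not candidates:
        return TurnAssignment(r1.seq_id, "IV", obs, ca_d)
    candidates.sort(key=lambda kd: kd[1])
    kind, dev = candidates[0]
    # I vs III (and mirrored) disambiguation on a near-tie
    pairs = {"I": "III", "I'": "III'", "III": "I", "III'": "I'"}
    if kind in pairs and len(candidates) > 1:
        other = next((c for c in candidates[1:] if c[0] == pairs[kind]), None)
        if other is not None and abs(other[1] - dev) < 1e-9:
            psi3_dev0 = _angdiff(psi3, 0.0)
            kind = (
                ("III'" if "'" in kind else "III")
                if psi3_dev0 > 25.0
                else ("I'" if "'" in kind else "I")
            )
    return TurnAssignment(r1.seq_id, kind, obs, ca_d, dev)


# ---------------------------------------------------------------------------
# motif annotation


@dataclass
class Motif:
    kind: str  # strand, alpha-turn, 3_10, beta-bulge, turn:<type>
    chain_id: str
    start_seq: int
    end_seq: int


@dataclass
class MotifAnnotation:
    labels: dict[tuple[str, int], str] = field(default_factory=dict)
    motifs: list[Motif] = field(default_factory=list)
    strand_pairs: list[tuple[tuple[str, int, int], tuple[str, int, int]]] = field(
        default_factory=list
    )
    hbonds: list[HBond] = field(default_factory=list)


def _bridge_partners(chain_index, hb_set):
    """DSSP-style bridge detection across all residue pairs.

    chain_index: dict (chain, seq) -> (chain, pos-in-chain, list) for
    neighbor lookup.  Returns set of frozenset bridges.
    """
    bridges = set()
    keys = list(chain_index)
    for a in keys:
        for b in keys:
            if a >= b:
                continue
            ca, ia, la = chain_index[a]
            cb, ib, lb = chain_index[b]
            if ca == cb and abs(ia - ib) < 3:
                continue

            def seq(chain, lst, i):
                return (chain, lst[i].seq_id) if 0 <= i < len(lst) else None

            # antiparallel: (i->j and j->i) or (i-1 -> j+1 and j-1 -> i+1)
            anti = ((a, b) in hb_set and (b, a) in hb_set) or (
                (seq(ca, la, ia - 1), seq(cb, lb, ib + 1)) in hb_set
                and (seq(cb, lb, ib - 1), seq(ca, la, ia + 1)) in hb_set
            )
            # parallel: (i-1 -> j and j -> i+1) or (j-1 -> i and i -> j+1)
            par = (
                (seq(ca, la, ia - 1), b) in hb_set and (b, seq(ca, la, ia + 1)) in hb_set
            ) or ((seq(cb, lb, ib - 1), a) in hb_set and (a, seq(cb, lb, ib + 1)) in hb_set)
            if anti or par:
                bridges.add((a, b, "A" if anti else "P"))
    return bridges


def annotate_motifs(structure: Structure, hbonds: list[HBond] | None = None) -> MotifAnnotation:
    """Per-residue secondary-structure labels and an ordered motif list.

    Assignment rules (H-bond (i, j) meaning N-H of i donates to O=C of j):

    * 3_10-helix: two consecutive i->i+3 bonds label the spanned turn
      residues ``G``.
    * alpha-turn: an isolated i->i+4 bond labels the three corner
      residues ``T``.
    * strand/bridge: Kabsch-Sander ladder rules; ladder residues are
      ``E``; a one-residue interruption on one strand of a ladder is a
      beta-bulge (``B`` on the extra residue).
    * beta-turns: distance + dihedral classification of every 4-residue
      window not inside a helix, reported as ``turn:<type>`` motifs.
    """
    ann = MotifAnnotation()
    ann.hbonds = assign_backbone_hbonds(structure) if hbonds is None else hbonds
    hb_set = {(b.donor[:2], b.acceptor[:2]) for b in ann.hbonds}

    for chain_id, chain in structure.chains.items():
        for res in chain:
            ann.labels[(chain_id, res.seq_id)] = "-"

    # helix patterns within each chain
    for chain_id, chain in structure.chains.items():
        n = len(chain)
        turn3 = [
            ((chain_id, chain[i + 3].seq_id), (chain_id, chain[i].seq_id)) in hb_set
            for i in range(max(n - 3, 0))
        ]
        turn4 = [
            ((chain_id, chain[i + 4].seq_id), (chain_id, chain[i].seq_id)) in hb_set
            for i in range(max(n - 4, 0))
        ]
        for i in range(len(turn3) - 1):
            if turn3[i] and turn3[i + 1]:
                for k in range(i + 1, i + 4):
                    ann.labels[(chain_id, chain[k].seq_id)] = "G"
                ann.motifs.append(Motif("3_10", chain_id, chain[i].seq_id, chain[i + 4].seq_id))
        for i, t4 in enumerate(turn4):
            prev4 = turn4[i - 1] if i > 0 else False
            next4 = turn4[i + 1] if i + 1 < len(turn4) else False
            if t4 and not prev4 and not next4:
                for k in range(i + 1, i + 4):
                    if ann.labels[(chain_id, chain[k].seq_id)] == "-":
                        ann.labels[(chain_id, chain[k].seq_id)] = "T"
                ann.motifs.append(
                    Motif("alpha-turn", chain_id, chain[i].seq_id, chain[i + 4].seq_id)
                )
            elif t4 and (prev4 or next4):
                # consecutive i->i+4 bonds: alpha-helix, labeled H
                for k in range(i + 1, i + 4):
                    ann.labels[(chain_id, chain[k].seq_id)] = "H"

    # bridges and ladders
    chain_index = {}
    for chain_id, chain in structure.chains.items():
        for i, res in enumerate(chain):
            chain_index[(chain_id, res.seq_id)] = (chain_id, i, chain)
    bridges = _bridge_partners(chain_index, hb_set)
    # group bridges into ladders: consecutive (i, j) with i+1 paired to j-1 (anti) or j+1 (par)
    bridge_list = sorted(bridges)
    used = set()
    ladders = []
    for br in bridge_list:
        if br in used:
            continue
        a, b, sense = br
        ladder = [br]
        used.add(br)
        cur = br
        while True:
            (ca, sa), (cb, sb), s = cur[0], cur[1], cur[2]
            nxt_b = sb - 1 if s == "A" else sb + 1
            candidate = ((ca, sa + 1), (cb, nxt_b), s)
            candidate_r = ((cb, nxt_b), (ca, sa + 1), s)
            if candidate in bridges and candidate not in used:
                ladder.append(candidate)
                used.add(candidate)
                cur = candidate
            elif candidate_r in bridges and candidate_r not in used:
                ladder.append(candidate_r)
                used.add(candidate_r)
                cur = ((ca, sa + 1), (cb, nxt_b), s)
            else:
                break
        ladders.append(ladder)
    for ladder in ladders:
        sides = ([p[0] for p in ladder], [p[1] for p in ladder])
        for side in sides:
            for chain_id, seq in side:
                if ann.labels[(chain_id, seq)] in "-T":
                    ann.labels[(chain_id, seq)] = "E"
        s0, s1 = sides
        ann.strand_pairs.append(
            (
                (s0[0][0], min(s[1] for s in s0), max(s[1] for s in s0)),
                (s1[0][0], min(s[1] for s in s1), max(s[1] for s in s1)),
            )
        )
        for side in sides:
            ann.motifs.append(
                Motif("strand", side[0][0], min(s[1] for s in side), max(s[1] for s in side))
            )
    # bulge: two ladders whose strands are separated by one extra residue on one side
    for la in ladders:
        for lb in ladders:
            if la is lb:
                continue
            a_end = la[-1]
            b_start = lb[0]
            if a_end[2] != b_start[2]:
                continue
            (c1, s1e), (c2, s2e) = a_end[0], a_end[1]
            (c3, s3s), (c4, s4s) = b_start[0], b_start[1]
            if c1 == c3 and c2 == c4:
                gap1 = s3s - s1e
                gap2 = abs(s4s - s2e)
                if (gap1 == 1 and gap2 == 2) or (gap1 == 2 and gap2 == 1):
                    chain_id = c1 if gap1 == 2 else c2
                    seq = s1e + 1 if gap1 == 2 else min(s2e, s4s) + 1
                    ann.labels[(chain_id, seq)] = "B"
                    ann.motifs.append(Motif("beta-bulge", chain_id, seq, seq))

    # beta turns outside helices
    for chain_id, chain in structure.chains.items():
        for i in range(len(chain) - 3):
            window = chain[i : i + 4]
            if not all(r.has_atoms("N", "CA", "C") for r in window):
                continue
            if any(ann.labels[(chain_id, r.seq_id)] in "GH" for r in window[1:3]):
                continue
            if window[3].seq_id - window[0].seq_id != 3:
                continue
            ta = classify_beta_turn(list(window))
            if ta.kind not in ("none", "IV"):
                ann.motifs.append(
                    Motif(f"turn:{ta.kind}", chain_id, window[0].seq_id, window[3].seq_id)
                )

    ann.motifs.sort(key=lambda m: (m.chain_id, m.start_seq, m.kind))
    return ann
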