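"""Systematic loop-closure fragment search and grafting.

The pseudo-C2 dimer leaves a gap between the C-terminus of the rotated
copy and the N-terminus of the original fragment.  A fragment library
(directory of PDB files plus a plain-text index) is scanned: for every
gap length L (1..7 intervening residues) every contiguous window of
L+2 residues is superposed by its two anchor residues (N/CA/C/O of the
first and last window residues, one joint rigid fit) onto the stub
pair; windows within the backbone-RMSD cutoff (default 1 Angstrom)
become hits.  Four-residue hits are typed as beta-turns, and the best
hit is grafted to produce a single renumbered chain.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry_core import Transform, distance, superpose
from .motif_annotator import classify_beta_turn
from .structure_io import Residue, Structure, StructureError, read_structure

__all__ = [
    "StubPair",
    "LoopHit",
    "FragmentLibrary",
    "extract_stubs",
    "search_fragments",
    "graft",
    "tabulate_turns",
]

ANCHOR_ATOMS = ("N", "CA", "C", "O")
MAX_GAP = 7
RMSD_CUTOFF = 1.0  # Angstrom, backbone anchor fit
_JUNCTION_OK = (1.2, 1.45)  # peptide C-N range, Angstrom
_JUNCTION_HARD = 2.0  # beyond this the graft is rejected

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "AIB": "B",
}


@dataclass
class StubPair:
    """The two anchor residues flanking the gap to close.

    ``c_side`` precedes the loop in the final chain (the C-terminal
    anchor of the symmetric copy); ``n_side`` follows it (the original
    fragment's N-terminal anchor).
    """

    c_side: Residue
    n_side: Residue

    def anchor_coords(self) -> np.ndarray:
        rows = [self.c_side.atom(a).coords for a in ANCHOR_ATOMS]
        rows += [self.n_side.atom(a).coords for a in ANCHOR_ATOMS]
        return np.array(rows)


@dataclass
class LoopHit:
    source: str
    chain_id: str
    start_seq: int  # seq_id of the window's first (anchor) residue
    gap_length: int
    anchor_rmsd: float
    transform: Transform
    turn_type: str = "none"
    sequence: str = ""  # one-letter codes of the intervening residues

    def __post_init__(self) -> None:
        if not 1 <= self.gap_length <= MAX_GAP:
            raise StructureError(f"gap_length {self.gap_length} outside [1, {MAX_GAP}]")
        if self.anchor_rmsd < 0:
            raise StructureError("anchor_rmsd must be non-negative")


class FragmentLibrary:
    """Directory of PDB files with a tab-separated index (id, chain, path).

    Paths in the index are resolved relative to the index file.  Chains
    are parsed lazily and cached.
    """

    def __init__(self, index_path: str | Path):
        self.index_path = Path(index_path)
        if self.index_path.is_dir():
            self.index_path = self.index_path / "index.tsv"
        if not self.index_path.exists():
            raise StructureError(f"no library index at {self.index_path}")
        self.entries: list[tuple[str, str, Path]] = []
        with open(self.index_path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                sid, chain, relpath = row[0], row[1], row[2]
                self.entries.append((sid, chain, self.index_path.parent / relpath))
        self._cache: dict[Path, Structure] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def chains(self):
        """Yield (structure_id, chain_id, residue list)."""
        for sid, chain_id, path in self.entries:
            if path not in self._cache:
                self._cache[path] = read_structure(path)
            st = self._cache[path]
            if chain_id in st.chains:
                yield sid, chain_id, st.chains[chain_id]


def extract_stubs(dimer: Structure) -> StubPair:
    """Anchor residues of a two-chain dimer: the last residue of the
    second chain (C-side) and the first residue of the first chain
    (N-side).

    Chains holding only hetero atoms (the metal) are ignored.
    """
    peptide_chains = [
        chain
        for chain in dimer.chains.values()
        if any(r.has_atoms("CA") for r in chain)
    ]
    if len(peptide_chains) != 2:
        raise StructureError(
            f"extract_stubs needs exactly two peptide chains, found {len(peptide_chains)}"
        )
    c_side = peptide_chains[1][-1]
    n_side = peptide_chains[0][0]
    for res, role in ((c_side, "C-side"), (n_side, "N-side")):
        missing = [a for a in ANCHOR_ATOMS if not res.has_atoms(a)]
        if missing:
            raise StructureError(
                f"{role} anchor {res.name}{res.seq_id} is missing atoms: {', '.join(missing)}"
            )
    return StubPair(c_side=c_side, n_side=n_side)


def _windows(chain: list[Residue], size: int):
    """Contiguous complete-backbone windows of ``size`` residues."""
    for i in range(len(chain) - size + 1):
        window = chain[i : i + size]
        if window[-1].seq_id - window[0].seq_id != size - 1:
            continue  # numbering break
        if not all(r.has_atoms(*ANCHOR_ATOMS) for r in window):
            continue
        # geometric chain breaks: consecutive C-N beyond a stretched bond
        broken = any(
            distance(window[k].atom("C").coords, window[k + 1].atom("N").coords) > 2.5
            for k in range(size - 1)
        )
        if broken:
            continue
        yield i, window


def search_fragments(
    library: FragmentLibrary,
    stubs: StubPair,
    max_gap: int = MAX_GAP,
    rmsd_cutoff: float = RMSD_CUTOFF,
) -> tuple[list[LoopHit], dict[int, int]]:
    """Scan the library for gap-closing fragments.

    Returns hits sorted by anchor RMSD (ascending) and the per-gap-length
    hit histogram.  Four-residue hits carry their beta-turn type.
    """
    if rmsd_cutoff < 0:
        raise StructureError("rmsd_cutoff must be non-negative")
    target = stubs.anchor_coords()
    hits: list[LoopHit] = []
    histogram: dict[int, int] = {}
    for sid, chain_id, chain in library.chains():
        for gap in range(1, max_gap + 1):
            for i, window in _windows(chain, gap + 2):
                mobile = np.array(
                    [window[0].atom(a).coords for a in ANCHOR_ATOMS]
                    + [window[-1].atom(a).coords for a in ANCHOR_ATOMS]
                )
                res = superpose(mobile, target)
                if res.rmsd <= rmsd_cutoff:
                    seq = "".join(_ONE_LETTER.get(r.name, "X") for r in window[1:-1])
                    hit = LoopHit(
                        source=sid,
                        chain_id=chain_id,
                        start_seq=window[0].seq_id,
                        gap_length=gap,
                        anchor_rmsd=res.rmsd,
                        transform=res.transform,
                        sequence=seq,
                    )
                    if gap == 4:
                        moved = [_transformed_residue(r, res.transform) for r in window[1:5]]
                        hit.turn_type = classify_beta_turn(moved).kind
                    hits.append(hit)
                    histogram[gap] = histogram.get(gap, 0) + 1
    hits.sort(key=lambda h: h.anchor_rmsd)
    return hits, histogram


def _transformed_residue(res: Residue, transform: Transform) -> Residue:
    import copy

    out = copy.deepcopy(res)
    for atom in out.atoms:
        atom.coords = transform.apply(atom.coords)
    return out


def _find_window(library: FragmentLibrary, hit: LoopHit) -> list[Residue]:
    for sid, chain_id, chain in library.chains():
        if sid != hit.source or chain_id != hit.chain_id:
            continue
        for i, window in _windows(chain, hit.gap_length + 2):
            if window[0].seq_id == hit.start_seq:
                return window
    raise StructureError(
        f"hit window {hit.source}/{hit.chain_id}/{hit.start_seq} not found in library"
    )


def graft(
    dimer: Structure,
    hit: LoopHit,
    library: FragmentLibrary,
    trim_termini: int = 0,
) -> Structure:
    """Insert the hit's intervening residues between the dimer halves.

    The output is a single chain renumbered 1..N in the order: second
    (rotated) chain, loop residues moved by the hit transform, first
    chain.  Anchor residues keep the scaffold's coordinates.  Junction
    peptide C-N bonds outside [1.2, 1.45] Angstrom attach a geometry
    warning to the structure name; beyond 2.0 Angstrom the hit is
    rejected as ungraftable.  ``trim_termini`` drops that many residues
    from each end of the final chain.
    """
    import copy

    window = _find_window(library, hit)
    loop = [_transformed_residue(r, hit.transform) for r in window[1:-1]]
    peptide_chains = [
        chain for chain in dimer.chains.values() if any(r.has_atoms("CA") for r in chain)
    ]
    if len(peptide_chains) != 2:
        raise StructureError("graft expects a two-peptide-chain dimer")
    ordered = [copy.deepcopy(r) for r in peptide_chains[1]] + loop + [
        copy.deepcopy(r) for r in peptide_chains[0]
    ]
    if trim_termini:
        if trim_termini * 2 >= len(ordered):
            raise StructureError("trim_termini removes the whole chain")
        ordered = ordered[trim_termini : len(ordered) - trim_termini]
    out = Structure(name=f"{dimer.name}_graft_{hit.source}")
    for i, res in enumerate(ordered, start=1):
        res.seq_id = i
        res.chain_id = "A"
        out.add_residue(res)
    # carry the metal over, if present
    for chain in dimer.chains.values():
        for res in chain:
            if not res.has_atoms("CA") and res.atoms:
                out.add_residue(copy.deepcopy(res))
    # junction checks at both splice points
    n_chain2 = len(peptide_chains[1]) - trim_termini
    warnings = []
    for j in (n_chain2, n_chain2 + len(loop)):
        chain = out.chains["A"]
        if 0 < j < len(chain):
            d = distance(chain[j - 1].atom("C").coords, chain[j].atom("N").coords)
            if d > _JUNCTION_HARD:
                raise StructureError(
                    f"ungraftable hit: junction C-N distance {d:.2f} A at residue {j}"
                )
            if not (_JUNCTION_OK[0] <= d <= _JUNCTION_OK[1]):
                warnings.append(f"junction{j}:{d:.2f}A")
    if warnings:
        out.name += "|warning:" + ",".join(warnings)
    return out


def tabulate_turns(hits: list[LoopHit]) -> tuple[Counter, dict[str, float]]:
    """Turn-type counts and positional Gly frequencies for 4-residue hits.

    Returns (Counter of turn types, {"i+1": f, "i+2": f}) where f is the
    fraction of hits carrying Gly at that loop position.
    """
    four = [h for h in hits if h.gap_length == 4]
    counts = Counter(h.turn_type for h in four)
    gly = {"i+1": 0.0, "i+2": 0.0}
    if four:
        gly["i+1"] = sum(1 for h in four if len(h.sequence) > 1 and h.sequence[1] == "G") / len(four)
        gly["i+2"] = sum(1 for h in four if len(h.sequence) > 2 and h.sequence[2] == "G") / len(four)
    return counts, gly
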