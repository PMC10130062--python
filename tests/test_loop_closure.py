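"""Loop-closure fragment search, turn census and grafting."""

import numpy as np
import pytest

from minimet import fixtures
from minimet.geometry_core import Transform, distance
from minimet.loop_closure import (
    FragmentLibrary,
    LoopHit,
    StubPair,
    extract_stubs,
    graft,
    search_fragments,
    tabulate_turns,
)
from minimet.structure_io import Structure, StructureError, write_structure


class TestExtractStubs:
    def test_dimer_stubs_are_terminal_residues(self, dimer, dimer_stubs):
        assert dimer_stubs.n_side.seq_id == dimer.chains["A"][0].seq_id == 38
        assert dimer_stubs.c_side.seq_id == dimer.chains["B"][-1].seq_id == 50
        np.testing.assert_allclose(
            dimer_stubs.n_side.atom("CA").coords, dimer.chains["A"][0].atom("CA").coords
        )

    def test_single_chain_rejected(self):
        st = fixtures.backbone_from_dihedrals([(-60.0, -40.0, 180.0)] * 5)
        with pytest.raises(StructureError):
            extract_stubs(st)

    def test_incomplete_anchor_rejected(self, dimer):
        broken = dimer.copy()
        broken.chains["B"][-1].atoms = [
            a for a in broken.chains["B"][-1].atoms if a.name != "O"
        ]
        with pytest.raises(StructureError, match="O"):
            extract_stubs(broken)


class TestSearch:
    def test_planted_loops_recovered_with_tiny_rmsd(self, planted_library):
        lib, planted = planted_library
        for plant in planted:
            hits, histogram = search_fragments(lib, plant.stubs)
            ours = [h for h in hits if h.source == plant.source]
            assert ours, f"planted {plant.source} not found"
            best = ours[0]
            assert best.gap_length == plant.gap_length
            # coordinates only pass through 3-decimal PDB storage
            assert best.anchor_rmsd < 0.01
            assert histogram[plant.gap_length] >= 1

    def test_gap4_plant_is_typed_as_its_turn(self, planted_library):
        lib, planted = planted_library
        plant = next(p for p in planted if p.gap_length == 4)
        hits, _ = search_fragments(lib, plant.stubs)
        best = next(h for h in hits if h.source == plant.source)
        assert best.turn_type == plant.turn_type == "I'"
        assert best.sequence == "GGGG"

    def test_empty_library(self, tmp_path, planted_library):
        (tmp_path / "index.tsv").write_text("")
        empty = FragmentLibrary(tmp_path)
        _, planted = planted_library
        hits, histogram = search_fragments(empty, planted[0].stubs)
        assert hits == [] and histogram == {}

    def test_zero_cutoff_is_the_limiting_case(self, planted_library):
        lib, planted = planted_library
        stubs = planted[0].stubs
        exact = search_fragments(lib, stubs, rmsd_cutoff=0.0)[0]
        tight = search_fragments(lib, stubs, rmsd_cutoff=0.01)[0]
        loose = search_fragments(lib, stubs, rmsd_cutoff=1.0)[0]
        assert len(exact) <= len(tight) <= len(loose)
        assert all(h.anchor_rmsd == 0.0 for h in exact)

    def test_histogram_monotone_in_cutoff(self, planted_library, dimer_stubs):
        lib, _ = planted_library
        prev: dict[int, int] = {}
        for cutoff in (0.25, 0.5, 1.0, 2.0):
            _, histogram = search_fragments(lib, dimer_stubs, rmsd_cutoff=cutoff)
            for gap in set(prev) | set(histogram):
                assert histogram.get(gap, 0) >= prev.get(gap, 0)
            prev = histogram

    def test_search_is_rigid_motion_invariant(self, planted_library):
        lib, planted = planted_library
        stubs = planted[0].stubs
        base = {(h.source, h.start_seq, h.gap_length): h.anchor_rmsd
                for h in search_fragments(lib, stubs)[0]}
        tf = Transform.about_axis([1.0, 2.0, 3.0], [0.3, -0.5, 0.8], 117.0)
        import copy

        moved = StubPair(
            c_side=copy.deepcopy(stubs.c_side), n_side=copy.deepcopy(stubs.n_side)
        )
        for res in (moved.c_side, moved.n_side):
            for atom in res.atoms:
                atom.coords = tf.apply(atom.coords) + np.array([5.0, -7.0, 2.0])
        after = {(h.source, h.start_seq, h.gap_length): h.anchor_rmsd
                 for h in search_fragments(lib, moved)[0]}
        assert set(base) == set(after)
        for key in base:
            assert after[key] == pytest.approx(base[key], abs=1e-6)

    def test_noisy_plant_recovered_within_3_sigma(self, tmp_path):
        """A planted loop with sigma-jittered coordinates keeps anchor
        RMSD <= 3 sigma (50 seeds, sigma = 0.1 A)."""
        sigma = 0.1
        window = fixtures.backbone_from_dihedrals(
            fixtures._turn_window_dihedrals(4, "I'", np.random.default_rng(7))
        )
        import copy

        chain = window.chains["A"]
        stubs = StubPair(c_side=copy.deepcopy(chain[0]), n_side=copy.deepcopy(chain[-1]))
        lines = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            noisy = window.copy()
            noisy.name = f"noisy{seed:02d}"
            for atom in noisy.atoms():
                atom.coords = atom.coords + rng.normal(0.0, sigma, 3)
            fname = f"noisy{seed:02d}.pdb"
            write_structure(noisy, tmp_path / fname)
            lines.append(f"noisy{seed:02d}\tA\t{fname}")
        (tmp_path / "index.tsv").write_text("\n".join(lines) + "\n")
        lib = FragmentLibrary(tmp_path)
        hits, _ = search_fragments(lib, stubs, rmsd_cutoff=3 * sigma)
        found = {h.source for h in hits if h.gap_length == 4}
        assert len(found) == 50
        assert all(h.anchor_rmsd <= 3 * sigma for h in hits if h.gap_length == 4)


class TestGraft:
    @pytest.fixture()
    def grafted(self, dimer, dimer_stubs, tmp_path):
        """Plant a numerically closed bridge for the dimer and graft it."""
        window, close_rmsd = fixtures.close_gap_loop(dimer_stubs, 4, seed=0)
        assert close_rmsd < 0.05
        write_structure(window, tmp_path / "bridge.pdb")
        (tmp_path / "index.tsv").write_text("bridge\tA\tbridge.pdb\n")
        lib = FragmentLibrary(tmp_path)
        hits, _ = search_fragments(lib, dimer_stubs)
        assert hits and hits[0].gap_length == 4
        return graft(dimer, hits[0], lib), hits[0], lib

    def test_graft_yields_renumbered_single_chain(self, grafted):
        model, hit, _ = grafted
        peptide = [c for k, c in model.chains.items() if k == "A"]
        assert len(peptide) == 1
        assert [r.seq_id for r in peptide[0]] == list(range(1, 31))  # 13 + 4 + 13

    def test_trimming_gives_28(self, dimer, grafted, tmp_path):
        _, hit, lib = grafted
        model = graft(dimer, hit, lib, trim_termini=1)
        assert len(model.chains["A"]) == 28

    def test_junction_bonds_are_peptide_like(self, grafted):
        model, _, _ = grafted
        chain = model.chains["A"]
        for j in (13, 17):  # chain2|loop and loop|chain1 splices
            d = distance(chain[j - 1].atom("C").coords, chain[j].atom("N").coords)
            assert d == pytest.approx(1.33, abs=0.05)

    def test_loop_coordinates_transferred(self, grafted, dimer_stubs):
        model, hit, lib = grafted
        # loop residues sit between the anchors, near both stubs
        loop = model.chains["A"][13:17]
        mid = np.mean([r.atom("CA").coords for r in loop], axis=0)
        assert distance(mid, dimer_stubs.c_side.atom("CA").coords) < 12.0

    def test_displaced_hit_is_ungraftable(self, grafted, dimer):
        model, hit, lib = grafted
        shifted = LoopHit(
            source=hit.source, chain_id=hit.chain_id, start_seq=hit.start_seq,
            gap_length=hit.gap_length, anchor_rmsd=hit.anchor_rmsd,
            transform=Transform(hit.transform.rotation, hit.transform.translation + 5.0),
            sequence=hit.sequence,
        )
        with pytest.raises(StructureError, match="ungraftable"):
            graft(dimer, shifted, lib)


class TestTabulateTurns:
    def test_empty(self):
        counts, gly = tabulate_turns([])
        assert not counts and gly == {"i+1": 0.0, "i+2": 0.0}

    def test_mixed_planted_census(self, tmp_path):
        """5 canonical type I' and 3 canonical type III' planted loops
        are counted as {I': 5, III': 3}; their Gly-rich centers dominate
        the positional Gly frequencies."""
        plants = [(4, "I'")] * 5 + [(4, "III'")] * 3
        seqs = ["GGGG"] * 5 + ["AGGA"] * 3
        lib, planted = fixtures.make_mini_library(
            tmp_path, n_structures=0, planted_loops=plants, seed=5, loop_sequences=seqs
        )
        hits = []
        for plant in planted:
            found, _ = search_fragments(lib, plant.stubs, rmsd_cutoff=0.05)
            hits.append(next(h for h in found if h.source == plant.source))
        counts, gly = tabulate_turns(hits)
        assert counts["I'"] == 5 and counts["III'"] == 3
        assert gly["i+1"] == pytest.approx(1.0)
        assert gly["i+2"] == pytest.approx(1.0)
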