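"""Structure reading, base pairing, substitution and perturbation."""

import io

import numpy as np
import pytest

from tfire import (
    Atom,
    ComplexStructure,
    PerturbationSpec,
    compute_rmsd,
    detect_base_pairs,
    effective_tfbs,
    make_bdna,
    perturb_dna,
    read_complex,
    substitute_base_pair,
    write_complex,
)
from tfire.structure import PAIR_TYPES


class TestReadWrite:
    def test_round_trip_preserves_atoms(self, toy):
        text = write_complex(toy)
        back = read_complex(io.StringIO(text), ["P"], ["D", "E"])
        assert len(back.protein_atoms) == len(toy.protein_atoms)
        assert len(back.dna_atoms) == len(toy.dna_atoms)
        assert [a.name for a in back.dna_atoms] == [a.name for a in toy.dna_atoms]
        assert [a.chain_id for a in back.protein_atoms] == \
            [a.chain_id for a in toy.protein_atoms]
        np.testing.assert_allclose(back.dna_coords(), toy.dna_coords(), atol=1e-3)
        np.testing.assert_allclose(back.protein_coords(), toy.protein_coords(), atol=1e-3)
        assert len(back.base_pairs) == len(toy.base_pairs)
        assert back.Ln == toy.Ln

    def test_partition_follows_chain_lists(self, toy):
        text = write_complex(toy)
        back = read_complex(io.StringIO(text), "P", "D,E")
        assert {a.chain_id for a in back.protein_atoms} == {"P"}
        assert {a.chain_id for a in back.dna_atoms} == {"D", "E"}

    def test_missing_chain_is_named_in_error(self, toy):
        with pytest.raises(ValueError, match="'Q'"):
            read_complex(io.StringIO(write_complex(toy)), ["Q"], ["D", "E"])

    def test_amino_acid_in_dna_chain_rejected(self, toy):
        with pytest.raises(ValueError, match="amino acid"):
            read_complex(io.StringIO(write_complex(toy)), ["D"], ["P", "E"])

    def test_empty_dna_chain_list_rejected(self, toy):
        with pytest.raises(ValueError, match="DNA"):
            read_complex(io.StringIO(write_complex(toy)), ["P"], [])


class TestBasePairs:
    def test_ideal_duplex_pairs_in_order(self):
        duplex = make_bdna("GCCGGTACCGGC")
        assert [bp.position for bp in duplex.base_pairs] == list(range(1, 13))
        assert [bp.pair_type[0] for bp in duplex.base_pairs] == list("GCCGGTACCGGC")

    def test_overhang_excluded_with_warning(self):
        duplex = make_bdna("GCCGGTACCGG")
        # Drop the partner of the first pair: a one-residue 5' overhang.
        partner = duplex.base_pairs[0].strand2_residue
        duplex.dna_atoms = [a for a in duplex.dna_atoms
                            if (a.chain_id, a.residue_index) != partner]
        with pytest.warns(UserWarning, match="could not be paired"):
            pairs = detect_base_pairs(duplex)
        assert len(pairs) == 10

    def test_single_strand_rejected(self):
        duplex = make_bdna("GCGCGC")
        duplex.dna_atoms = [a for a in duplex.dna_atoms if a.chain_id == "D"]
        with pytest.raises(ValueError, match="two DNA strands"):
            detect_base_pairs(duplex)


class TestEffectiveTfbs:
    def test_full_contact_gives_all_positions(self, toy):
        assert toy.tfbs_positions == tuple(range(1, len(toy.base_pairs) + 1))
        assert toy.Ln == len(toy.base_pairs)

    def test_distant_pairs_excluded(self, toy):
        moved = toy.copy()
        far = {bp.strand1_residue for bp in moved.base_pairs[-3:]}
        far |= {bp.strand2_residue for bp in moved.base_pairs[-3:]}
        for atom in moved.dna_atoms:
            if (atom.chain_id, atom.residue_index) in far:
                atom.coords = atom.coords + np.array([60.0, 0.0, 0.0])
        positions = effective_tfbs(moved)
        assert set(positions) == set(range(1, len(moved.base_pairs) - 2))

    def test_monotone_in_cutoff(self, toy):
        inner = set(effective_tfbs(toy, cutoff=4.0))
        outer = set(effective_tfbs(toy, cutoff=10.0))
        assert inner <= outer

    def test_zero_cutoff_means_no_interface(self, toy):
        with pytest.raises(ValueError, match="no interface"):
            effective_tfbs(toy, cutoff=0.0)


class TestSubstitution:
    def test_self_substitution_is_near_exact(self, toy):
        pos = toy.tfbs_positions[3]
        native = toy.pair_by_position(pos).pair_type
        sub = substitute_base_pair(toy, pos, native)
        for key in (toy.pair_by_position(pos).strand1_residue,
                    toy.pair_by_position(pos).strand2_residue):
            before = {a.name: a.coords for a in toy.dna_residues()[key]}
            after = {a.name: a.coords for a in sub.dna_residues()[key]}
            base_names = [n for n in before if "'" not in n and not n.startswith("OP")
                          and n != "P"]
            rmsd = compute_rmsd([before[n] for n in base_names],
                                [after[n] for n in base_names])
            assert rmsd < 0.8
            backbone = [n for n in before if n not in base_names]
            assert compute_rmsd([before[n] for n in backbone],
                                [after[n] for n in backbone]) == 0.0

    @pytest.mark.parametrize("pair_type", PAIR_TYPES)
    def test_only_the_substituted_pair_moves(self, toy, pair_type):
        pos = toy.tfbs_positions[5]
        bp = toy.pair_by_position(pos)
        sub = substitute_base_pair(toy, pos, pair_type)
        assert sub.pair_by_position(pos).pair_type == pair_type
        np.testing.assert_array_equal(sub.protein_coords(), toy.protein_coords())
        pair_keys = {bp.strand1_residue, bp.strand2_residue}
        before = toy.dna_residues()
        after = sub.dna_residues()
        for key, atoms in before.items():
            if key in pair_keys:
                continue
            got = {a.name: a.coords for a in after[key]}
            for a in atoms:
                np.testing.assert_array_equal(a.coords, got[a.name])

    def test_substituted_pair_has_standard_heavy_atom_count(self, toy):
        pos = toy.tfbs_positions[0]
        expected = {"A-T": 19, "C-G": 19, "G-C": 19, "T-A": 19}
        for pair_type, count in expected.items():
            sub = substitute_base_pair(toy, pos, pair_type)
            assert len(sub.pair_base_atoms(pos)) == count

    def test_non_tfbs_position_rejected(self, toy):
        with pytest.raises(ValueError, match="not part"):
            substitute_base_pair(toy, 999, "A-T")

    def test_unknown_pair_type_rejected(self, toy):
        with pytest.raises(ValueError, match="pair type"):
            substitute_base_pair(toy, toy.tfbs_positions[0], "A-C")


class TestPerturbation:
    @pytest.mark.parametrize("group", [1, 2, 3, 4])
    def test_rmsd_lands_in_group_interval(self, toy, group):
        spec = PerturbationSpec(group_n=group, seed=7)
        moved = perturb_dna(toy, spec)
        rmsd = compute_rmsd(toy.dna_coords(), moved.dna_coords())
        assert group - 1 < rmsd <= group

    def test_deterministic_and_protein_fixed(self, toy):
        spec = PerturbationSpec(group_n=1, seed=7)
        a = perturb_dna(toy, spec)
        b = perturb_dna(toy, spec)
        np.testing.assert_array_equal(a.dna_coords(), b.dna_coords())
        np.testing.assert_array_equal(a.protein_coords(), toy.protein_coords())

    def test_rigidity_preserves_internal_distances(self, toy):
        moved = perturb_dna(toy, PerturbationSpec(group_n=3, seed=5))
        rng = np.random.default_rng(0)
        coords_a = toy.dna_coords()
        coords_b = moved.dna_coords()
        idx = rng.choice(len(coords_a), size=(50, 2))
        d_a = np.linalg.norm(coords_a[idx[:, 0]] - coords_a[idx[:, 1]], axis=1)
        d_b = np.linalg.norm(coords_b[idx[:, 0]] - coords_b[idx[:, 1]], axis=1)
        np.testing.assert_allclose(d_a, d_b, atol=1e-9)


class TestRmsd:
    def test_identity_and_translation(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(12, 3))
        assert compute_rmsd(coords, coords) == 0.0
        assert compute_rmsd(coords, coords + [3.0, 0.0, 0.0]) == pytest.approx(3.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        acc = sum(sum((a[i][k] - b[i][k]) ** 2 for k in range(3)) for i in range(10))
        expected = (acc / 10) ** 0.5
        assert compute_rmsd(a, b) == pytest.approx(expected, abs=1e-12)
        assert compute_rmsd(b, a) == pytest.approx(compute_rmsd(a, b), abs=1e-15)

    def test_triangle_like_bound(self):
        rng = np.random.default_rng(3)
        a, b, c = rng.normal(size=(3, 8, 3))
        assert compute_rmsd(a, c) <= compute_rmsd(a, b) + compute_rmsd(b, c) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            compute_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
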