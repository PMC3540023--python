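"""Energy-function derivation: binning, corrections, evaluation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfire import (
    Atom,
    ComplexStructure,
    PotentialConfig,
    accumulate_pairs,
    assign_atom_type,
    build_potential,
    dipolar_weight,
    interaction_energy,
    read_potential,
    smooth,
    train_tfire,
    volume_fraction_factor,
    write_potential,
)
from tfire.potential import AtomType, PairHistogram


def _minimal_pair(distance: float) -> ComplexStructure:
    """One CB probe at the origin, one adenine N6 at the given x offset."""
    protein = [Atom("CB", "ALA", 1, "A", np.zeros(3), "protein")]
    dna = [Atom("N6", "DA", 1, "D", np.array([distance, 0.0, 0.0]), "dna")]
    return ComplexStructure(protein, dna, source_id=f"pair@{distance}")


class TestAtomTypes:
    def test_identity_mapping(self):
        assert assign_atom_type("ALA", "CB") == AtomType("ALA", "CB")

    def test_residue_specificity(self):
        assert assign_atom_type("GUA", "N2") != assign_atom_type("ADE", "N6")
        assert assign_atom_type("DG", "N2") == assign_atom_type("GUA", "N2")

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="HOH"):
            assign_atom_type("HOH", "O")


class TestAccumulate:
    def test_single_pair_lands_in_its_bin(self, plain_config):
        hist = accumulate_pairs([_minimal_pair(5.1)], plain_config)
        (key, bins), = hist.counts.items()
        assert key == (AtomType("ALA", "CB"), AtomType("ADE", "N6"))
        assert bins[int(5.0 / plain_config.delta_r)] == 1.0
        assert bins.sum() == 1.0

    def test_pair_beyond_cutoff_ignored(self, plain_config):
        hist = accumulate_pairs([_minimal_pair(12.0)], plain_config)
        assert hist.total_weight() == 0.0

    def test_empty_training_set_rejected(self, plain_config):
        with pytest.raises(ValueError, match="at least one"):
            accumulate_pairs([], plain_config)

    def test_duplicated_structure_invariant_under_reweight(self, toy):
        config = PotentialConfig(use_smoothing=False, use_dipolar=False)
        single = build_potential(accumulate_pairs([toy], config), [toy], config)
        double = build_potential(accumulate_pairs([toy, toy], config), [toy, toy], config)
        assert single.energies.keys() == double.energies.keys()
        for key in single.energies:
            np.testing.assert_array_equal(single.energies[key], double.energies[key])


class TestSmoothing:
    def test_interior_delta_spreads_to_kernel(self):
        config = PotentialConfig(use_smoothing=True)
        bins = np.zeros(config.n_bins)
        bins[10] = 10.0
        hist = PairHistogram({(AtomType("ALA", "CB"), AtomType("ADE", "N6")): bins},
                             1, config.bin_edges, config)
        out, = smooth(hist, config).counts.values()
        np.testing.assert_allclose(out[8:13], [1.0, 2.0, 4.0, 2.0, 1.0])

    def test_edge_truncation_conserves_mass(self):
        config = PotentialConfig(use_smoothing=True)
        bins = np.zeros(config.n_bins)
        bins[0] = 7.0
        bins[-1] = 3.0
        hist = PairHistogram({(AtomType("ALA", "CB"), AtomType("ADE", "N6")): bins},
                             1, config.bin_edges, config)
        out, = smooth(hist, config).counts.values()
        assert out.sum() == pytest.approx(10.0, abs=1e-9)

    def test_disabled_smoothing_is_identity(self, toy, plain_config):
        hist = accumulate_pairs([toy], plain_config)
        out = smooth(hist, plain_config)
        assert out is hist


class TestVolumeFraction:
    def test_fraction_definition(self):
        protein = [Atom("CA", "GLY", i, "A", np.array([0.0, 0.0, i * 4.0]), "protein")
                   for i in range(6)]
        dna = [Atom("N6", "DA", i, "D", np.array([5.0, 0.0, i * 4.0]), "dna")
               for i in range(4)]
        s = ComplexStructure(protein, dna)
        assert volume_fraction_factor([s]) == (0.6, 0.4)
        assert volume_fraction_factor([s, s]) == (0.6, 0.4)

    def test_single_class_rejected_downstream(self, plain_config):
        config = PotentialConfig(use_smoothing=False, use_dipolar=False,
                                 use_reweight=False, use_volume_fraction=True)
        s = _minimal_pair(5.0)
        s.dna_atoms = []
        hist = accumulate_pairs([_minimal_pair(5.0)], config)
        with pytest.raises(ValueError, match="both molecule classes"):
            build_potential(hist, [s], config)


class TestBuildPotential:
    def test_reference_shaped_counts_give_zero_energy(self):
        config = PotentialConfig(use_smoothing=False, use_dipolar=False,
                                 use_reweight=False, use_volume_fraction=False,
                                 pseudo_count=0.0)
        shape = (config.bin_centers / config.r_cut) ** config.alpha
        hist = PairHistogram({(AtomType("ALA", "CB"), AtomType("ADE", "N6")): 7.0 * shape},
                             1, config.bin_edges, config)
        pot = build_potential(hist, [_minimal_pair(5.0)], config)
        table, = pot.energies.values()
        np.testing.assert_allclose(table, 0.0, atol=1e-9)

    def test_extra_counts_lower_that_bin(self, plain_config):
        key = (AtomType("ALA", "CB"), AtomType("ADE", "N6"))
        base = np.ones(plain_config.n_bins)
        bumped = base.copy()
        bumped[6] *= 2.0
        s = _minimal_pair(5.0)
        pot_a = build_potential(PairHistogram({key: base}, 1, plain_config.bin_edges,
                                              plain_config), [s], plain_config)
        pot_b = build_potential(PairHistogram({key: bumped}, 1, plain_config.bin_edges,
                                              plain_config), [s], plain_config)
        assert pot_b.energies[key][6] < pot_a.energies[key][6]

    def test_reference_self_normalization(self, toy):
        config = PotentialConfig(use_volume_fraction=False, use_dipolar=False)
        hist = smooth(accumulate_pairs([toy], config), config)
        shape = (config.bin_centers / config.r_cut) ** config.alpha
        for bins in hist.counts.values():
            obs = bins + config.pseudo_count
            ref = shape * (obs.sum() / shape.sum())
            assert ref.sum() == pytest.approx(obs.sum(), abs=1e-9)

    def test_queries_beyond_cutoff_are_zero(self, toy_potential):
        key = next(iter(toy_potential.energies))
        assert toy_potential.energy(*key, 10.0) == 0.0
        assert toy_potential.energy(*key, 25.0) == 0.0

    def test_finite_whenever_pseudo_count_positive(self, toy_potential):
        for table in toy_potential.energies.values():
            assert np.all(np.isfinite(table))


class TestDipolarWeight:
    def _atom(self, name, coords):
        return Atom(name, "ALA", 1, "A", np.asarray(coords, dtype=float), "protein")

    def test_apolar_pair_is_unweighted(self):
        a = self._atom("CB", [0, 0, 0])
        b = self._atom("CG", [4, 0, 0])
        assert dipolar_weight(a, [np.array([-1.5, 0, 0])], b, [np.array([5.5, 0, 0])]) == 1.0

    def test_aligned_dipoles_score_one(self):
        a = self._atom("N", [0, 0, 0])
        b = self._atom("O", [4, 0, 0])
        w = dipolar_weight(a, [np.array([-1.4, 0.0, 0.0])],
                           b, [np.array([5.4, 0.0, 0.0])])
        assert w == pytest.approx(1.0)

    def test_opposed_dipoles_score_zero(self):
        a = self._atom("N", [0, 0, 0])
        b = self._atom("O", [4, 0, 0])
        w = dipolar_weight(a, [np.array([1.4, 0.0, 0.0])],
                           b, [np.array([2.6, 0.0, 0.0])])
        assert w == pytest.approx(0.0)

    def test_missing_neighbor_warns_and_defaults(self):
        a = self._atom("N", [0, 0, 0])
        b = self._atom("O", [4, 0, 0])
        with pytest.warns(UserWarning, match="no bonded neighbor"):
            assert dipolar_weight(a, [], b, [np.array([5.4, 0, 0])]) == 1.0

    @given(st.lists(st.floats(-1, 1), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_weight_bounded_for_random_geometry(self, vals):
        v = np.array(vals).reshape(2, 3)
        if np.linalg.norm(v[0]) < 1e-3 or np.linalg.norm(v[1]) < 1e-3:
            return
        a = self._atom("N", [0, 0, 0])
        b = self._atom("O", [3, 1, -1])
        w = dipolar_weight(a, [a.coords + v[0]], b, [b.coords + v[1]])
        assert 0.0 <= w <= 1.0


class TestTrainAndEvaluate:
    def test_tfire_composition_and_training_id(self, toy, toy_potential):
        assert toy_potential.training_ids == [toy.source_id]
        assert len(toy_potential.energies) > 0

    def test_empty_interface_rejected(self):
        s = _minimal_pair(5.0)
        s.protein_atoms[0].coords = np.array([500.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="empty interface"):
            train_tfire(s, PotentialConfig(use_dipolar=False))

    def test_empty_subset_scores_zero(self, toy, toy_potential):
        assert interaction_energy(toy_potential, toy, set()) == 0.0

    def test_additive_over_disjoint_positions(self, toy, toy_potential):
        total = interaction_energy(toy_potential, toy)
        by_position = sum(interaction_energy(toy_potential, toy, {p})
                          for p in toy.tfbs_positions)
        assert by_position == pytest.approx(total, abs=1e-9)

    def test_matches_brute_force_double_loop(self, toy, toy_potential):
        subset = set(toy.tfbs_positions[:3])
        expected = 0.0
        dna = [a for p in sorted(subset) for a in toy.pair_base_atoms(p)]
        for pa in toy.protein_atoms:
            for da in dna:
                r = float(np.linalg.norm(pa.coords - da.coords))
                if r < toy_potential.config.r_cut:
                    expected += toy_potential.energy(
                        assign_atom_type(pa.residue_name, pa.name),
                        assign_atom_type(da.residue_name, da.name), r)
        assert interaction_energy(toy_potential, toy, subset) == \
            pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self, toy, toy_potential):
        moved = toy.copy()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([3.0, -2.0, 11.0])
        for atom in moved.protein_atoms + moved.dna_atoms:
            atom.coords = rot @ atom.coords + shift
        assert interaction_energy(toy_potential, moved) == \
            pytest.approx(interaction_energy(toy_potential, toy), abs=1e-9)


class TestSerialization:
    def test_tsv_round_trip(self, toy_potential):
        text = write_potential(toy_potential)
        back = read_potential(io.StringIO(text))
        assert back.config.r_cut == toy_potential.config.r_cut
        assert back.training_ids == toy_potential.training_ids
        for key, table in toy_potential.energies.items():
            np.testing.assert_allclose(back.energies[key], table, atol=1e-6)
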