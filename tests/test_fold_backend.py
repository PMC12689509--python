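"""Folding contract: enumeration oracle, dynamic-programming equivalence,
Boltzmann ensemble statistics, and input validation."""

import math

import numpy as np
import pytest

from thermoscan.fold_backend import (
    GAS_CONSTANT_KCAL,
    ToyBackend,
    ToyEnergyParams,
    base_pair_distance,
    ensemble_from_enumeration,
    enumerate_structures,
    normalize_rna,
    rt_kcal,
)


class TestEnumeration:
    def test_unpairable_sequence_has_only_empty_structure(self):
        assert enumerate_structures("AAAA") == [(frozenset(), 0.0)]

    def test_gaaac_two_structures(self):
        structures = dict(enumerate_structures("GAAAC"))
        assert structures == {frozenset(): 0.0, frozenset({(0, 4)}): -3.0}

    def test_min_loop_respected_and_stacked_pairs_found(self):
        structures = dict(enumerate_structures("GGAAACC"))
        assert structures[frozenset({(0, 6), (1, 5)})] == -6.0
        for pairs in structures:
            assert all(j - i >= 4 for i, j in pairs)

    def test_no_duplicate_structures(self):
        structures = enumerate_structures("GGCAAAGCC")
        assert len(structures) == len({s for s, _ in structures})

    def test_refuses_long_sequences(self):
        with pytest.raises(ValueError, match="18"):
            enumerate_structures("GC" * 12)


class TestEnsembleFromEnumeration:
    def test_two_equiprobable_structures(self):
        probs, ed, centroid = ensemble_from_enumeration(
            [(frozenset(), 0.0), (frozenset({(0, 8)}), 0.0)], 37.0
        )
        assert probs[(0, 8)] == pytest.approx(0.5)
        assert ed == pytest.approx(0.5)  # E[d] = 2 * 0.25 * 1 over ordered pairs
        assert centroid == frozenset()

    def test_single_structure_is_its_own_centroid(self):
        probs, ed, centroid = ensemble_from_enumeration(
            [(frozenset({(0, 5)}), -2.0)], 25.0
        )
        assert ed == 0.0
        assert centroid == frozenset({(0, 5)})

    def test_gaaac_closed_form(self):
        # two-state ensemble: E in {0, -3}, p = w/(1+w), w = exp(3/RT)
        probs, ed, _ = ensemble_from_enumeration(enumerate_structures("GAAAC"), 37.0)
        w = math.exp(3.0 / (GAS_CONSTANT_KCAL * 310.15))
        p = w / (1.0 + w)
        assert probs[(0, 4)] == pytest.approx(p, abs=1e-12)
        assert probs[(0, 4)] == pytest.approx(0.992, abs=5e-4)
        assert ed == pytest.approx(2 * p * (1 - p), abs=1e-12)


class TestBasePairDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({(0, 8)}, {(0, 8)}, 0),
            ({(0, 8)}, set(), 1),
            ({(0, 8), (1, 7)}, {(0, 8), (2, 6)}, 2),
        ],
    )
    def test_symmetric_difference(self, a, b, expected):
        assert base_pair_distance(a, b) == expected
        assert base_pair_distance(b, a) == expected


class TestToyBackend:
    def test_homopolymer_folds_to_nothing(self, toy_backend):
        fr = toy_backend.fold("AAAAAAAAA", 37.0)
        assert fr.mfe_kcal_mol == 0.0
        assert fr.mfe_pairs == frozenset()
        assert fr.ensemble_diversity == 0.0
        assert fr.centroid_dbn == "." * 9

    def test_triple_gc_hairpin_mfe(self, toy_backend):
        fr = toy_backend.fold("GGGAAACCC", 37.0)
        assert fr.mfe_pairs == frozenset({(0, 8), (1, 7), (2, 6)})
        assert fr.mfe_kcal_mol == pytest.approx(-9.0)

    def test_dp_matches_enumeration_oracle(self, toy_backend):
        """ED, pair probabilities, centroid, and MFE from the dynamic path
        must equal exhaustive-enumeration values (30 random sequences)."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 15))
            seq = "".join(rng.choice(list("ACGU"), n))
            structures = enumerate_structures(seq)
            probs, ed, centroid = ensemble_from_enumeration(structures, 37.0)
            fr = toy_backend.fold(seq, 37.0)
            assert fr.mfe_kcal_mol == pytest.approx(
                min(e for _, e in structures), abs=1e-9
            )
            assert fr.ensemble_diversity == pytest.approx(ed, abs=1e-9)
            assert fr.centroid_pairs == centroid
            keys = set(probs) | set(fr.pair_probabilities)
            for k in keys:
                assert probs.get(k, 0.0) == pytest.approx(
                    fr.pair_probabilities.get(k, 0.0), abs=1e-9
                )

    def test_ed_equals_weighted_average_pair_distance(self, toy_backend):
        """ED must equal the brute-force Boltzmann-weighted mean base-pair
        distance over all ordered structure pairs."""
        rng = np.random.default_rng(11)
        rt = rt_kcal(37.0)
        for _ in range(30):
            n = int(rng.integers(6, 14))
            seq = "".join(rng.choice(list("ACGU"), n))
            structures = enumerate_structures(seq)
            energies = np.array([e for _, e in structures])
            w = np.exp(-energies / rt)
            w /= w.sum()
            brute = sum(
                w[a] * w[b] * base_pair_distance(structures[a][0], structures[b][0])
                for a in range(len(structures))
                for b in range(len(structures))
            )
            assert toy_backend.fold(seq, 37.0).ensemble_diversity == pytest.approx(
                brute, abs=1e-9
            )

    def test_mfe_not_above_any_enumerated_structure(self, toy_backend):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), 12))
            emin = min(e for _, e in enumerate_structures(seq))
            assert toy_backend.fold(seq, 37.0).mfe_kcal_mol <= emin + 1e-12

    def test_fold_result_invariants(self, toy_backend):
        fr = toy_backend.fold("GGCGAAACGCCAUAU", 37.0)
        n = len(fr.sequence)
        per_position = np.zeros(n)
        for (i, j), p in fr.pair_probabilities.items():
            assert 0.0 <= p <= 1.0
            assert j - i >= 4
            per_position[i] += p
            per_position[j] += p
        assert (per_position <= 1.0 + 1e-9).all()
        for p in fr.centroid_pairs:
            assert fr.pair_probabilities[p] > 0.5
        assert fr.ensemble_diversity >= 0.0

    def test_two_state_melting_direction(self, toy_backend):
        """For the two-state hairpin GAAAC, the pair probability strictly
        decreases and ED increases with temperature (pre-melting regime)."""
        temps = [20.0, 30.0, 40.0, 50.0, 60.0]
        ps = [toy_backend.fold("GAAAC", t).pair_probabilities[(0, 4)] for t in temps]
        eds = [toy_backend.fold("GAAAC", t).ensemble_diversity for t in temps]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(a < b for a, b in zip(eds, eds[1:]))


class TestInputValidation:
    def test_empty_sequence_rejected(self, toy_backend):
        with pytest.raises(ValueError, match="empty"):
            toy_backend.fold("", 37.0)

    def test_bad_character_named_in_error(self, toy_backend):
        with pytest.raises(ValueError, match="'X'"):
            toy_backend.fold("ACGX", 37.0)

    def test_t_and_lowercase_normalized(self):
        assert normalize_rna("acgt") == "ACGU"

    def test_ambiguity_codes_allowed_but_never_pair(self, toy_backend):
        fr = toy_backend.fold("GNNNC", 37.0)
        assert (0, 4) in fr.pair_probabilities  # G-C still pairs
        assert all(0 not in (i, j) or (i, j) == (0, 4)
                   for i, j in fr.pair_probabilities)

    def test_temperature_range_enforced(self, toy_backend):
        with pytest.raises(ValueError, match="temperature"):
            toy_backend.fold("GAAAC", 150.0)

    def test_toy_params_validate(self):
        with pytest.raises(ValueError):
            ToyEnergyParams(gc=1.0)
        with pytest.raises(ValueError):
            ToyEnergyParams(min_loop=-1)
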