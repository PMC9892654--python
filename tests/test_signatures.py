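"""Binarization, truth tables, signature derivation and response calls."""

import numpy as np
import pytest

import boolmark as bm
from boolmark.minimize import DONT_CARE, BooleanTerm
from boolmark.signatures import INDETERMINATE


def _matrix(values, feature_ids=None):
    values = np.asarray(values, dtype=float)
    return bm.ExpressionMatrix(
        feature_ids or [f"F{i}" for i in range(values.shape[0])],
        [f"S{j}" for j in range(values.shape[1])],
        values,
        np.zeros_like(values, dtype=bool),
    )


class TestBinarize:
    def test_median_scheme_thresholds(self):
        b = bm.binarize(_matrix([[1.0, 2.0, 8.0, 9.0]]))
        assert b.bits[0].tolist() == [0, 0, 1, 1]

    def test_median_tie_maps_low_by_default(self):
        b = bm.binarize(_matrix([[1.0, 2.0, 2.0, 5.0, 9.0]]))
        assert b.bits[0].tolist() == [0, 0, 0, 1, 1]
        b1 = bm.binarize(_matrix([[1.0, 2.0, 2.0, 5.0, 9.0]]), tie_value=1)
        assert b1.bits[0].tolist() == [0, 1, 1, 1, 1]

    def test_positive_scaling_invariance(self, rng):
        row = rng.uniform(1, 10, 12)
        a = bm.binarize(_matrix([row]))
        b = bm.binarize(_matrix([row * 37.5]))
        assert np.array_equal(a.bits, b.bits)

    def test_log_transform_invariance(self, rng):
        values = rng.uniform(0.5, 20, size=(5, 14))
        a = bm.binarize(_matrix(values))
        b = bm.binarize(_matrix(np.log2(values) + 10))  # keep medians positive
        assert np.array_equal(a.bits, b.bits)

    def test_non_positive_median_names_feature(self):
        with pytest.raises(ValueError, match="F1"):
            bm.binarize(_matrix([[1.0, 2.0, 3.0], [-1.0, -2.0, 0.0]]))

    def test_quantile_band(self):
        row = np.arange(1.0, 11.0)
        b = bm.binarize(_matrix([row]), scheme="quantile_band")
        lo, hi = np.quantile(row, 0.3), np.quantile(row, 0.7)
        expected = [0 if v < lo else (1 if v > hi else INDETERMINATE) for v in row]
        assert b.bits[0].tolist() == expected
        assert b.bits[0].tolist()[:3] == [0, 0, 0]
        assert b.bits[0].tolist()[-3:] == [1, 1, 1]
        assert set(b.bits[0].tolist()[3:7]) == {INDETERMINATE}


def _toy_binarized():
    """Three markers, seven samples: RD patterns {001,011,110,111}, NR {100}."""
    bits = np.array(
        [
            [0, 0, 1, 1, 1, 1, 0],
            [0, 1, 1, 1, 0, 0, 0],
            [1, 1, 0, 1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    b = bm.BinarizedMatrix(
        feature_ids=["A", "B", "C"],
        sample_ids=[f"S{j}" for j in range(7)],
        bits=bits,
        scheme="median",
    )
    labels = bm.ResponseLabels(
        [f"S{j}" for j in range(7)], ["RD"] * 4 + ["NR"] * 3
    )
    return b, labels


class TestTruthTable:
    def test_patterns_and_frequencies(self):
        b, labels = _toy_binarized()
        minterms, freq = bm.group_truth_table(b, labels, "RD")
        assert minterms == {(0, 0, 1), (0, 1, 1), (1, 1, 0), (1, 1, 1)}
        assert sum(freq.values()) == pytest.approx(1.0)
        minterms_nr, freq_nr = bm.group_truth_table(b, labels, "NR")
        assert minterms_nr == {(1, 0, 0), (0, 0, 0)}
        assert freq_nr[(1, 0, 0)] == pytest.approx(2 / 3)

    def test_all_identical_single_pattern(self):
        bits = np.zeros((2, 4), dtype=np.int8)
        b = bm.BinarizedMatrix(["A", "B"], [f"S{j}" for j in range(4)], bits, "median")
        labels = bm.ResponseLabels([f"S{j}" for j in range(4)], ["RD"] * 4)
        minterms, freq = bm.group_truth_table(b, labels, "RD")
        assert minterms == {(0, 0)}
        assert freq[(0, 0)] == 1.0

    def test_empty_group_and_indeterminate_rejected(self):
        b, labels = _toy_binarized()
        with pytest.raises(ValueError, match="no samples"):
            bm.group_truth_table(b, labels, "PR")
        b.bits[0, 0] = INDETERMINATE
        with pytest.raises(ValueError, match="INDETERMINATE"):
            bm.group_truth_table(b, labels, "RD")


class TestSignatures:
    def test_worked_example_signatures(self):
        b, labels = _toy_binarized()
        sets = bm.derive_signatures(b, labels)
        assert {s.term for s in sets["RD"].signatures} == {
            BooleanTerm((0, DONT_CARE, 1)),  # A'C
            BooleanTerm((1, 1, DONT_CARE)),  # AB
        }
        # coverage: A'C matches patterns 001,011 (2 samples); AB matches 110,111
        cov = {s.term.render(["A", "B", "C"]): s.coverage
               for s in sets["RD"].signatures}
        assert cov == {"A′·C": 0.5, "A·B": 0.5}

    def test_ids_ascend_with_term_order(self):
        b, labels = _toy_binarized()
        sets = bm.derive_signatures(b, labels)
        ids = [s.id for s in sets["RD"].signatures]
        assert ids == [1, 2]
        keys = [s.term.sort_key() for s in sets["RD"].signatures]
        assert keys == sorted(keys)

    def test_tautology_group(self):
        bits = np.array([[0, 0, 1, 1], [0, 1, 0, 1]], dtype=np.int8)
        b = bm.BinarizedMatrix(["A", "B"], [f"S{j}" for j in range(4)], bits, "median")
        labels = bm.ResponseLabels([f"S{j}" for j in range(4)], ["RD"] * 4)
        sets = bm.derive_signatures(b, labels)
        assert sets["RD"].signatures[0].term == BooleanTerm((DONT_CARE, DONT_CARE))
        assert sets["RD"].signatures[0].coverage == 1.0

    def test_groups_are_independent(self, rng):
        """Permuting one group's samples never changes another's signatures."""
        b, labels = _toy_binarized()
        base = bm.derive_signatures(b, labels)
        shuffled_bits = b.bits.copy()
        nr_cols = [4, 5, 6]
        shuffled_bits[:, nr_cols] = shuffled_bits[:, rng.permutation(nr_cols)]
        b2 = bm.BinarizedMatrix(b.feature_ids, b.sample_ids, shuffled_bits, "median")
        after = bm.derive_signatures(b2, labels)
        assert {s.term for s in base["RD"].signatures} == {
            s.term for s in after["RD"].signatures
        }

    def test_cross_group_collision_warns(self):
        bits = np.array([[0, 0], [1, 1]], dtype=np.int8)
        b = bm.BinarizedMatrix(["A", "B"], ["S0", "S1"], bits, "median")
        labels = bm.ResponseLabels(["S0", "S1"], ["RD", "NR"])
        with pytest.warns(UserWarning, match="both RD and NR"):
            bm.derive_signatures(b, labels)


class TestMatchAndPredict:
    A_PRIME_C = BooleanTerm((0, DONT_CARE, 1))

    def test_match_semantics(self):
        assert bm.match((0, 1, 1), self.A_PRIME_C)
        assert not bm.match((1, 1, 1), self.A_PRIME_C)
        assert bm.match((INDETERMINATE, 0, 1), self.A_PRIME_C)
        assert not bm.match((0, INDETERMINATE, 0), self.A_PRIME_C)
        with pytest.raises(ValueError):
            bm.match((0, 1), self.A_PRIME_C)

    def test_predict_single_and_no_call(self):
        b, labels = _toy_binarized()
        sets = bm.derive_signatures(b, labels)
        groups, matches = bm.predict_response((0, 0, 1), sets)
        assert groups == {"RD"}
        assert matches == [("RD", 1)]
        groups, matches = bm.predict_response((1, 0, 1), sets)
        assert groups == set() and matches == []

    def test_discovery_round_trip(self, sim_dataset):
        """Median-binarized discovery samples always re-match their group."""
        import warnings

        ds, m = sim_dataset
        panel = sorted(ds.informative_ids)[:5]
        b = bm.binarize(m.subset(panel))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cross-group pattern collisions
            sets = bm.derive_signatures(b, ds.labels)
        for sid, cls in zip(b.sample_ids, ds.labels.classes):
            groups, _ = bm.predict_response(b.sample_bits(sid), sets)
            assert cls in groups

    def test_coverage_positive_and_jointly_complete(self, rng):
        """On random cohorts every group sample satisfies >= 1 signature."""
        for trial in range(20):
            n_feat, n_samp = 4, 15
            bits = (rng.random((n_feat, n_samp)) < 0.5).astype(np.int8)
            classes = rng.choice(bm.CLASSES, size=n_samp).tolist()
            while len(set(classes)) < 2:
                classes = rng.choice(bm.CLASSES, size=n_samp).tolist()
            b = bm.BinarizedMatrix(
                [f"F{i}" for i in range(n_feat)],
                [f"S{j}" for j in range(n_samp)],
                bits, "median",
            )
            labels = bm.ResponseLabels([f"S{j}" for j in range(n_samp)], classes)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sets = bm.derive_signatures(b, labels)
            for g, sset in sets.items():
                assert all(0 < s.coverage <= 1 for s in sset.signatures)
            for sid, cls in zip(b.sample_ids, classes):
                groups, _ = bm.predict_response(b.sample_bits(sid), sets)
                assert cls in groups


def test_serialization_round_trip():
    b, labels = _toy_binarized()
    sets = bm.derive_signatures(b, labels)
    text = bm.signatures_to_json(sets)
    back = bm.signatures_from_json(text)
    assert set(back) == set(sets)
    for g in sets:
        assert [s.term for s in back[g].signatures] == [
            s.term for s in sets[g].signatures
        ]
        assert [s.coverage for s in back[g].signatures] == [
            s.coverage for s in sets[g].signatures
        ]
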