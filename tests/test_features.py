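from collections import Counter

import numpy as np
import pytest

from plantrbp.features import (
    FeatureMatrix,
    SequenceTooShortError,
    append_columns,
    encode_dataset,
    kpc_encode,
    kpc_names,
)
from plantrbp.seqio import AMINO_ACIDS, LabeledSequence


def naive_kpc(residues: str, k: int) -> dict[str, float]:
    """Independent oracle: slide a window and tally counts into a map."""
    total = len(residues) - k + 1
    counts = Counter(residues[i : i + k] for i in range(total))
    return {pep: c / total for pep, c in counts.items()}


def test_tripeptides_of_short_sequence():
    vec = kpc_encode(LabeledSequence("a", "ACDEFG", 1), 3)
    nonzero = {n: v for n, v in zip(vec.names, vec.values) if v > 0}
    assert nonzero == {"ACD": 0.25, "CDE": 0.25, "DEF": 0.25, "EFG": 0.25}
    assert len(vec.values) == 8000


def test_homopolymer_and_dipeptides():
    vec = kpc_encode(LabeledSequence("a", "AAAA", 1), 1)
    assert vec.values[0] == 1.0 and vec.values[1:].sum() == 0.0
    vec2 = kpc_encode(LabeledSequence("a", "ACDEFG", 1), 2)
    nonzero = {n: v for n, v in zip(vec2.names, vec2.values) if v > 0}
    assert nonzero == {"AC": 0.2, "CD": 0.2, "DE": 0.2, "EF": 0.2, "FG": 0.2}


def test_sequence_shorter_than_k_errors():
    with pytest.raises(SequenceTooShortError, match="rec1"):
        kpc_encode(LabeledSequence("rec1", "AC", 1), 3)


def test_kpc_matches_naive_oracle_on_random_sequences(rng):
    """Window-count oracle equivalence over >= 100 random (seq, k) cases."""
    aas = list(AMINO_ACIDS)
    for case in range(120):
        k = int(rng.integers(1, 4))
        L = int(rng.integers(k, 51))
        residues = "".join(rng.choice(aas, size=L))
        vec = kpc_encode(LabeledSequence(f"r{case}", residues, None), k)
        expected = naive_kpc(residues, k)
        got = {n: v for n, v in zip(vec.names, vec.values) if v > 0}
        assert got.keys() == expected.keys()
        for pep in expected:
            assert got[pep] == pytest.approx(expected[pep], abs=1e-12)
        assert vec.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (vec.values >= 0).all()


def test_aac_is_residue_counts_over_length(rng):
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=40))
    vec = kpc_encode(LabeledSequence("x", residues, None), 1)
    for aa, value in zip(AMINO_ACIDS, vec.values):
        assert value == pytest.approx(residues.count(aa) / 40)


def test_shuffling_leaves_composition_unchanged(rng):
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=30))
    shuffled = "".join(rng.permutation(list(residues)))
    v1 = kpc_encode(LabeledSequence("x", residues, None), 1)
    v2 = kpc_encode(LabeledSequence("x", shuffled, None), 1)
    np.testing.assert_array_equal(v1.values, v2.values)


@pytest.mark.parametrize(
    "ks,expected_n", [((1,), 20), ((2,), 400), ((1, 2), 420),
                      ((3,), 8000), ((1, 2, 3), 8420)]
)
def test_dimension_arithmetic(tiny_sequences, ks, expected_n):
    matrix = encode_dataset(tiny_sequences, ks)
    assert matrix.n == expected_n
    assert matrix.n_rows == len(tiny_sequences)
    # each per-k block sums to 1, so a row sums to len(ks)
    np.testing.assert_allclose(matrix.values.sum(axis=1), len(ks), atol=1e-9)


def test_encode_dataset_aggregates_short_sequence_errors(tiny_sequences):
    bad = tiny_sequences + [LabeledSequence("tiny1", "A", 0),
                            LabeledSequence("tiny2", "C", 1)]
    with pytest.raises(SequenceTooShortError) as err:
        encode_dataset(bad, (1, 2))
    assert "tiny1" in str(err.value) and "tiny2" in str(err.value)


def test_append_columns_reaches_424(tiny_sequences):
    base = encode_dataset(tiny_sequences, (1, 2))
    extra = {f"{n}_Pred_Result": np.linspace(0, 1, base.n_rows)
             for n in ("SVM", "LR", "LDA", "LightGBM")}
    fused = append_columns(base, extra)
    assert fused.n == 424
    assert fused.column_names[-4:] == list(extra)


def test_append_columns_edge_cases(tiny_sequences):
    base = encode_dataset(tiny_sequences, (1,))
    same = append_columns(base, {})
    np.testing.assert_array_equal(same.values, base.values)
    with pytest.raises(ValueError, match="rows"):
        append_columns(base, {"x": np.zeros(99)})
    with pytest.raises(ValueError, match="duplicate"):
        append_columns(base, {"A": np.zeros(base.n_rows)})


def test_feature_matrix_csv_roundtrip(tmp_path, tiny_sequences):
    matrix = encode_dataset(tiny_sequences, (1,))
    matrix.to_csv(tmp_path / "m.csv")
    back = FeatureMatrix.from_csv(tmp_path / "m.csv")
    assert back.column_names == matrix.column_names
    assert back.ids == matrix.ids
    np.testing.assert_allclose(back.values, matrix.values)


def test_kpc_names_are_lexicographic():
    names = kpc_names(2)
    assert names[0] == "AA" and names[-1] == "YY"
    assert list(names) == sorted(names)
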