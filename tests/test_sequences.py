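"""Generator contracts: domains, determinism, and the statistical structure
each synthetic stimulus family is supposed to have."""

import math

import numpy as np
import pytest

from seqmem import (
    CorrelationSpec,
    PatternSequence,
    alias_sequence,
    generate_binary_sequence,
    generate_correlated_binary_sequence,
    generate_moving_bar,
    generate_onehot_word,
    generate_rotating_shape_set,
)


class TestPatternSequence:
    def test_invariants_enforced(self, rng):
        with pytest.raises(ValueError):
            PatternSequence(np.ones((1, 4)))  # no transition
        with pytest.raises(ValueError):
            PatternSequence(np.array([[0.5, 1.0], [1.0, -1.0]]), "binary")
        with pytest.raises(ValueError):
            PatternSequence(np.array([[1.0, 1.0], [1.0, 0.0]]), "onehot")
        with pytest.raises(ValueError):
            PatternSequence(np.ones((3, 5)), "image", frame_shape=(2, 2))

    def test_csv_roundtrip(self, tiny_real_seq, tmp_path):
        path = tmp_path / "seq.csv"
        tiny_real_seq.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t," + ",".join(f"f{i}" for i in range(6))
        back = PatternSequence.from_csv(path)
        np.testing.assert_allclose(back.patterns, tiny_real_seq.patterns)

    def test_pgm_dump(self, tmp_path):
        bar = generate_moving_bar()
        paths = bar.to_pgm_frames(tmp_path)
        assert len(paths) == 5
        first = (tmp_path / "frame_000.pgm").read_text().splitlines()
        assert first[0] == "P2" and first[1] == "5 5"


class TestBinaryGenerators:
    def test_domain_and_determinism(self):
        a = generate_binary_sequence(1, 2, seed=3)
        assert set(np.unique(a.patterns)) <= {-1.0, 1.0}
        b = generate_binary_sequence(50, 20, seed=9)
        c = generate_binary_sequence(50, 20, seed=9)
        np.testing.assert_array_equal(b.patterns, c.patterns)

    def test_mean_concentration(self):
        seq = generate_binary_sequence(100, 50, seed=0)
        assert abs(seq.patterns.mean()) < 4 / math.sqrt(5000)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_binary_sequence(0, 5, seed=0)
        with pytest.raises(ValueError):
            generate_binary_sequence(5, -1, seed=0)

    @pytest.mark.parametrize("b", [0.0, 0.2, 0.4, 0.6, 0.8])
    def test_correlation_matches_b(self, b):
        seq = generate_correlated_binary_sequence(40, 2000, b, seed=1)
        C = np.corrcoef(seq.patterns.T)
        off = C[~np.eye(40, dtype=bool)]
        assert abs(off.mean() - b) < 0.05

    def test_correlated_b025_mean_offdiagonal(self):
        seq = generate_correlated_binary_sequence(100, 2000, 0.25, seed=1)
        C = np.corrcoef(seq.patterns.T)
        off = C[~np.eye(100, dtype=bool)]
        assert abs(off.mean() - 0.25) < 0.03

    def test_high_b_all_pairs_positive(self):
        seq = generate_correlated_binary_sequence(10, 500, 0.9, seed=2)
        C = np.corrcoef(seq.patterns.T)
        assert np.all(C[~np.eye(10, dtype=bool)] > 0)

    def test_marginals_stay_uniform(self):
        seq = generate_correlated_binary_sequence(20, 4000, 0.6, seed=3)
        assert np.all(np.abs(seq.patterns.mean(axis=0)) < 0.08)

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            generate_correlated_binary_sequence(10, 10, 1.0, seed=0)
        with pytest.raises(ValueError):
            CorrelationSpec(-0.1)


class TestOnehotWords:
    def test_minimal_three_letter_word_is_permutation(self):
        seq = generate_onehot_word(3, 3, seed=5, distinct=True)
        np.testing.assert_array_equal(seq.patterns.sum(axis=0), np.ones(3))
        assert np.all(seq.patterns.sum(axis=1) == 1)

    def test_single_letter_alphabet(self):
        seq = generate_onehot_word(1, 1, seed=0)
        np.testing.assert_array_equal(seq.patterns, [[1.0]])

    @pytest.mark.parametrize("k", [2, 5, 11])
    def test_distinct_words_use_k_letters(self, k):
        seq = generate_onehot_word(26, k, seed=k)
        assert int(seq.patterns.sum()) == k
        assert np.count_nonzero(seq.patterns.sum(axis=0)) == k

    def test_word_longer_than_alphabet_rejected(self):
        with pytest.raises(ValueError):
            generate_onehot_word(4, 5, seed=0, distinct=True)
        assert generate_onehot_word(4, 6, seed=0, distinct=False).length == 6


class TestMovingBar:
    def test_frame_shape_and_aliasing(self):
        bar = generate_moving_bar()
        assert bar.frame_shape == (5, 5)
        assert set(np.unique(bar.patterns)) == {0.0, 1.0}
        # the down-then-up trajectory (rows 1,2,3,2,1) aliases steps 2/4 and
        # also the endpoints 1/5; no other pair coincides
        np.testing.assert_array_equal(bar.patterns[1], bar.patterns[3])
        np.testing.assert_array_equal(bar.patterns[0], bar.patterns[4])
        for i in range(5):
            for j in range(i + 1, 5):
                if (i, j) not in ((1, 3), (0, 4)):
                    assert not np.array_equal(bar.patterns[i], bar.patterns[j])


class TestConverters:
    def test_roundtrip_between_pixel_and_bipolar_domains(self):
        from seqmem import to_bipolar, to_unit_range

        bar = generate_moving_bar()
        bipolar = to_bipolar(bar)
        assert bipolar.domain_tag == "binary"
        back = to_unit_range(bipolar)
        np.testing.assert_array_equal(back.patterns, bar.patterns)
        assert back.frame_shape == bar.frame_shape


class TestAliasSequence:
    @pytest.mark.parametrize("length,fraction,expected", [(10, 0.2, 2), (3, 0.2, 1), (15, 0.2, 3)])
    def test_replaces_exactly_ceil_fraction(self, length, fraction, expected):
        seq = generate_binary_sequence(16, length, seed=0)
        rep = generate_binary_sequence(16, 2, seed=99)[0]
        out = alias_sequence(seq, fraction, rep, seed=1)
        changed = [t for t in range(length) if not np.array_equal(out.patterns[t], seq.patterns[t])]
        replaced = [t for t in range(length) if np.array_equal(out.patterns[t], rep)]
        assert len(replaced) == expected
        assert set(changed) <= set(replaced)  # untouched steps are bit-identical

    def test_near_total_replacement_gives_constant(self):
        seq = generate_binary_sequence(8, 10, seed=0)
        rep = np.ones(8)
        out = alias_sequence(seq, 0.99, rep, seed=2)
        assert np.all(out.patterns == rep)

    def test_invalid_fraction(self):
        seq = generate_binary_sequence(4, 4, seed=0)
        with pytest.raises(ValueError):
            alias_sequence(seq, 0.0, np.ones(4), seed=0)
        with pytest.raises(ValueError):
            alias_sequence(seq, 1.5, np.ones(4), seed=0)


class TestRotatingShapes:
    def test_zero_angle_gives_constant_sequences(self):
        seqs = generate_rotating_shape_set(3, 10, 4, 0.0, "train", seed=0)
        for s in seqs:
            for t in range(1, 4):
                np.testing.assert_allclose(s.patterns[t], s.patterns[0])

    def test_full_rotation_returns_near_start(self):
        (s,) = generate_rotating_shape_set(1, 16, 4, 90.0, "train", seed=1)
        full = generate_rotating_shape_set(1, 16, 5, 90.0, "train", seed=1)[0]
        # after 4 x 90 degrees the frame matches the base up to resampling
        assert np.mean((full.patterns[4] - full.patterns[0]) ** 2) < 1e-3

    def test_pixel_range_and_shape(self):
        seqs = generate_rotating_shape_set(2, 12, 5, 30.0, "heldout", seed=3)
        for s in seqs:
            assert s.frame_shape == (12, 12)
            assert s.patterns.min() >= 0.0 and s.patterns.max() <= 1.0

    def test_determinism(self):
        a = generate_rotating_shape_set(2, 12, 3, 45.0, "train", seed=8)
        b = generate_rotating_shape_set(2, 12, 3, 45.0, "train", seed=8)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.patterns, y.patterns)

    def test_families_are_disjoint_shape_classes(self):
        # no held-out star ever coincides with a train polygon, across seeds
        train = [
            s.patterns[0].tobytes()
            for seed in range(6)
            for s in generate_rotating_shape_set(4, 16, 2, 45.0, "train", seed=seed)
        ]
        heldout = [
            s.patterns[0].tobytes()
            for seed in range(6)
            for s in generate_rotating_shape_set(4, 16, 2, 45.0, "heldout", seed=seed)
        ]
        assert not set(train) & set(heldout)
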