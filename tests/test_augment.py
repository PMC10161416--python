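"""Semantics of the seven augmentations: identities, contracts, statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evoaug import augment as A
from evoaug.seqdata import is_one_hot, one_hot_decode, one_hot_encode, random_one_hot

dna = st.text(alphabet="ACGT", min_size=8, max_size=60)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSettings:
    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            A.AugmentationSettings(shift_min=5, shift_max=2)

    def test_negative_noise_std_rejected(self):
        with pytest.raises(ValueError):
            A.AugmentationSettings(noise_std=-0.1)

    def test_presets(self):
        b = A.AugmentationSettings.basset_defaults()
        assert (b.mutate_frac, b.shift_max, b.insert_max, b.delete_max) == (0.15, 30, 30, 30)
        assert (b.rc_prob, b.noise_std) == (0.5, 0.3)
        d = A.AugmentationSettings.deepstarr_defaults()
        assert (d.mutate_frac, d.shift_max, d.insert_max, d.delete_max) == (0.05, 20, 20, 30)
        assert d.rc_prob == 0.0


IDENTITY_CASES = [
    ("mutate", lambda x, rng: A.mutate(x, 0.0, rng)),
    ("translocate", lambda x, rng: A.translocate(x, 0, 0, rng)),
    ("insert", lambda x, rng: A.insert(x, 0, 0, rng)),
    ("delete", lambda x, rng: A.delete(x, 0, 0, rng)),
    ("invert", lambda x, rng: A.invert(x, 0, 0, rng)),
    ("reverse_complement", lambda x, rng: A.reverse_complement(x, 0.0, rng)),
    ("add_noise", lambda x, rng: A.add_noise(x, 0.0, 0.0, rng)),
]


@pytest.mark.parametrize("name,fn", IDENTITY_CASES, ids=[c[0] for c in IDENTITY_CASES])
def test_degenerate_setting_is_exact_identity(name, fn, random_seq):
    out = fn(random_seq, _rng())
    assert np.array_equal(out, random_seq)


ONE_HOT_CASES = [
    ("mutate", lambda x, rng: A.mutate(x, 0.2, rng)),
    ("translocate", lambda x, rng: A.translocate(x, 0, 5, rng)),
    ("insert", lambda x, rng: A.insert(x, 0, 6, rng)),
    ("delete", lambda x, rng: A.delete(x, 0, 5, rng)),
    ("invert", lambda x, rng: A.invert(x, 0, 6, rng)),
    ("reverse_complement", lambda x, rng: A.reverse_complement(x, 1.0, rng)),
]


@pytest.mark.parametrize("name,fn", ONE_HOT_CASES, ids=[c[0] for c in ONE_HOT_CASES])
@given(s=dna)
def test_one_hot_preserved(name, fn, s):
    out = fn(one_hot_encode(s), _rng(1))
    assert is_one_hot(out)


@pytest.mark.parametrize("name,fn,delta", [
    ("mutate", lambda x, rng: A.mutate(x, 0.2, rng), 0),
    ("translocate", lambda x, rng: A.translocate(x, 0, 5, rng), 0),
    ("insert", lambda x, rng: A.insert(x, 0, 6, rng), 6),
    ("delete", lambda x, rng: A.delete(x, 0, 5, rng), 0),
    ("invert", lambda x, rng: A.invert(x, 0, 6, rng), 0),
    ("reverse_complement", lambda x, rng: A.reverse_complement(x, 1.0, rng), 0),
    ("add_noise", lambda x, rng: A.add_noise(x, 0.0, 0.3, rng), 0),
], ids=lambda v: v if isinstance(v, str) else "")
def test_length_contract(name, fn, delta, random_seq):
    out = fn(random_seq, _rng(2))
    assert out.shape[0] == random_seq.shape[0] + delta


class TestMutate:
    def test_draw_count_at_basset_defaults(self, rng):
        x = random_one_hot(rng, 1, 600)[0]
        _, pos = A.mutate(x, 0.15, _rng(3), return_positions=True)
        assert len(pos) == 120  # round(600 * 0.15 / 0.75)

    def test_sequence_is_pure_function_of_seed(self, random_seq):
        a = A.mutate(random_seq, 0.3, _rng(7))
        b = A.mutate(random_seq, 0.3, _rng(7))
        assert np.array_equal(a, b)

    def test_change_rate_is_three_quarters(self):
        # over many draws, a uniform resample changes the letter w.p. 3/4
        rng = _rng(10)
        x = random_one_hot(rng, 1, 600)[0]
        changed = drawn = 0
        for i in range(300):
            out, pos = A.mutate(x, 0.15, _rng(1000 + i), return_positions=True)
            final = out.argmax(axis=1)
            orig = x.argmax(axis=1)
            # count per draw: a position drawn twice contributes twice
            for p in pos:
                drawn += 1
                changed += final[p] != orig[p]
        assert drawn >= 30_000
        assert abs(changed / drawn - 0.75) < 0.01

    def test_overflow_caps_with_warning(self, random_seq):
        with pytest.warns(UserWarning):
            out, pos = A.mutate(random_seq, 0.9, _rng(), return_positions=True)
        assert len(pos) == random_seq.shape[0]


class TestTranslocate:
    def test_hand_rolled_hexamer(self):
        x = one_hot_encode("ACGTAC")
        out = A.translocate(x, 3, 3, _rng(seed=12))
        # forward or backward roll by 3 of a 6-mer gives the same sequence
        assert one_hot_decode(out) == "TACACG"

    def test_full_roll_is_identity(self, random_seq):
        L = random_seq.shape[0]
        out = A.translocate(random_seq, L, L, _rng())
        assert np.array_equal(out, random_seq)

    def test_content_is_permutation(self, random_seq):
        out = A.translocate(random_seq, 0, 20, _rng(5))
        assert np.array_equal(
            np.sort(out.argmax(axis=1)), np.sort(random_seq.argmax(axis=1))
        )

    def test_forward_then_backward_recovers_input(self, random_seq):
        fwd = np.roll(random_seq, 7, axis=0)
        back = np.roll(fwd, -7, axis=0)
        assert np.array_equal(back, random_seq)


class TestInsert:
    def test_pad_split_arithmetic(self):
        # leftover 15 splits 7 to 5' and 8 to 3'
        assert A.pad_split(15) == (7, 8)
        assert A.pad_split(0) == (0, 0)
        assert A.pad_split(1) == (0, 1)

    def test_full_length_insertion_keeps_flanks(self):
        # insert_min == insert_max: no leftover pad, original is split in two
        x = one_hot_encode("ACGTACGTACGT")
        out = A.insert(x, 4, 4, _rng(3))
        s = one_hot_decode(out)
        assert len(s) == 16
        # original sequence must appear as prefix+suffix around a 4-nt block
        found = any(
            s[:k] == "ACGTACGTACGT"[:k] and s[k + 4 :] == "ACGTACGTACGT"[k:]
            for k in range(13)
        )
        assert found

    def test_output_length_always_l_plus_max(self, random_seq):
        for seed in range(5):
            out = A.insert(random_seq, 0, 9, _rng(seed))
            assert out.shape[0] == random_seq.shape[0] + 9

    def test_insertion_length_uniform(self):
        # chi-square on insertion lengths over {0..4}; generous alpha
        from scipy.stats import chisquare

        x = random_one_hot(_rng(), 1, 30)[0]
        lengths = []
        for i in range(2000):
            rng = _rng(5000 + i)
            ell = int(rng.integers(0, 5))  # reproduce the first draw
            out = A.insert(x, 0, 4, _rng(5000 + i))
            lengths.append(ell)
            assert out.shape[0] == 34
        _, p = chisquare(np.bincount(lengths, minlength=5))
        assert p > 1e-4


class TestDelete:
    def test_surviving_flanks_contiguous(self):
        x = one_hot_encode("ACGTACGT")
        out = A.delete(x, 4, 4, _rng(6))
        s = one_hot_decode(out)
        assert len(s) == 8
        n5, n3 = A.pad_split(4)
        core = s[n5 : n5 + 4]
        original = "ACGTACGT"
        assert any(
            core == original[:k] + original[k + 4 :] for k in range(5)
        )

    def test_delete_max_must_be_below_length(self, random_seq):
        with pytest.raises(ValueError):
            A.delete(random_seq, 0, random_seq.shape[0], _rng())


class TestInvert:
    def test_homopolymer_block_complemented(self):
        x = one_hot_encode("AAAAAAAA")
        out = A.invert(x, 4, 4, _rng(2))
        s = one_hot_decode(out)
        assert s.count("T") == 4 and s.count("A") == 4
        # the complemented block is contiguous
        first, last = s.index("T"), s.rindex("T")
        assert last - first == 3

    def test_full_length_equals_reverse_complement(self, random_seq):
        L = random_seq.shape[0]
        out = A.invert(random_seq, L, L, _rng())
        rc = A.reverse_complement(random_seq, 1.0, _rng())
        assert np.array_equal(out, rc)

    def test_outside_block_untouched(self):
        x = one_hot_encode("ACGT" * 10)
        rng = _rng(9)
        ell, start = 6, None
        out = A.invert(x, 6, 6, _rng(9))
        diff = np.flatnonzero((out != x).any(axis=1))
        if diff.size:
            assert diff.max() - diff.min() < 6


class TestReverseComplement:
    def test_involution(self, random_seq):
        once = A.reverse_complement(random_seq, 1.0, _rng())
        twice = A.reverse_complement(once, 1.0, _rng())
        assert np.array_equal(twice, random_seq)

    def test_string_semantics(self):
        x = one_hot_encode("AACGTT")
        out = A.reverse_complement(x, 1.0, _rng())
        assert one_hot_decode(out) == "AACGTT"  # palindrome
        out2 = A.reverse_complement(one_hot_encode("AAACCC"), 1.0, _rng())
        assert one_hot_decode(out2) == "GGGTTT"

    def test_rate_matches_probability(self):
        rng = _rng(20)
        x = one_hot_encode("AAACCC")  # non-palindromic
        flips = sum(
            not np.array_equal(A.reverse_complement(x, 0.5, rng), x)
            for _ in range(10_000)
        )
        assert abs(flips / 10_000 - 0.5) < 0.02


class TestNoise:
    def test_moments(self):
        x = np.zeros((500, 4), dtype=np.float32)
        out = A.add_noise(x, 0.0, 0.3, _rng(4))
        assert abs(out.mean()) < 0.02
        assert abs(out.std() - 0.3) < 0.02

    def test_shape_preserved(self, random_seq):
        assert A.add_noise(random_seq, 0.0, 0.1, _rng()).shape == random_seq.shape
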