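"""Evolution-inspired augmentations for one-hot DNA sequences.

Seven label-preserving stochastic transforms emulating the sequence changes
that evolution applies to regulatory DNA: point mutation, translocation
(circular roll), insertion, deletion, inversion (in-place reverse
complement of a subsequence), whole-sequence reverse complement, and
additive Gaussian noise.

Every transform is a pure function of ``(sequence, settings, rng)``: the
same input, hyperparameters and :class:`numpy.random.Generator` state yield
bit-identical output.  All transforms except :func:`insert` and
:func:`add_noise` map strictly one-hot ``(L, 4)`` inputs to strictly one-hot
outputs of the same length; :func:`insert` always returns ``L + insert_max``
rows, and :func:`add_noise` returns unconstrained reals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .seqdata import COMPLEMENT_INDEX, random_one_hot

__all__ = [
    "AugmentationSettings",
    "mutate",
    "translocate",
    "insert",
    "delete",
    "invert",
    "reverse_complement",
    "add_noise",
    "pad_split",
]


@dataclass(frozen=True)
class AugmentationSettings:
    """Hyperparameters for all seven augmentations.

    Ranges (``*_min``/``*_max``) are inclusive integer intervals in
    nucleotides.  ``mutate_frac`` is the target fraction of positions whose
    letter actually changes (the silent-mutation correction below inflates
    the number of draws accordingly).  Defaults are the settings tuned for
    Basset-scale 600-nt accessibility models.
    """

    mutate_frac: float = 0.15
    shift_min: int = 0
    shift_max: int = 30
    insert_min: int = 0
    insert_max: int = 30
    delete_min: int = 0
    delete_max: int = 30
    invert_min: int = 0
    invert_max: int = 30
    rc_prob: float = 0.5
    noise_mean: float = 0.0
    noise_std: float = 0.3

    def __post_init__(self) -> None:
        for name in ("shift", "insert", "delete", "invert"):
            lo = getattr(self, f"{name}_min")
            hi = getattr(self, f"{name}_max")
            if lo < 0 or hi < lo:
                raise ValueError(f"require 0 <= {name}_min <= {name}_max, got {lo}, {hi}")
        if not 0.0 <= self.mutate_frac <= 1.0:
            raise ValueError("mutate_frac must lie in [0, 1]")
        if not 0.0 <= self.rc_prob <= 1.0:
            raise ValueError("rc_prob must lie in [0, 1]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")

    @classmethod
    def basset_defaults(cls) -> "AugmentationSettings":
        """Settings tuned for 600-nt chromatin-accessibility models."""
        return cls()

    @classmethod
    def deepstarr_defaults(cls) -> "AugmentationSettings":
        """Settings tuned for 249-nt enhancer-activity regression models.

        Also used for the 200-nt TF-binding classification task.  The
        reverse-complement probability is 0 here because STARR-seq activity
        is strand-specific.
        """
        return cls(
            mutate_frac=0.05,
            shift_max=20,
            insert_max=20,
            delete_max=30,
            invert_max=20,
            rc_prob=0.0,
        )

    def with_updates(self, **kwargs) -> "AugmentationSettings":
        return replace(self, **kwargs)


def _check_one_hot(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError(f"expected an (L, 4) one-hot matrix, got shape {x.shape}")
    return x


def mutate(
    x: np.ndarray,
    mutate_frac: float,
    rng: np.random.Generator,
    return_positions: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Apply random single-nucleotide mutations.

    ``round(L * mutate_frac / 0.75)`` positions are drawn uniformly *with
    replacement* and each drawn position is resampled uniformly over the
    four letters.  Dividing by 0.75 corrects for silent draws: a uniform
    resample keeps the original letter with probability 1/4, so on average
    a fraction ``mutate_frac`` of the sequence ends up actually changed.
    A position drawn twice is simply resampled twice (last draw wins).

    With ``return_positions=True`` also returns the drawn position array
    (one entry per draw, duplicates included).
    """
    x = _check_one_hot(x)
    L = x.shape[0]
    frac = mutate_frac / 0.75
    if frac > 1.0:
        warnings.warn(
            f"mutate_frac={mutate_frac} implies more draws than positions after the "
            "0.75 silent-mutation correction; capping at sequence length",
            stacklevel=2,
        )
        n_draws = L
    else:
        n_draws = int(np.rint(L * frac))
    out = x.copy()
    if n_draws > 0:
        pos = rng.integers(0, L, size=n_draws)
        out[pos] = random_one_hot(rng, n_draws)
    else:
        pos = np.empty(0, dtype=np.int64)
    if return_positions:
        return out, pos
    return out


def translocate(
    x: np.ndarray, shift_min: int, shift_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Circularly roll the sequence by a random signed shift.

    Equivalent to cutting at a random break point and swapping the two
    segments.  The shift magnitude is uniform on ``{shift_min, ...,
    shift_max}`` and its sign uniform on ``{+, -}`` (a backward shift rolls
    the other way); ``-0`` equals ``+0``, so with ``shift_min=0`` the
    identity is reachable.
    """
    x = np.asarray(x)
    if shift_max > x.shape[0]:
        raise ValueError("shift_max must not exceed sequence length")
    magnitude = int(rng.integers(shift_min, shift_max + 1))
    sign = 1 if rng.random() < 0.5 else -1
    return np.roll(x, sign * magnitude, axis=0)


def pad_split(p: int) -> tuple[int, int]:
    """Split a pad of total length ``p`` into (5', 3') flank lengths.

    Even split with the odd remainder going to the 3' end.
    """
    return p // 2, p - p // 2


def insert(
    x: np.ndarray, insert_min: int, insert_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Insert a random-DNA block, padding flanks to a fixed output length.

    An insertion of length ``l`` uniform on ``{insert_min, ..., insert_max}``
    of uniform random DNA is placed at a uniform position in ``{0, ..., L}``
    (both ends allowed).  To keep the model input length constant the
    leftover ``insert_max - l`` is added as random-DNA flanks via
    :func:`pad_split`.  Output length is always ``L + insert_max``.
    """
    x = _check_one_hot(x)
    L = x.shape[0]
    if insert_max == 0:
        return x.copy()
    ell = int(rng.integers(insert_min, insert_max + 1))
    pos = int(rng.integers(0, L + 1))
    block = random_one_hot(rng, ell) if ell else np.empty((0, 4), dtype=x.dtype)
    n5, n3 = pad_split(insert_max - ell)
    pieces = [
        random_one_hot(rng, n5) if n5 else np.empty((0, 4), dtype=x.dtype),
        x[:pos],
        block,
        x[pos:],
        random_one_hot(rng, n3) if n3 else np.empty((0, 4), dtype=x.dtype),
    ]
    out = np.concatenate(pieces, axis=0).astype(x.dtype)
    assert out.shape[0] == L + insert_max
    return out


def delete(
    x: np.ndarray, delete_min: int, delete_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Excise a random contiguous block and re-pad flanks with random DNA.

    Deletion length ``l`` is uniform on ``{delete_min, ..., delete_max}``,
    the start uniform over the positions that can contain it.  The two
    surviving flanks are concatenated in order and random-DNA pads of total
    length ``l`` restore the original length (split per :func:`pad_split`).
    """
    x = _check_one_hot(x)
    L = x.shape[0]
    if delete_max >= L:
        raise ValueError("delete_max must be smaller than the sequence length")
    ell = int(rng.integers(delete_min, delete_max + 1))
    if ell == 0:
        return x.copy()
    start = int(rng.integers(0, L - ell + 1))
    core = np.concatenate([x[:start], x[start + ell :]], axis=0)
    n5, n3 = pad_split(ell)
    pieces = [
        random_one_hot(rng, n5) if n5 else np.empty((0, 4), dtype=x.dtype),
        core,
        random_one_hot(rng, n3) if n3 else np.empty((0, 4), dtype=x.dtype),
    ]
    out = np.concatenate(pieces, axis=0).astype(x.dtype)
    assert out.shape[0] == L
    return out


def _reverse_complement_block(block: np.ndarray) -> np.ndarray:
    # reversing both axes implements reverse + (A<->T, C<->G) complement
    return block[::-1, ::-1]


def invert(
    x: np.ndarray, invert_min: int, invert_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Replace a random subsequence by its reverse complement in place.

    Length uniform on ``{invert_min, ..., invert_max}``, start uniform on the
    valid positions; everything outside the block is untouched.  With the
    block spanning the whole sequence this is exactly
    :func:`reverse_complement` applied deterministically.
    """
    x = _check_one_hot(x)
    L = x.shape[0]
    if invert_max > L:
        raise ValueError("invert_max must not exceed sequence length")
    ell = int(rng.integers(invert_min, invert_max + 1))
    if ell == 0:
        return x.copy()
    start = int(rng.integers(0, L - ell + 1))
    out = x.copy()
    out[start : start + ell] = _reverse_complement_block(x[start : start + ell])
    return out


def reverse_complement(
    x: np.ndarray, rc_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """With probability ``rc_prob``, replace the sequence by its reverse complement."""
    x = _check_one_hot(x)
    if rng.random() < rc_prob:
        return _reverse_complement_block(x).copy()
    return x.copy()


def add_noise(
    x: np.ndarray, noise_mean: float, noise_std: float, rng: np.random.Generator
) -> np.ndarray:
    """Add iid Gaussian noise to every matrix element.

    The output is real-valued and no longer one-hot; it is meant as the last
    transform before the model input.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    x = np.asarray(x, dtype=np.float32)
    return x + rng.normal(noise_mean, noise_std, size=x.shape).astype(np.float32)
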