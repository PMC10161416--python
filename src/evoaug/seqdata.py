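"""Sequence encoding, dataset containers, and the synthetic fixture generator.

DNA sequences are represented either as upper-case strings over the alphabet
``{A, C, G, T, N}`` or as one-hot matrices of shape ``(L, 4)`` with the fixed
column order ``(A, C, G, T)``.  The complement mapping is A<->T, C<->G, which
in one-hot space is a simultaneous reversal of both axes.

All randomness flows through :class:`numpy.random.Generator` objects so that
every dataset, split and sample is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
#: index of the complement letter under (A, C, G, T) ordering
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])

_LETTER_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class SequenceError(ValueError):
    """Raised for sequences that violate encoding preconditions."""


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def one_hot_encode(seq: str) -> np.ndarray:
    """Encode an N-free DNA string as an ``(L, 4)`` float32 one-hot matrix.

    Parameters
    ----------
    seq
        DNA string over ``{A, C, G, T}``; lower case accepted and normalised.

    Raises
    ------
    SequenceError
        If the string is empty, contains ``N``, or any other letter outside
        the alphabet.  ``N``-containing sequences are handled by filtering
        (:func:`filter_n_sequences`), never by soft-encoding.
    """
    s = str(seq).upper()
    if not s:
        raise SequenceError("cannot encode an empty sequence")
    if "N" in s:
        raise SequenceError(
            "sequence contains N; remove it with filter_n_sequences before encoding"
        )
    try:
        idx = np.array([_LETTER_TO_INDEX[c] for c in s], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise SequenceError(f"invalid nucleotide {exc.args[0]!r}") from None
    x = np.zeros((len(s), 4), dtype=np.float32)
    x[np.arange(len(s)), idx] = 1.0
    return x


def one_hot_decode(x: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; requires a strictly one-hot matrix."""
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[1] != 4:
        raise SequenceError(f"expected an (L, 4) matrix, got shape {x.shape}")
    if not is_one_hot(x):
        raise SequenceError("matrix is not strictly one-hot; cannot decode")
    idx = x.argmax(axis=1)
    return "".join(ALPHABET[i] for i in idx)


def is_one_hot(x: np.ndarray) -> bool:
    """True when every row has exactly one 1 and three 0s."""
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[1] != 4:
        return False
    return bool(np.all((x == 0) | (x == 1)) and np.all(x.sum(axis=1) == 1))


def encode_batch(seqs: list[str]) -> np.ndarray:
    """Stack equal-length N-free strings into an ``(N, L, 4)`` array."""
    mats = [one_hot_encode(s) for s in seqs]
    lengths = {m.shape[0] for m in mats}
    if len(lengths) > 1:
        raise SequenceError(f"sequences have mixed lengths {sorted(lengths)}")
    return np.stack(mats)


def random_one_hot(rng: np.random.Generator, n: int, length: int | None = None) -> np.ndarray:
    """Uniform random one-hot DNA: ``(n, 4)`` or ``(n, length, 4)`` matrices."""
    shape = (n,) if length is None else (n, length)
    idx = rng.integers(0, 4, size=shape)
    return np.eye(4, dtype=np.float32)[idx]


def reverse_complement_string(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Filtering / splitting / balancing
# ---------------------------------------------------------------------------

def filter_n_sequences(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop every record whose sequence contains at least one ``N``.

    Genomic windows overlapping assembly gaps carry runs of ``N``; these are
    removed outright rather than imputed.  Order of surviving records is
    preserved and the operation is idempotent.
    """
    return [(rid, seq) for rid, seq in records if "N" not in seq.upper()]


def split_indices(
    n: int,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Randomly partition ``range(n)`` into train/valid/test index arrays.

    Validation and test receive ``floor(n * f)`` records each; the remainder
    goes to training.  The partition is a deterministic function of ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_valid = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_valid - n_test
    return {
        "train": np.sort(perm[:n_train]),
        "valid": np.sort(perm[n_train : n_train + n_valid]),
        "test": np.sort(perm[n_train + n_valid :]),
    }


def balance_negatives(pos: list, neg: list, seed: int = 0) -> list:
    """Down-sample negatives (without replacement) to match the positive count.

    Mirrors class balancing for peak-vs-background classification: negatives
    are never up-sampled, so ``len(neg) >= len(pos)`` is required.
    """
    if len(neg) < len(pos):
        raise ValueError(
            f"cannot balance: {len(neg)} negatives < {len(pos)} positives "
            "(up-sampling is not supported)"
        )
    if len(neg) == len(pos):
        return list(neg)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    return [neg[i] for i in np.sort(keep)]


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Fixed-length one-hot sequences with task labels and named splits.

    Attributes
    ----------
    x : (N, L, 4) float32 array of one-hot sequences.
    y : (N, T) float32 array of labels (binary or real, per ``task_kind``).
    ids : record identifiers, length N.
    splits : mapping of split name -> sorted index array; disjoint.
    task_kind : ``"binary"`` or ``"regression"``.
    motif_sites : optional ground truth for synthetic data; maps record index
        to a list of ``(motif_index, offset)`` planted-instance coordinates.
    """

    x: np.ndarray
    y: np.ndarray
    ids: list[str]
    splits: dict[str, np.ndarray]
    task_kind: str = "binary"
    motif_sites: dict[int, list[tuple[int, int]]] | None = None

    def __post_init__(self) -> None:
        if self.x.ndim != 3 or self.x.shape[2] != 4:
            raise ValueError(f"x must be (N, L, 4), got {self.x.shape}")
        if self.y.ndim != 2 or self.y.shape[0] != self.x.shape[0]:
            raise ValueError("y must be (N, T) aligned with x")
        if len(self.ids) != self.x.shape[0]:
            raise ValueError("ids length must match number of records")
        if self.task_kind not in ("binary", "regression"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        seen: set[int] = set()
        for name, idx in self.splits.items():
            s = set(int(i) for i in idx)
            if s & seen:
                raise ValueError(f"split {name!r} overlaps another split")
            seen |= s

    @property
    def n_records(self) -> int:
        return self.x.shape[0]

    @property
    def length(self) -> int:
        return self.x.shape[1]

    @property
    def n_tasks(self) -> int:
        return self.y.shape[1]

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.splits[name]
        return self.x[idx], self.y[idx]

    def sequences(self, name: str | None = None) -> list[str]:
        """Decode records (optionally one split) back to strings."""
        idx = range(self.n_records) if name is None else self.splits[name]
        return [one_hot_decode(self.x[i]) for i in idx]


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a motif-implanted benchmark dataset with known ground truth.

    Half the records are positives carrying motif instances, half are pure
    background; labels are single-task binary.  Each positive receives each
    motif with probability ``embed_prob``, implanted at a uniform random
    offset (non-overlapping between motifs where possible).  Motif instances
    are sampled from the consensus with an independent per-position
    substitution rate, emulating degenerate transcription-factor binding
    sites on a uniform background.
    """

    n_records: int = 2000
    length: int = 200
    motifs: list[tuple[str, float]] = field(default_factory=lambda: [("TGACTCA", 0.1)])
    embed_prob: float = 1.0
    seed: int = 0
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.embed_prob <= 1.0:
            raise ValueError("embed_prob must lie in [0, 1]")
        for consensus, rate in self.motifs:
            if len(consensus) >= self.length:
                raise ValueError(
                    f"motif {consensus!r} is not shorter than sequence length {self.length}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValueError("substitution rate must lie in [0, 1]")


def _sample_motif_instance(consensus: str, rate: float, rng: np.random.Generator) -> np.ndarray:
    inst = one_hot_encode(consensus)
    flip = rng.random(len(consensus)) < rate
    if flip.any():
        repl = random_one_hot(rng, int(flip.sum()))
        inst[flip] = repl
    return inst


def generate_synthetic_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a seed-deterministic planted-motif dataset.

    Positives (label 1) are background sequences with motif instances
    implanted at recorded offsets; negatives (label 0) are pure background.
    Ground-truth ``(motif_index, offset)`` pairs are kept in
    ``LabeledDataset.motif_sites`` keyed by record index.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    length = spec.length
    x = random_one_hot(rng, n, length)
    n_pos = n // 2
    labels = np.zeros((n, 1), dtype=np.float32)
    labels[:n_pos] = 1.0
    sites: dict[int, list[tuple[int, int]]] = {}
    for i in range(n_pos):
        occupied: list[tuple[int, int]] = []
        placed: list[tuple[int, int]] = []
        for m, (consensus, rate) in enumerate(spec.motifs):
            if rng.random() >= spec.embed_prob:
                continue
            w = len(consensus)
            # rejection-sample a non-overlapping offset; fall back to any offset
            offset = None
            for _ in range(50):
                cand = int(rng.integers(0, length - w + 1))
                if all(cand + w <= a or cand >= b for a, b in occupied):
                    offset = cand
                    break
            if offset is None:
                offset = int(rng.integers(0, length - w + 1))
            x[i, offset : offset + w] = _sample_motif_instance(consensus, rate, rng)
            occupied.append((offset, offset + w))
            placed.append((m, offset))
        sites[i] = placed
    # shuffle records so splits are class-mixed, then remap ground truth
    perm = rng.permutation(n)
    x = x[perm]
    labels = labels[perm]
    inv = {int(old): new for new, old in enumerate(perm)}
    sites = {inv[i]: v for i, v in sites.items()}
    ids = [f"synth_{i}" for i in range(n)]
    splits = split_indices(n, spec.fractions, seed=spec.seed + 1)
    return LabeledDataset(
        x=x, y=labels, ids=ids, splits=splits, task_kind="binary", motif_sites=sites
    )


def dataset_from_strings(
    seqs: list[str],
    labels: np.ndarray,
    ids: list[str] | None = None,
    task_kind: str = "binary",
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> LabeledDataset:
    """Build a :class:`LabeledDataset` from raw strings with a random split."""
    x = encode_batch(seqs)
    y = np.asarray(labels, dtype=np.float32)
    if y.ndim == 1:
        y = y[:, None]
    if ids is None:
        ids = [f"seq_{i}" for i in range(len(seqs))]
    splits = split_indices(len(seqs), fractions, seed=seed)
    return LabeledDataset(x=x, y=y, ids=list(ids), splits=splits, task_kind=task_kind)
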