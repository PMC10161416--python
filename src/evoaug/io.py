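"""File I/O: FASTA, BED interval extraction, and the HDF5 dataset container.

The HDF5 layout stores one-hot sequences and label matrices per split::

    /train/x  (n_train, L, 4)    /train/y  (n_train, T)
    /valid/x  ...                /valid/y  ...
    /test/x   ...                /test/y   ...

with ``task_kind`` as a root attribute, so a dataset round-trips without
side files.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqdata import LabeledDataset, one_hot_decode


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, upper-case sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs, wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals (0-based half-open) as (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"region_{i}"
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            out.append((chrom, start, end, name))
    return out


def extract_bed_sequences(bed_path, fasta_path) -> list[tuple[str, str]]:
    """Extract interval sequences from an indexed FASTA reference."""
    from pyfaidx import Fasta

    ref = Fasta(str(fasta_path))
    records = []
    for chrom, start, end, name in read_bed(bed_path):
        seq = ref[chrom][start:end].seq.upper()
        records.append((name, seq))
    return records


def save_dataset_h5(dataset: LabeledDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["task_kind"] = dataset.task_kind
        for split in dataset.splits:
            x, y = dataset.split(split)
            grp = fh.create_group(split)
            grp.create_dataset("x", data=x.astype(np.float32), compression="gzip")
            grp.create_dataset("y", data=y.astype(np.float32), compression="gzip")


def load_dataset_h5(path) -> LabeledDataset:
    import h5py

    xs, ys, splits, ids = [], [], {}, []
    offset = 0
    with h5py.File(path, "r") as fh:
        task_kind = fh.attrs.get("task_kind", "binary")
        for split in ("train", "valid", "test"):
            if split not in fh:
                continue
            x = fh[split]["x"][...]
            y = fh[split]["y"][...]
            xs.append(x)
            ys.append(y)
            splits[split] = np.arange(offset, offset + len(x))
            ids.extend(f"{split}_{i}" for i in range(len(x)))
            offset += len(x)
    return LabeledDataset(
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        ids=ids,
        splits=splits,
        task_kind=str(task_kind),
    )


def dataset_to_fasta(dataset: LabeledDataset, path, split: str | None = None) -> None:
    idx = range(dataset.n_records) if split is None else dataset.splits[split]
    records = [(dataset.ids[i], one_hot_decode(dataset.x[i])) for i in idx]
    write_fasta(records, path)
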