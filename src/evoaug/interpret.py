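"""Post hoc model interpretability.

Two complementary views of what a trained sequence model has learned:

* **Filter motifs** — each first-layer convolutional filter is summarised
  as a position frequency matrix (PFM) by collecting the sequence windows
  that activate it strongly (activation above a fraction of the filter's
  maximum over a scan set) and counting nucleotides per offset.  PFMs can
  be exported in MEME minimal format for downstream motif comparison
  (e.g. Tomtom against JASPAR).

* **Attribution maps** — expected-gradient attributions with random-DNA
  references: importance of input element ``(l, a)`` is the average over
  references of ``(x - ref) * grad`` evaluated at a random interpolation
  point between the reference and the input.  A gradient correction
  removes the per-position component that is uniform across the four
  nucleotides, which is unidentifiable for one-hot inputs and otherwise
  pollutes sequence logos.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import ALPHABET, random_one_hot

logger = logging.getLogger(__name__)


@dataclass
class PositionFrequencyMatrix:
    """Nucleotide counts of the strongly activating windows of one filter."""

    counts: np.ndarray  # (W, 4) non-negative integers
    n_sites: int
    filter_index: int

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def ppm(self) -> np.ndarray:
        """Position probability matrix; rows sum to 1 (requires n_sites > 0)."""
        if self.n_sites == 0:
            raise ValueError("PFM has no sites")
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        if self.n_sites == 0:
            return ""
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=1))


@dataclass
class AttributionMap:
    """Per-position, per-nucleotide importance scores for one sequence."""

    values: np.ndarray  # (L, 4)
    sequence_id: str = ""
    corrected: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(ALPHABET))
        df.insert(0, "position", np.arange(len(df)))
        return df


# ---------------------------------------------------------------------------
# Filter PFMs
# ---------------------------------------------------------------------------

def extract_filter_pfms(
    model,
    sequences: np.ndarray,
    threshold_frac: float = 0.5,
    batch_size: int = 256,
) -> list[PositionFrequencyMatrix]:
    """Activation-based alignment of first-layer filters to PFMs.

    For each filter the raw convolution response is scanned over every
    valid window of ``sequences`` (an ``(N, L, 4)`` one-hot array); windows
    with activation strictly above ``threshold_frac`` times that filter's
    maximum response are stacked and letter counts per offset form the PFM.
    Filters with no qualifying window (e.g. all-negative response) are
    returned with ``n_sites = 0``.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie strictly between 0 and 1")
    conv = model.first_conv()
    width = conv.width
    n_filters = conv.w.shape[2]
    x = np.asarray(sequences, dtype=np.float64)
    if x.ndim != 3 or x.shape[1] < width:
        raise ValueError("sequences must be (N, L, 4) with L >= filter width")

    # pass 1: per-filter maximum activation over the scan
    max_act = np.full(n_filters, -np.inf)
    for i in range(0, len(x), batch_size):
        act = conv.linear_response(x[i : i + batch_size])
        max_act = np.maximum(max_act, act.max(axis=(0, 1)))

    counts = np.zeros((n_filters, width, 4), dtype=np.int64)
    n_sites = np.zeros(n_filters, dtype=np.int64)
    for i in range(0, len(x), batch_size):
        xb = x[i : i + batch_size]
        act = conv.linear_response(xb)  # (B, Lout, F)
        for f in range(n_filters):
            hits = np.argwhere(act[:, :, f] > threshold_frac * max_act[f])
            for b, l in hits:
                counts[f] += xb[b, l : l + width].astype(np.int64)
            n_sites[f] += len(hits)
    return [
        PositionFrequencyMatrix(counts=counts[f], n_sites=int(n_sites[f]), filter_index=f)
        for f in range(n_filters)
    ]


def write_meme(
    pfms: list[PositionFrequencyMatrix],
    path=None,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> str:
    """Serialize PFMs to MEME minimal motif format.

    Zero-site filters are skipped with a logged notice.  Returns the text;
    also writes it to ``path`` when given.
    """
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A {:.3f} C {:.3f} G {:.3f} T {:.3f}".format(*background),
        "",
    ]
    for pfm in pfms:
        if pfm.n_sites == 0:
            logger.info("filter %d has no qualifying sites; skipped", pfm.filter_index)
            continue
        lines.append(f"MOTIF filter_{pfm.filter_index}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pfm.width} "
            f"nsites= {pfm.n_sites} E= 0"
        )
        for row in pfm.ppm:
            lines.append("  ".join(f"{v:.6f}" for v in row))
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def attribution_map(
    model,
    x: np.ndarray,
    task_index: int = 0,
    n_references: int = 1000,
    rng: np.random.Generator | None = None,
    batch_size: int = 100,
    sequence_id: str = "",
) -> AttributionMap:
    """Expected-gradient attribution with random-DNA references.

    Each of the ``n_references`` uniform random one-hot sequences
    contributes one sample: the model gradient for ``task_index`` is taken
    at a uniformly interpolated point between reference and input, and
    weighted by ``(x - reference)``.  The average over references is the
    (uncorrected) attribution map.
    """
    if n_references < 1:
        raise ValueError("n_references must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, dtype=np.float64)
    L = x.shape[0]
    total = np.zeros_like(x)
    for start in range(0, n_references, batch_size):
        b = min(batch_size, n_references - start)
        refs = random_one_hot(rng, b, L).astype(np.float64)
        alphas = rng.random((b, 1, 1))
        points = refs + alphas * (x[None] - refs)
        grads = model.input_gradient(points, task_index)
        total += ((x[None] - refs) * grads).sum(axis=0)
    return AttributionMap(values=total / n_references, sequence_id=sequence_id, corrected=False)


def gradient_correction(attr: AttributionMap) -> AttributionMap:
    """Remove the across-nucleotide mean at each position.

    After correction the four values at every position sum to zero; the
    operation is idempotent.
    """
    centred = attr.values - attr.values.mean(axis=1, keepdims=True)
    return AttributionMap(values=centred, sequence_id=attr.sequence_id, corrected=True)


def select_top_activity(y: np.ndarray, task_index: int = 0, percentile: float = 99.0) -> np.ndarray:
    """Indices of records whose measured activity exceeds a percentile.

    Convenience selector for choosing high-activity sequences (default top
    1%) whose attribution logos are worth inspecting.
    """
    task = np.asarray(y)[:, task_index]
    cut = np.percentile(task, percentile)
    return np.flatnonzero(task >= cut)
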