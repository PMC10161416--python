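"""MPRA-style variant-effect scoring and per-experiment evaluation.

A single-nucleotide variant is scored by running the model on the
reference window and on the same window with the alternative allele
substituted, averaging the task outputs of each (the cell-type-agnostic
view), and taking the natural-log ratio::

    effect = ln( mean_tasks f(x_alt) / mean_tasks f(x_ref) )

The score is 0 when the alleles agree, exactly antisymmetric under allele
swap, and invariant to any common positive rescaling of the outputs.
Predicted effects are compared with measured effects by Pearson
correlation within each saturation-mutagenesis experiment (regulatory
element), and summarised by the unweighted mean correlation across
elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .curriculum import pad_for_inference
from .seqdata import ALPHABET, one_hot_encode


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant within a regulatory-element window."""

    element_id: str
    position: int  # 0-based offset within the model input window
    ref_allele: str
    alt_allele: str
    measured_effect: float

    def __post_init__(self) -> None:
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        if ref not in ALPHABET or alt not in ALPHABET:
            raise ValueError(f"alleles must be single letters in {ALPHABET}")
        if ref == alt:
            raise ValueError("ref and alt alleles must differ")
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)


def center_window(element: str, window_length: int, flank_source: str = "N") -> tuple[str, int]:
    """Center an element inside a window, extra base going to the 3' side.

    Returns the 0-based offset of the element start within the window.  In
    practice windows come straight from the reference genome; this helper
    computes where measured element coordinates land inside them.
    """
    pad = window_length - len(element)
    if pad < 0:
        raise ValueError("element longer than window")
    left = pad // 2
    return flank_source * left + element + flank_source * (pad - left), left


def build_variant_pair(
    reference_window: str, v: VariantRecord
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot (ref, alt) pair differing at exactly ``v.position``."""
    window = reference_window.upper()
    if window[v.position] != v.ref_allele:
        raise ValueError(
            f"window has {window[v.position]!r} at position {v.position}, "
            f"expected ref allele {v.ref_allele!r}"
        )
    ref_x = one_hot_encode(window)
    alt_x = ref_x.copy()
    alt_x[v.position] = 0.0
    alt_x[v.position, ALPHABET.index(v.alt_allele)] = 1.0
    return ref_x, alt_x


def score_variant(model, ref_x: np.ndarray, alt_x: np.ndarray) -> float:
    """Natural-log ratio of task-mean predictions, alt over ref."""
    preds = model.predict(np.stack([ref_x, alt_x]))
    ref_mean = float(preds[0].mean())
    alt_mean = float(preds[1].mean())
    if ref_mean <= 0 or alt_mean <= 0:
        raise ValueError(
            f"non-positive mean prediction (ref={ref_mean}, alt={alt_mean}); "
            "log-ratio undefined"
        )
    return float(np.log(alt_mean / ref_mean))


def score_variants(
    model,
    windows: dict[str, str],
    variants: list[VariantRecord],
    insert_max: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score a variant list against per-element reference windows.

    For models trained with insertion augmentation, both members of each
    ref/alt pair receive the *same* random 3' pad (length ``insert_max``)
    so the pad contribution cancels in the log-ratio.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for v in variants:
        ref_x, alt_x = build_variant_pair(windows[v.element_id], v)
        if insert_max:
            ref_x = pad_for_inference(ref_x, insert_max, rng)
            # identical pad for both alleles so it cancels in the log-ratio
            alt_x = np.concatenate([alt_x, ref_x[-insert_max:]], axis=0)
        rows.append(
            {
                "element_id": v.element_id,
                "position": v.position,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "measured": v.measured_effect,
                "predicted": score_variant(model, ref_x, alt_x),
            }
        )
    return pd.DataFrame(rows)


def evaluate_experiments(scores: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-element Pearson r between measured and predicted effects.

    Elements with fewer than two variants or zero variance on either axis
    are flagged (``r = NaN``) with a warning and excluded from the
    unweighted mean across elements.
    """
    rows = []
    for element, grp in scores.groupby("element_id", sort=True):
        measured = grp["measured"].to_numpy(float)
        predicted = grp["predicted"].to_numpy(float)
        if len(grp) < 2 or np.std(measured) == 0 or np.std(predicted) == 0:
            warnings.warn(
                f"element {element!r} has insufficient variance for Pearson r; excluded",
                stacklevel=2,
            )
            rows.append({"element_id": element, "n_variants": len(grp), "pearson_r": np.nan})
            continue
        r = pearsonr(measured, predicted).statistic
        rows.append({"element_id": element, "n_variants": len(grp), "pearson_r": float(r)})
    table = pd.DataFrame(rows)
    mean_r = float(table["pearson_r"].dropna().mean())
    return table, mean_r


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_variants_tsv(path) -> list[VariantRecord]:
    """Read variants from TSV columns: element_id, pos, ref, alt, measured."""
    df = pd.read_csv(path, sep="\t")
    return [
        VariantRecord(
            element_id=str(r.element_id),
            position=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            measured_effect=float(r.measured),
        )
        for r in df.itertuples()
    ]


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_variants_vcf(
    path,
    window_starts: dict[str, int],
    element_by_chrom: dict[str, str] | None = None,
    effect_tag: str = "EFFECT",
) -> list[VariantRecord]:
    """Read single-nucleotide variants from a VCF file.

    ``window_starts`` maps element ids to the 0-based genomic start of the
    model input window; VCF ``POS`` (1-based) is converted to a 0-based
    window offset.  By default the element id is the CHROM field (the
    common layout for saturation-mutagenesis VCFs keyed per element);
    ``element_by_chrom`` can remap chromosome names to element ids.
    Measured effect sizes are taken from the ``effect_tag`` INFO field.
    Multi-nucleotide records are skipped.
    """
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        if len(rec.REF) != 1 or not rec.ALT or len(rec.ALT[0]) != 1:
            continue
        element = rec.CHROM if element_by_chrom is None else element_by_chrom[rec.CHROM]
        measured = rec.INFO.get(effect_tag)
        if measured is None:
            continue
        out.append(
            VariantRecord(
                element_id=element,
                position=rec.POS - 1 - window_starts[element],
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                measured_effect=float(measured),
            )
        )
    return out
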