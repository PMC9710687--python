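"""Evaluation arithmetic: variant-calling accuracy, compression ratio, entropy.

Recall, precision and F1 follow the usual confusion-count definitions
(Rec = TP/(TP+FN), Prec = TP/(TP+FP), F1 = harmonic mean), with the hap.py
convention that degenerate 0/0 cases are reported as 0.  Compression ratio is
compressed size over original size (smaller is better); space saving is the
percent reduction of a variant's compressed size against a baseline.  The
zeroth-order empirical entropy quantifies why quantization shrinks gzip
output: merging score symbols can only lower the per-symbol entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .fastq_io import MAX_SCORE


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round with ties away from zero, matching how result tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """True-positive / false-positive / false-negative variant counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")


@dataclass(frozen=True)
class MetricTriple:
    rec: float
    prec: float
    f1: float

    def rounded(self, ndigits: int = 4) -> "MetricTriple":
        return MetricTriple(
            round_half_up(self.rec, ndigits),
            round_half_up(self.prec, ndigits),
            round_half_up(self.f1, ndigits),
        )


def metrics_from_counts(counts: ConfusionCounts) -> MetricTriple:
    """Recall, precision and F1 from confusion counts (0 on empty denominators)."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return MetricTriple(rec, prec, f1)


def f1_from_pr(prec: float, rec: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not 0.0 <= prec <= 1.0:
        raise ValueError(f"precision {prec} outside [0, 1]")
    if not 0.0 <= rec <= 1.0:
        raise ValueError(f"recall {rec} outside [0, 1]")
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)


def compression_ratio(original_bytes: int, compressed_bytes: int) -> float:
    """Compressed size divided by original size; smaller ratios compress better."""
    if original_bytes <= 0:
        raise ValueError(f"original size must be positive, got {original_bytes}")
    return compressed_bytes / original_bytes


def space_saving_percent(baseline_compressed_bytes: int, variant_compressed_bytes: int) -> float:
    """Percent size reduction of a variant vs the baseline's compressed size.

    Negative when the variant compresses worse than the baseline.
    """
    if baseline_compressed_bytes <= 0:
        raise ValueError(
            f"baseline size must be positive, got {baseline_compressed_bytes}"
        )
    return 100.0 * (baseline_compressed_bytes - variant_compressed_bytes) / baseline_compressed_bytes


@dataclass(frozen=True)
class CompressionReport:
    """Byte sizes of one dataset plus the derived ratio and saving."""

    original_bytes: int
    compressed_bytes: int
    cr: float
    saving_percent: float

    @classmethod
    def from_sizes(
        cls,
        original_bytes: int,
        compressed_bytes: int,
        baseline_compressed_bytes: int | None = None,
    ) -> "CompressionReport":
        base = baseline_compressed_bytes if baseline_compressed_bytes is not None else compressed_bytes
        return cls(
            original_bytes=original_bytes,
            compressed_bytes=compressed_bytes,
            cr=compression_ratio(original_bytes, compressed_bytes),
            saving_percent=space_saving_percent(base, compressed_bytes),
        )


def empirical_entropy0(scores: Sequence[int] | Iterable[int]) -> float:
    """Zeroth-order empirical entropy of a score sequence, in bits per symbol."""
    arr = np.asarray(list(scores) if not isinstance(scores, (np.ndarray, list)) else scores)
    if arr.size == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    counts = np.bincount(arr, minlength=MAX_SCORE + 1)
    p = counts[counts > 0] / arr.size
    return float(-(p * np.log2(p)).sum())
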