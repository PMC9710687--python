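"""Repetitive-sequence detection and the two-regime context quantizer.

Nanopore basecalls are least reliable in repetitive sequence — homopolymers
(>= h copies of one base) and dinucleotide repeats (>= d copies of a two-base
unit).  The context quantizer <f, f'>_delta therefore keeps higher score
resolution near repeats: a score at position j is mapped by f' if j lies
within delta bases of a repetitive interval, and by f otherwise.  Default
parameters are h=5, d=4, delta=5.

Coordinates are 0-based, half-open throughout.  Detection is
case-insensitive and treats 'N' (or any IUPAC letter) like any other symbol.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fastq_io import FastqRecord
from .quantizers import Quantizer, parse_quantizer_spec

HOMOPOLYMER = "homopolymer"
DINUCLEOTIDE = "dinucleotide"


@dataclass(frozen=True)
class RepeatInterval:
    """A repetitive stretch [start, end) of a read, with its repeat kind."""

    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def find_homopolymer_runs(sequence: str, h: int = 5) -> list[RepeatInterval]:
    """Maximal runs of one repeated letter with length >= h, in ascending order."""
    if h < 2:
        raise ValueError(f"h must be >= 2, got {h}")
    s = sequence.upper()
    n = len(s)
    out = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and s[j] == s[i]:
            j += 1
        if j - i >= h:
            out.append(RepeatInterval(i, j, HOMOPOLYMER))
        i = j
    return out


def find_dinucleotide_repeats(sequence: str, d: int = 4) -> list[RepeatInterval]:
    """Maximal intervals covered by >= d consecutive copies of a two-letter unit.

    The two letters of the unit must differ (an "AA" unit is a homopolymer and
    is governed by h, not d); both phase offsets are considered and
    overlapping intervals are merged.  Each reported interval has length
    >= 2*d.
    """
    if d < 2:
        raise ValueError(f"d must be >= 2, got {d}")
    s = sequence.upper()
    n = len(s)
    raw: list[tuple[int, int]] = []
    i = 0
    # A union of >=d-copy windows of an alternating two-letter unit is exactly
    # a maximal alternation of length >= 2d, so scanning maximal alternating
    # runs suffices.
    while i < n - 1:
        if s[i] == s[i + 1]:
            i += 1
            continue
        e = i + 2
        while e < n and s[e] == s[e - 2]:
            e += 1
        if e - i >= 2 * d:
            raw.append((i, e))
        # the next alternation may start one position before this one ends
        i = e - 1
    merged: list[tuple[int, int]] = []
    for start, end in raw:
        if merged and start < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return [RepeatInterval(a, b, DINUCLEOTIDE) for a, b in merged]


def repeat_intervals(sequence: str, h: int = 5, d: int = 4) -> list[RepeatInterval]:
    """All repetitive intervals (both kinds), sorted by start position."""
    runs = find_homopolymer_runs(sequence, h) + find_dinucleotide_repeats(sequence, d)
    return sorted(runs, key=lambda r: (r.start, r.end))


def repeat_mask(sequence: str, h: int = 5, d: int = 4, delta: int = 5) -> list[bool]:
    """Per-position flag: True where the position is within delta bases of a repeat.

    Position j is flagged for interval [s, e) iff s - delta <= j <= e - 1 + delta;
    the mask is the union over all homopolymer and dinucleotide intervals.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    n = len(sequence)
    mask = [False] * n
    for iv in repeat_intervals(sequence, h, d):
        lo = max(0, iv.start - delta)
        hi = min(n, iv.end + delta)
        for j in range(lo, hi):
            mask[j] = True
    return mask


@dataclass(frozen=True)
class ContextQuantizer:
    """<far, near>_delta: ``near`` within delta bases of a repeat, ``far`` elsewhere."""

    far: Quantizer
    near: Quantizer
    delta: int = 5
    h: int = 5
    d: int = 4

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.h < 2 or self.d < 2:
            raise ValueError("h and d must be >= 2")

    @classmethod
    def from_specs(
        cls, far: str, near: str, delta: int = 5, h: int = 5, d: int = 4
    ) -> "ContextQuantizer":
        return cls(parse_quantizer_spec(far), parse_quantizer_spec(near), delta, h, d)

    def spec_string(self) -> str:
        return (
            f"<{self.far.spec_string()},{self.near.spec_string()}>"
            f"delta={self.delta},h={self.h},d={self.d}"
        )


def quantize_record_with_context(cq: ContextQuantizer, record: FastqRecord) -> FastqRecord:
    """Apply the two-regime quantizer to one read; bases and headers unchanged."""
    mask = repeat_mask(record.sequence, cq.h, cq.d, cq.delta)
    scores = [
        (cq.near if near else cq.far)(s) for s, near in zip(record.scores, mask)
    ]
    return FastqRecord(
        header=record.header,
        sequence=record.sequence,
        scores=scores,
        separator=record.separator,
    )
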