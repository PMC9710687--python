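"""Position-independent quality-score quantizers.

An interval quantizer partitions the nanopore score domain [0, 93] into
contiguous bins, each mapped to one representative value inside the bin; a
constant quantizer F_z maps every score to the fixed value z.  The built-ins
are the standard 2/4/8-level maps plus F10 (10 being a common low-quality
read-filtering threshold):

    Q2:  0-7 -> 5,  8-93 -> 15
    Q4:  0-7 -> 5,  8-13 -> 12, 14-19 -> 18, 20-93 -> 24
    Q8:  0-6 -> 5,  7-11 -> 10, 12-16 -> 15, 17-21 -> 20,
         22-26 -> 25, 27-31 -> 30, 32-36 -> 35, 37-93 -> 40
    F10: every score -> 10

Collapsing the large high-score range into one value while keeping finer
resolution for the frequent low scores is what makes quantized files gzip so
much smaller with little downstream effect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

from .errors import QuantizerSpecError, ScoreRangeError
from .fastq_io import MAX_SCORE, FastqRecord


def _check_score(x: int) -> None:
    if not 0 <= x <= MAX_SCORE:
        raise ScoreRangeError(f"score {x} outside [0, {MAX_SCORE}]")


@dataclass(frozen=True)
class IntervalQuantizer:
    """Total monotone map from [0, 93] onto a small alphabet via contiguous bins.

    ``bins`` is an ordered tuple of ``(low, high, value)`` with inclusive
    bounds.  Bins must partition [0, 93] exactly, values must be strictly
    increasing, and each value must lie inside its own bin — the latter makes
    the map idempotent, so re-quantizing an already quantized file is a no-op.
    """

    bins: tuple[tuple[int, int, int], ...]
    name: str = ""
    _table: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.bins:
            raise QuantizerSpecError("quantizer needs at least one bin")
        expected_low = 0
        prev_value: int | None = None
        for i, (low, high, value) in enumerate(self.bins):
            label = f"bin {i} ({low}-{high}:{value})"
            if low != expected_low:
                if low > expected_low:
                    raise QuantizerSpecError(
                        f"{label}: scores {expected_low}-{low - 1} are uncovered"
                    )
                raise QuantizerSpecError(f"{label}: overlaps the previous bin")
            if low > high:
                raise QuantizerSpecError(f"{label}: low > high")
            if not (0 <= value <= MAX_SCORE):
                raise QuantizerSpecError(f"{label}: value outside [0, {MAX_SCORE}]")
            if not (low <= value <= high):
                raise QuantizerSpecError(
                    f"{label}: value must lie inside its own interval"
                )
            if prev_value is not None and value <= prev_value:
                raise QuantizerSpecError(f"{label}: values must be strictly increasing")
            prev_value = value
            expected_low = high + 1
        if expected_low != MAX_SCORE + 1:
            raise QuantizerSpecError(
                f"last bin ends at {expected_low - 1}, scores up to {MAX_SCORE} uncovered"
            )
        table = []
        for low, high, value in self.bins:
            table.extend([value] * (high - low + 1))
        object.__setattr__(self, "_table", tuple(table))

    @property
    def alphabet_size(self) -> int:
        return len({v for _, _, v in self.bins})

    @property
    def alphabet(self) -> tuple[int, ...]:
        return tuple(sorted({v for _, _, v in self.bins}))

    def __call__(self, x: int) -> int:
        _check_score(x)
        return self._table[x]

    def spec_string(self) -> str:
        return ",".join(f"{lo}-{hi}:{v}" for lo, hi, v in self.bins)


@dataclass(frozen=True)
class ConstantQuantizer:
    """F_z: maps every score in [0, 93] to the fixed value ``z``."""

    z: int
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.z <= MAX_SCORE:
            raise QuantizerSpecError(f"constant value {self.z} outside [0, {MAX_SCORE}]")

    @property
    def alphabet_size(self) -> int:
        return 1

    @property
    def alphabet(self) -> tuple[int, ...]:
        return (self.z,)

    def __call__(self, x: int) -> int:
        _check_score(x)
        return self.z

    def spec_string(self) -> str:
        return f"F:{self.z}"


Quantizer = Union[IntervalQuantizer, ConstantQuantizer]

_BUILTIN_BINS = {
    "Q2": ((0, 7, 5), (8, 93, 15)),
    "Q4": ((0, 7, 5), (8, 13, 12), (14, 19, 18), (20, 93, 24)),
    "Q8": (
        (0, 6, 5),
        (7, 11, 10),
        (12, 16, 15),
        (17, 21, 20),
        (22, 26, 25),
        (27, 31, 30),
        (32, 36, 35),
        (37, 93, 40),
    ),
}

BUILTIN_NAMES = ("Q2", "Q4", "Q8", "F10")


def builtin_quantizer(name: str) -> Quantizer:
    """Return one of the built-in quantizers Q2, Q4, Q8 or F10 by name."""
    key = name.strip().upper()
    if key in _BUILTIN_BINS:
        return IntervalQuantizer(_BUILTIN_BINS[key], name=key)
    if key == "F10":
        return ConstantQuantizer(10, name="F10")
    raise LookupError(
        f"unknown quantizer {name!r}; valid names: {', '.join(BUILTIN_NAMES)}"
    )


_BIN_RE = re.compile(r"^(\d+)-(\d+):(\d+)$")


def parse_quantizer_spec(spec: str) -> Quantizer:
    """Parse a quantizer description.

    Grammar: a builtin name (``Q2``/``Q4``/``Q8``/``F10``), ``F:<z>`` for a
    constant quantizer, or comma-separated ``<low>-<high>:<value>`` bins in
    ascending order covering 0-93 exactly.
    """
    text = spec.strip()
    if text.upper() in BUILTIN_NAMES:
        return builtin_quantizer(text)
    if text.upper().startswith("F:"):
        body = text[2:]
        if not body.isdigit():
            raise QuantizerSpecError(f"constant quantizer spec {spec!r}: expected F:<int>")
        return ConstantQuantizer(int(body))
    bins = []
    for piece in text.split(","):
        m = _BIN_RE.match(piece.strip())
        if m is None:
            raise QuantizerSpecError(
                f"bad bin {piece.strip()!r} in {spec!r}; expected <low>-<high>:<value>"
            )
        bins.append((int(m.group(1)), int(m.group(2)), int(m.group(3))))
    return IntervalQuantizer(tuple(bins))


def quantize_score(q: Quantizer, x: int) -> int:
    """Apply a quantizer to a single Phred score."""
    return q(x)


def quantize_record(q: Quantizer, record: FastqRecord) -> FastqRecord:
    """Quantize a read's scores elementwise; bases, header, separator untouched."""
    return FastqRecord(
        header=record.header,
        sequence=record.sequence,
        scores=[q(s) for s in record.scores],
        separator=record.separator,
    )
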