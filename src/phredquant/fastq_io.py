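"""Streaming FASTQ I/O with a Phred+33 codec, gzip transparency and seeded downsampling.

Only the 4-line FASTQ dialect is accepted (one record = header / bases /
separator / quality), which is what nanopore basecallers emit.  Records are
yielded one at a time so peak memory is bounded by the longest read, not the
file.  Oxford Nanopore quality scores span 0..93, stored as ASCII 33..126.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import IO, Iterable, Iterator, Union

import numpy as np

from .errors import FastqFormatError, MalformedQualityError, ScoreRangeError

PHRED_OFFSET = 33
MAX_SCORE = 93  # ASCII 126 - 33

PathOrStream = Union[str, "PathLike[str]", IO[bytes]]


@dataclass
class FastqRecord:
    """One sequencing read.

    ``header`` is line 1 without the leading ``@``; ``separator`` is line 3
    without the leading ``+`` (often empty, sometimes a repeat of the header —
    it is preserved verbatim).  ``scores`` are integer Phred values, one per
    base.
    """

    header: str
    sequence: str
    scores: list[int]
    separator: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.scores):
            raise FastqFormatError(
                f"record {self.header!r}: sequence length {len(self.sequence)} "
                f"!= number of quality scores {len(self.scores)}"
            )
        if "\n" in self.header or "\r" in self.header:
            raise FastqFormatError(f"record {self.header!r}: header contains a line break")
        if "\n" in self.separator or "\r" in self.separator:
            raise FastqFormatError(f"record {self.header!r}: separator contains a line break")
        for j, s in enumerate(self.scores):
            if not 0 <= s <= MAX_SCORE:
                raise ScoreRangeError(
                    f"record {self.header!r}, position {j}: score {s} outside [0, {MAX_SCORE}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def decode_quality(encoded: str, *, where: str = "") -> list[int]:
    """Map a Phred+33 quality string to integer scores (ASCII code minus 33)."""
    scores = []
    for j, ch in enumerate(encoded):
        code = ord(ch)
        if not 33 <= code <= 126:
            ctx = f" in {where}" if where else ""
            raise MalformedQualityError(
                f"quality character {ch!r} (code {code}) at position {j}{ctx} "
                "is outside ASCII 33-126"
            )
        scores.append(code - PHRED_OFFSET)
    return scores


def encode_quality(scores: Iterable[int]) -> str:
    """Inverse of :func:`decode_quality`; exact round trip on [0, 93]."""
    chars = []
    for j, s in enumerate(scores):
        if not 0 <= s <= MAX_SCORE:
            raise ScoreRangeError(f"score {s} at position {j} outside [0, {MAX_SCORE}]")
        chars.append(chr(s + PHRED_OFFSET))
    return "".join(chars)


def _open_source(source: PathOrStream, gzip_auto: bool) -> IO[bytes]:
    if hasattr(source, "read"):
        raw: IO[bytes] = source  # type: ignore[assignment]
    else:
        raw = open(source, "rb")
    if gzip_auto:
        buffered = raw if isinstance(raw, io.BufferedReader) else io.BufferedReader(raw)  # type: ignore[arg-type]
        magic = buffered.peek(2)[:2]
        if magic == b"\x1f\x8b":
            return gzip.open(buffered, "rb")  # type: ignore[return-value]
        return buffered
    return raw


def read_fastq(source: PathOrStream, *, gzip_auto: bool = True) -> Iterator[FastqRecord]:
    """Stream records from a 4-line FASTQ file, plain or gzip.

    Gzip is detected from the magic bytes ``1f 8b``, not the file name.
    Raises :class:`FastqFormatError` on truncated records, wrong sigil lines
    or base/quality length mismatches, naming the 1-based record ordinal.
    """
    handle = _open_source(source, gzip_auto)
    text = io.TextIOWrapper(handle, encoding="ascii", errors="strict")
    ordinal = 0
    try:
        while True:
            line1 = text.readline()
            if line1 == "":
                return
            ordinal += 1
            lines = [line1]
            for _ in range(3):
                nxt = text.readline()
                if nxt == "":
                    raise FastqFormatError(
                        f"record {ordinal}: file truncated mid-record "
                        f"(got {len(lines)} of 4 lines)"
                    )
                lines.append(nxt)
            lines = [ln.rstrip("\n").rstrip("\r") for ln in lines]
            if not lines[0].startswith("@"):
                raise FastqFormatError(
                    f"record {ordinal}: header line does not start with '@': {lines[0]!r}"
                )
            if not lines[2].startswith("+"):
                raise FastqFormatError(
                    f"record {ordinal}: separator line does not start with '+': {lines[2]!r}"
                )
            header = lines[0][1:]
            sequence = lines[1]
            separator = lines[2][1:]
            if len(sequence) != len(lines[3]):
                raise FastqFormatError(
                    f"record {ordinal} ({header!r}): {len(sequence)} bases but "
                    f"{len(lines[3])} quality characters"
                )
            scores = decode_quality(lines[3], where=f"record {ordinal} ({header!r})")
            yield FastqRecord(header, sequence, scores, separator)
    finally:
        text.close()


def write_fastq(
    records: Iterable[FastqRecord], sink: PathOrStream, *, gzip_out: bool = False
) -> int:
    """Write records as 4-line FASTQ; returns the number written.

    Headers and separator descriptions are emitted verbatim, so
    parse-then-write of an untransformed LF-terminated file is byte-identical.
    """
    if hasattr(sink, "write"):
        raw: IO[bytes] = sink  # type: ignore[assignment]
        close_raw = False
    else:
        raw = open(sink, "wb")
        close_raw = True
    handle: IO[bytes] = gzip.open(raw, "wb") if gzip_out else raw
    n = 0
    try:
        for rec in records:
            block = (
                f"@{rec.header}\n{rec.sequence}\n+{rec.separator}\n"
                f"{encode_quality(rec.scores)}\n"
            )
            handle.write(block.encode("ascii"))
            n += 1
    finally:
        if gzip_out:
            handle.close()
        if close_raw:
            raw.close()
    return n


def downsample_reads(
    records: Iterable[FastqRecord], fraction: float, seed: int
) -> list[FastqRecord]:
    """Select exactly ``round(fraction * N)`` reads uniformly without replacement.

    Rounding is half-up; relative input order is preserved; the same
    (input, fraction, seed) always selects the same reads.  This emulates
    coverage titration, e.g. keeping 10/20/60/100% of a dataset's reads.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    pool = list(records)
    n = len(pool)
    k = int(math.floor(fraction * n + 0.5))
    if k >= n:
        return pool if fraction == 1.0 or k == n else pool
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=k, replace=False))
    return [pool[i] for i in chosen]
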