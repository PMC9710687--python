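"""Seeded generator of nanopore-like FASTQ with planted repeats and exact ground truth.

The generator emulates the two features of nanopore reads the quantizers
care about: a low-skewed quality-score distribution (most scores between
~5 and ~20, a thin tail of higher scores) and repetitive base context
(homopolymers and dinucleotide repeats).  Background sequence is i.i.d. over
{A, C, G, T}, rejection-checked so it never creates an unplanned
homopolymer of length >= h or an alternation of length >= 2*d — planted
repeats are therefore the *only* repetitive intervals, and the ground-truth
annotation is exhaustive.  It makes no claim of signal-level or error-model
realism; it is a fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError
from .fastq_io import MAX_SCORE, FastqRecord
from .repeats import DINUCLEOTIDE, HOMOPOLYMER, RepeatInterval

_BASES = "ACGT"


def default_score_law() -> np.ndarray:
    """Discrete score distribution over [0, 93], peaked near 8-14 with a thin tail.

    A 0.85/0.15 mixture of two discretized gammas (modes ~11 and ~25),
    qualitatively matching the low-skewed histograms nanopore basecallers
    produce.
    """
    x = np.arange(MAX_SCORE + 1)
    body = stats.gamma.pdf(x, a=5.0, scale=2.8)
    tail = stats.gamma.pdf(x, a=6.0, scale=5.0)
    p = 0.85 * body + 0.15 * tail
    return p / p.sum()


@dataclass(frozen=True)
class RepeatPlant:
    """One repeat to plant: ``unit`` repeated ``copies`` times at ``start`` of ``read``."""

    read: int
    kind: str  # HOMOPOLYMER or DINUCLEOTIDE
    unit: str
    copies: int
    start: int

    def __post_init__(self) -> None:
        if self.kind not in (HOMOPOLYMER, DINUCLEOTIDE):
            raise ConfigError(f"unknown repeat kind {self.kind!r}")
        if self.kind == HOMOPOLYMER and len(self.unit) != 1:
            raise ConfigError(f"homopolymer unit must be one letter, got {self.unit!r}")
        if self.kind == DINUCLEOTIDE:
            if len(self.unit) != 2 or self.unit[0] == self.unit[1]:
                raise ConfigError(
                    f"dinucleotide unit must be two distinct letters, got {self.unit!r}"
                )
        if self.copies < 1 or self.start < 0 or self.read < 0:
            raise ConfigError("copies must be >= 1 and read/start non-negative")

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies

    @property
    def end(self) -> int:
        return self.start + self.length

    def bases(self) -> str:
        return self.unit * self.copies


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    ``length_law`` is (mean, shape) of a gamma read-length distribution
    (shape 4 gives a realistic ~50% coefficient of variation); ``score_law``
    is a probability vector over scores 0..93.  ``repeat_plan`` places
    explicit repeats; ``auto_plants_per_read`` additionally plants that many
    randomly chosen detectable repeats in every read.
    """

    n_reads: int = 100
    length_law: tuple[float, float] = (4000.0, 4.0)
    score_law: np.ndarray | None = None
    repeat_plan: Sequence[RepeatPlant] = ()
    auto_plants_per_read: int = 1
    h: int = 5
    d: int = 4
    min_length: int = 30
    seed: int = 0

    def resolved_score_law(self) -> np.ndarray:
        p = default_score_law() if self.score_law is None else np.asarray(self.score_law, float)
        if p.shape != (MAX_SCORE + 1,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ConfigError("score_law must be a probability vector over scores 0..93")
        return p / p.sum()

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")
        if self.h < 2 or self.d < 2:
            raise ConfigError("h and d must be >= 2")
        mean, shape = self.length_law
        if mean <= 0 or shape <= 0:
            raise ConfigError("length_law mean and shape must be positive")
        self.resolved_score_law()


def _alternation_through(t: bytearray, i: int, n: int) -> int:
    """Length of the maximal two-letter alternation containing position i.

    Unfilled positions (0 bytes) break runs.
    """
    b = i + 1
    while b < n and t[b] != 0 and t[b] != t[b - 1] and (b - 2 < i or t[b] == t[b - 2]):
        b += 1
    a = i
    while a > 0 and t[a - 1] != 0 and t[a - 1] != t[a] and (a + 1 >= b or t[a - 1] == t[a + 1]):
        a -= 1
    return b - a


def _homopolymer_through(t: bytearray, i: int, n: int) -> int:
    c = t[i]
    a = i
    while a > 0 and t[a - 1] == c:
        a -= 1
    b = i + 1
    while b < n and t[b] == c:
        b += 1
    return b - a


def _fill_background(t: bytearray, rng: np.random.Generator, h: int, d: int) -> None:
    """Fill unfilled positions left-to-right, rejecting bases that would create
    or extend a homopolymer run >= h or an alternation >= 2*d touching a
    background position."""
    n = len(t)
    lim_alt = 2 * d
    base_codes = tuple(ord(c) for c in _BASES)
    # one vectorized draw per read; rejected positions fall back to the next
    # base in rotation, which keeps generation deterministic and fast
    draws = rng.integers(0, 4, size=n)
    for i in range(n):
        if t[i] != 0:
            continue
        first = draws[i]
        placed = False
        for step in range(4):
            t[i] = base_codes[(first + step) & 3]
            if _homopolymer_through(t, i, n) >= h:
                continue
            if _alternation_through(t, i, n) >= lim_alt:
                continue
            placed = True
            break
        if not placed:
            t[i] = 0
            raise ConfigError(
                f"no base can be placed at position {i} without creating an "
                "unplanned repeat; plants are too tightly packed"
            )


def _auto_plants(
    rng: np.random.Generator,
    read: int,
    length: int,
    count: int,
    h: int,
    d: int,
    occupied: list[tuple[int, int]],
) -> list[RepeatPlant]:
    plants = []
    for _ in range(count):
        for _attempt in range(20):
            if rng.random() < 0.5:
                unit = _BASES[rng.integers(4)]
                copies = int(rng.integers(h, h + 4))
            else:
                a, b = rng.choice(4, size=2, replace=False)
                unit = _BASES[a] + _BASES[b]
                copies = int(rng.integers(d, d + 3))
            plen = len(unit) * copies
            if plen + 2 > length:
                break
            start = int(rng.integers(1, length - plen))
            # keep >= 2 background bases between plants
            if any(start < e + 2 and s < start + plen + 2 for s, e in occupied):
                continue
            kind = HOMOPOLYMER if len(unit) == 1 else DINUCLEOTIDE
            plants.append(RepeatPlant(read, kind, unit, copies, start))
            occupied.append((start, start + plen))
            break
    return plants


def simulate_fastq(
    cfg: SimulationConfig,
) -> tuple[list[FastqRecord], list[list[RepeatInterval]]]:
    """Generate reads and the exhaustive per-read ground-truth repeat intervals.

    Deterministic given ``cfg.seed``.  Ground truth lists every planted repeat
    that meets the detection thresholds (length >= h for homopolymers,
    >= d copies for dinucleotide units); sub-threshold plants are realized in
    the sequence but not annotated.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    score_p = cfg.resolved_score_law()
    mean, shape = cfg.length_law
    lengths = np.maximum(
        cfg.min_length,
        np.round(rng.gamma(shape, mean / shape, size=cfg.n_reads)).astype(int),
    )

    by_read: dict[int, list[RepeatPlant]] = {}
    for plant in cfg.repeat_plan:
        if plant.read >= cfg.n_reads:
            raise ConfigError(f"plant targets read {plant.read} but only {cfg.n_reads} reads")
        if plant.end > lengths[plant.read]:
            raise ConfigError(
                f"plant {plant.unit!r} x{plant.copies} at {plant.start} does not fit "
                f"in read {plant.read} (length {lengths[plant.read]})"
            )
        by_read.setdefault(plant.read, []).append(plant)

    records: list[FastqRecord] = []
    truths: list[list[RepeatInterval]] = []
    for r in range(cfg.n_reads):
        n = int(lengths[r])
        plants = sorted(by_read.get(r, []), key=lambda p: p.start)
        for prev, cur in zip(plants, plants[1:]):
            if cur.start < prev.end + 1:
                raise ConfigError(
                    f"read {r}: plants at {prev.start} and {cur.start} overlap or touch"
                )
        occupied = [(p.start, p.end) for p in plants]
        plants += _auto_plants(rng, r, n, cfg.auto_plants_per_read, cfg.h, cfg.d, occupied)
        plants.sort(key=lambda p: p.start)

        t = bytearray(n)
        for p in plants:
            t[p.start : p.end] = p.bases().encode("ascii")
        _fill_background(t, rng, cfg.h, cfg.d)
        sequence = t.decode("ascii")

        scores = rng.choice(MAX_SCORE + 1, size=n, p=score_p).tolist()
        records.append(FastqRecord(header=f"sim_{cfg.seed}_{r}", sequence=sequence, scores=scores))

        truth = [
            RepeatInterval(p.start, p.end, p.kind)
            for p in plants
            if (p.kind == HOMOPOLYMER and p.length >= cfg.h)
            or (p.kind == DINUCLEOTIDE and p.copies >= cfg.d)
        ]
        truths.append(sorted(truth, key=lambda iv: iv.start))
    return records, truths


def write_truth_bed(truths: list[list[RepeatInterval]], records: list[FastqRecord], path) -> None:
    """Write ground truth as a BED-like TSV: read-id, start, end, kind (0-based half-open)."""
    with open(path, "w") as fh:
        for rec, ivs in zip(records, truths):
            for iv in ivs:
                fh.write(f"{rec.header}\t{iv.start}\t{iv.end}\t{iv.kind}\n")
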