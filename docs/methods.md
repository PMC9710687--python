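# Methods

## Score domain and codec

Nanopore FASTQ quality scores are integers 0–93, stored as ASCII 33–126
(Phred+33). The codec is total on that domain and strict outside it: a
quality character below 33 or above 126 aborts parsing with an error naming
the record and position, rather than being clipped — such bytes indicate a
corrupt file, not a score. Only the 4-line FASTQ dialect is accepted
(nanopore basecallers emit it); this removes the classic ambiguity of
wrapped FASTQ where a quality line may begin with `+`. Headers and the
optional description after `+` are preserved verbatim, so an untransformed
parse-then-write round trip is byte-identical for LF-terminated files
(CRLF input is normalized to LF). Reading is streaming: memory is bounded
by the longest read, not the file.

## Quantizers

An interval quantizer is a total map q: [0,93] → [0,93] defined by an
ordered partition into contiguous bins, each with one representative value.
Three structural constraints are enforced at construction:

- the bins cover 0–93 exactly (no gaps or overlaps) — a partial map would
  silently pass through typos in a user spec;
- each representative lies inside its own bin — this makes q idempotent
  (q∘q = q), so re-running a quantization pipeline over already-quantized
  data is a no-op;
- representatives strictly increase across bins, so q is monotone and
  rank-based downstream heuristics are preserved. (Given disjoint ascending
  bins and in-bin representatives this is implied, but it is checked
  defensively.)

Constant quantizers F_z (every score → z) are supported for any z in
[0,93]; z = 10 is the built-in default because Q10 is a common
low-quality-read filtering threshold. The built-in interval maps Q2/Q4/Q8
collapse the large high-score range to a single value and keep finer bins
for low scores, which dominate nanopore score distributions.

Applying a quantizer to a record touches only the scores; bases, header and
separator are never rewritten.

## Repeat context

A read substring is *repetitive* if it is a homopolymer of length ≥ h or
≥ d consecutive copies of a two-base unit. Interpretation choices, stated
because off-by-one conventions differ:

- "homopolymer of length h" is read as a maximal run of length ≥ h;
- dinucleotide units with equal letters ("AA") are excluded — those regions
  are homopolymers and governed by h, otherwise d = 4 would silently lower
  the homopolymer threshold to 8;
- both phase offsets of a unit count, and overlapping findings are merged,
  so a maximal two-letter alternation of length L qualifies iff L ≥ 2d and
  is reported as a single interval (touching but non-overlapping
  alternations of different units stay separate);
- detection is case-insensitive and treats `N` like any base — basecaller
  case varies, and excluding `N` would need a rule with no principled
  default;
- coordinates are 0-based, half-open.

The mask of the context quantizer ⟨f, f′⟩δ flags position j iff
s − δ ≤ j ≤ e − 1 + δ for some repetitive interval [s, e): the near-region
extends δ positions beyond each end, inclusive. f′ applies on flagged
positions, f elsewhere. Degenerate limits follow structurally: with no
repeats ⟨f,f′⟩δ ≡ f exactly; on an all-repeat read it is f′; the mask grows
monotonically with δ. Defaults h = 5, d = 4, δ = 5.

The scanner is linear-time; its correctness is established in the test
suite by exact equality against brute-force oracles that enumerate every
threshold-length window of the literal definitions, on planted fixtures and
on thousands of random sequences (lengths 1–300 over {A,C,G,T,N}).

## Evaluation arithmetic

Rec = TP/(TP+FN), Prec = TP/(TP+FP), F1 = 2·Prec·Rec/(Prec+Rec), with the
hap.py-style convention that 0/0 denominators yield 0, keeping the
functions total. Full precision is kept internally; the reporting helper
rounds half-up to 4 decimals to match how benchmark tables are printed.
When the bundled benchmark tables are re-derived from their printed integer
counts, agreement is asserted to one unit in the 4th decimal rather than
exact rounded equality: published tables carry the benchmarking tool's
full-precision metrics (query-side TP for precision, F1 from unrounded
P/R), so the last printed digit can differ by one from any value computable
from the printed counts. The bundled INDEL table's precision column is not
recomputable from its counts at all for that reason; only recall-from-counts
and F1-from-printed-P/R are checked there.

Compression ratio is compressed/original bytes (smaller is better); space
saving is 100·(baseline − variant)/baseline and may be negative. The CLI
compresses with the stdlib gzip codec at level 9 (the module default,
logged per run) instead of shelling out to a gzip binary: byte counts are
then reproducible across platforms for a given zlib, and only ratios and
orderings — never absolute byte counts — are asserted anywhere.

The zeroth-order empirical entropy −Σ p̂ log₂ p̂ of a score sequence is the
diagnostic connecting quantization to compressibility: any deterministic
symbol merging is a data-processing step, so entropy can only decrease, and
gzip output tracks it. The test suite asserts the inequality exactly and
the compression effect directionally (original > Q8 > Q4 > Q2 > F10 in
gzip bytes on identical synthetic input); absolute ratios on real datasets
depend on read-length mix and basecaller and are out of scope here.

## Downsampling

Coverage titration keeps exactly round(f·N) reads (half-up), selected
uniformly without replacement by a seeded generator over record indices,
preserving input order. Exact-count selection rather than per-record
Bernoulli trials makes runs reproducible and matches the notion of "a
fraction of the dataset's reads". Multi-file datasets are treated as one
concatenated stream per invocation. The selection necessarily materializes
the record list; streaming constant-memory behaviour applies to reading,
writing and quantization, not to downsampling.

## Synthetic data generator

The generator emulates exactly the two features of nanopore reads the
quantizers interact with, and nothing else:

- **Score distribution**: a 0.85/0.15 mixture of two discretized gammas
  (modes ≈ 11 and ≈ 25), giving the low-skewed bulk at scores ~5–20 with a
  thin tail — the qualitative shape of basecaller output. It is a fixture
  shape, not a claim of fidelity to any instrument or chemistry.
- **Repeat context**: repeats are *planted* (explicitly, or auto-placed per
  read), and the i.i.d. {A,C,G,T} background is rejection-checked base by
  base so that no unplanned homopolymer ≥ h or two-letter alternation ≥ 2d
  ever forms, including across plant boundaries. Planted repeats are
  therefore the only repetitive intervals, and the emitted ground-truth
  annotation (BED-like TSV: read, start, end, kind) is exhaustive — tests
  can assert exact equality between detector output and ground truth
  instead of fuzzy overlap.

Read lengths follow a gamma law parameterized by (mean, shape); the default
(4000, 4) gives a long-read length scale with ~50% coefficient of
variation. Everything is driven by one seeded generator, so identical
configurations produce byte-identical FASTQ.

What passing tests on this generator do **not** show: realism of error
models, signal-level effects, reference-conditioned sequence composition,
or the absolute compression ratios of real datasets. They show the
transformations and detectors are exactly correct on inputs whose ground
truth is known by construction.

## Problem sizes and numerical choices

Test corpora are sized to keep the full suite under half a minute on one
core: the round-trip/downsampling check uses 100 000 reads of mean length
60, the compressibility ordering 400 reads of mean length 600, the entropy
check 100 reads of mean length 500, and oracle equivalence 1000 random
sequences of length ≤ 300. These sizes are the package's own choices; every
property they check is size-independent. Ties in half-up rounding are
resolved via decimal arithmetic, not binary floats. All randomness flows
from explicit integer seeds; there is no hidden global RNG state.

## Known limitations

- No FAST5/POD5, SAM/BAM or Phred+64 support; 4-line FASTQ only.
- Repeat context is limited to homopolymers and dinucleotide repeats;
  trinucleotide and longer tandem units are not detected.
- Quantizer bins are fixed, not rate-distortion optimized or trained per
  dataset; bin placement beyond the built-ins is the user's responsibility.
- Downsampling holds the read list in memory.
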