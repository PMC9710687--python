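"""FASTQ parsing/writing, the Phred+33 codec, gzip transparency, downsampling."""

import gzip
import io
import tracemalloc

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phredquant import (
    FastqFormatError,
    FastqRecord,
    MalformedQualityError,
    ScoreRangeError,
    decode_quality,
    downsample_reads,
    encode_quality,
    read_fastq,
    write_fastq,
)


class TestQualityCodec:
    @pytest.mark.parametrize(
        "encoded,scores",
        [("!", [0]), ("~", [93]), ("+5?", [10, 20, 30]), ("", [])],
    )
    def test_decode_known_values(self, encoded, scores):
        assert decode_quality(encoded) == scores

    @pytest.mark.parametrize(
        "scores,encoded", [([0], "!"), ([93], "~"), ([10, 10, 10], "+++")]
    )
    def test_encode_known_values(self, scores, encoded):
        assert encode_quality(scores) == encoded

    def test_decode_rejects_out_of_range_character(self):
        with pytest.raises(MalformedQualityError, match="position 1"):
            decode_quality("I\x1fI")

    def test_encode_rejects_out_of_range_score(self):
        with pytest.raises(ScoreRangeError):
            encode_quality([0, 94])
        with pytest.raises(ScoreRangeError):
            encode_quality([-1])

    @given(st.lists(st.integers(min_value=0, max_value=93), max_size=200))
    @settings(max_examples=200, derandomize=True)
    def test_codec_round_trip(self, scores):
        assert decode_quality(encode_quality(scores)) == scores


class TestReadWrite:
    def test_parse_well_formed_two_records(self, two_record_fastq_text):
        recs = list(read_fastq(io.BytesIO(two_record_fastq_text.encode())))
        assert len(recs) == 2
        r1, r2 = recs
        assert r1.header == "read1 desc"
        assert r1.sequence == "ACGTACGTAC"
        assert r1.scores == [0, 10, 20, 30, 40, 40, 40, 40, 93, 93]
        assert r1.separator == ""
        assert r2.separator == "read2"
        assert r2.scores == [26] * 5

    def test_gzip_input_transparent(self, two_record_fastq_text):
        plain = list(read_fastq(io.BytesIO(two_record_fastq_text.encode())))
        gz = list(read_fastq(io.BytesIO(gzip.compress(two_record_fastq_text.encode()))))
        assert gz == plain

    def test_byte_identity_round_trip(self, two_record_fastq_text, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text(two_record_fastq_text)
        out = tmp_path / "out.fastq"
        n = write_fastq(read_fastq(src), out)
        assert n == 2
        assert out.read_bytes() == src.read_bytes()

    def test_gzip_output_reparses(self, two_record_fastq_text, tmp_path):
        out = tmp_path / "out.fastq.gz"
        recs = list(read_fastq(io.BytesIO(two_record_fastq_text.encode())))
        assert write_fastq(recs, out, gzip_out=True) == 2
        assert out.read_bytes()[:2] == b"\x1f\x8b"
        assert list(read_fastq(out)) == recs

    def test_empty_stream_writes_empty_file(self, tmp_path):
        out = tmp_path / "empty.fastq"
        assert write_fastq([], out) == 0
        assert out.read_bytes() == b""
        assert list(read_fastq(out)) == []

    def test_length_mismatch_names_record_ordinal(self):
        bad = "@r1\nACGT\n+\nIIII\n@r2\nACGTG\n+\nIIII\n"
        with pytest.raises(FastqFormatError, match="record 2"):
            list(read_fastq(io.BytesIO(bad.encode())))

    def test_truncated_record_raises(self):
        bad = "@r1\nACGT\n+\n"
        with pytest.raises(FastqFormatError, match="truncated"):
            list(read_fastq(io.BytesIO(bad.encode())))

    @pytest.mark.parametrize(
        "text", ["r1\nACGT\n+\nIIII\n", "@r1\nACGT\n-\nIIII\n"]
    )
    def test_bad_sigil_lines_raise(self, text):
        with pytest.raises(FastqFormatError):
            list(read_fastq(io.BytesIO(text.encode())))

    def test_record_invariants_enforced(self):
        with pytest.raises(FastqFormatError):
            FastqRecord("r", "ACGT", [1, 2, 3])
        with pytest.raises(ScoreRangeError):
            FastqRecord("r", "A", [94])

    def test_streaming_memory_bounded(self, tmp_path):
        # memory while streaming must track the longest read, not the file
        path = tmp_path / "big.fastq"
        with open(path, "w") as fh:
            for i in range(20000):
                fh.write(f"@r{i}\n{'ACGT' * 25}\n+\n{'I' * 100}\n")
        file_bytes = path.stat().st_size
        tracemalloc.start()
        total = sum(1 for _ in read_fastq(path))
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        assert total == 20000
        assert peak < file_bytes / 4


class TestDownsampling:
    def _records(self, n):
        return [FastqRecord(f"r{i}", "ACGT", [10, 11, 12, 13]) for i in range(n)]

    def test_fraction_one_keeps_everything_in_order(self):
        recs = self._records(10)
        assert downsample_reads(recs, 1.0, seed=3) == recs

    def test_fraction_zero_empty(self):
        assert downsample_reads(self._records(10), 0.0, seed=3) == []

    def test_exact_count_order_and_determinism(self):
        recs = self._records(10)
        sub = downsample_reads(recs, 0.5, seed=11)
        assert len(sub) == 5
        # subsequence of input
        idx = [recs.index(r) for r in sub]
        assert idx == sorted(idx)
        assert downsample_reads(recs, 0.5, seed=11) == sub
        assert downsample_reads(recs, 0.5, seed=12) != sub

    @pytest.mark.parametrize("n,frac,expect", [(10, 0.25, 3), (3, 0.5, 2), (7, 0.1, 1)])
    def test_half_up_rounding_of_cardinality(self, n, frac, expect):
        assert len(downsample_reads(self._records(n), frac, seed=0)) == expect

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            downsample_reads(self._records(3), 1.5, seed=0)

    def test_selection_is_uniform_ish(self):
        # every read should be selected in roughly half of many seeded draws
        recs = self._records(20)
        hits = np.zeros(20)
        for seed in range(200):
            for r in downsample_reads(recs, 0.5, seed=seed):
                hits[int(r.header[1:])] += 1
        assert (hits > 60).all() and (hits < 140).all()
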