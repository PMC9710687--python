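"""Exception hierarchy shared across the package."""


class PhredquantError(Exception):
    """Base class for all package-specific errors."""


class FastqFormatError(PhredquantError):
    """Structurally invalid FASTQ input (bad sigil lines, length mismatch, truncation)."""


class MalformedQualityError(FastqFormatError):
    """Quality string contains a character outside ASCII 33-126."""


class ScoreRangeError(PhredquantError, ValueError):
    """Phred score outside the nanopore domain [0, 93]."""


class QuantizerSpecError(PhredquantError, ValueError):
    """Quantizer definition violates the interval-partition contract."""


class ConfigError(PhredquantError, ValueError):
    """Invalid simulation or run configuration."""
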