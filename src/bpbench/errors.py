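"""Exception taxonomy shared across the benchmark."""


class BPBenchError(Exception):
    """Base class for all bpbench errors."""


class SpecificationError(BPBenchError, ValueError):
    """A generator or pipeline specification violates one of its invariants."""


class ConfigurationError(BPBenchError, ValueError):
    """Invalid run-time configuration (fold counts, fractions, thresholds...)."""


class DataError(BPBenchError, ValueError):
    """Malformed input data (NaNs, missing labels, unknown subjects...)."""


class AlignmentError(BPBenchError):
    """Cross-correlation alignment is undefined (e.g. constant signals)."""


class LabelingError(BPBenchError):
    """BP label extraction failed (no detectable cardiac cycles)."""


class FeatureFailure(BPBenchError):
    """A landmark or feature could not be computed for a segment.

    Carries the name of the first missing landmark/feature so that the
    preprocessing audit can attribute the removal.
    """

    def __init__(self, missing: str, detail: str = ""):
        self.missing = missing
        super().__init__(f"feature extraction failed: missing {missing!r}"
                         + (f" ({detail})" if detail else ""))


class PairingError(BPBenchError, ValueError):
    """Two prediction sets do not cover the same segments."""


class CoverageError(BPBenchError, ValueError):
    """Pooled predictions do not cover every segment exactly once."""


class UndefinedMetricError(BPBenchError, ZeroDivisionError):
    """A metric is undefined for the given inputs (e.g. MAE_naive == 0)."""
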