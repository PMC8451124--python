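"""Exception types shared across the pipeline."""


class CoauthnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CoauthnetError):
    """A config value is out of range or a required mapping is missing."""


class CorpusReadError(CoauthnetError):
    """Raised in strict mode when one or more input rows are malformed.

    The ``row_errors`` attribute lists ``(row_number, message)`` pairs.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {n}: {msg}" for n, msg in self.row_errors[:10])
        suffix = " ..." if len(self.row_errors) > 10 else ""
        super().__init__(f"{len(self.row_errors)} malformed row(s): {lines}{suffix}")


class UnresolvedCountryError(CoauthnetError):
    """Country parsing left unresolved mentions where resolved ones are required."""

    def __init__(self, pub_ids):
        self.pub_ids = sorted(pub_ids)
        super().__init__(
            f"{len(self.pub_ids)} record(s) contain unresolved countries: "
            + ", ".join(self.pub_ids[:10])
            + (" ..." if len(self.pub_ids) > 10 else "")
        )


class UndefinedMetricError(CoauthnetError):
    """A metric is mathematically undefined on this input (e.g., zero denominator)."""


class PipelineError(CoauthnetError):
    """A pipeline stage failed; the message names the stage and context."""
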