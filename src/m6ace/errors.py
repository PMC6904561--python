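"""Exception hierarchy. Every user-facing failure maps onto one of these."""


class M6aceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(M6aceError):
    """Invalid or inconsistent configuration (e.g. missing spike-in contig)."""


class FormatError(M6aceError):
    """Malformed input file or record."""


class AnalysisError(M6aceError):
    """A computation cannot proceed on the given data (e.g. empty site set)."""
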