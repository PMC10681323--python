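"""Exception hierarchy for reeftrace."""


class ReeftraceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ReeftraceError):
    """Invalid configuration or input file layout (e.g. a missing column)."""


class DataIntegrityError(ReeftraceError):
    """Inconsistent input data, e.g. overlapping receiver deployments."""


class RowParseError(ReeftraceError):
    """Too many malformed rows in a detection export."""


class MetadataError(ReeftraceError):
    """Invalid tag or shark metadata (e.g. non-positive monitoring period)."""
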