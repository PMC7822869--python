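"""Exception types shared across the pipeline."""


class SynaptoshiftError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SynaptoshiftError, ValueError):
    """An input file violates its declared tabular format or invariants."""


class ConfigurationError(SynaptoshiftError, ValueError):
    """A configuration value or study design is invalid; names the offending field."""


class PairingError(SynaptoshiftError, ValueError):
    """A subject is missing one of its two fraction profiles; names the subject."""


class InsufficientDataError(SynaptoshiftError, ValueError):
    """Too few observations to compute the requested statistic."""
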