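"""Exception types shared across the pipeline."""


class MilknirError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MilknirError, ValueError):
    """A configuration object or parameter set is invalid or infeasible."""


class ParseError(MilknirError, ValueError):
    """An input file could not be parsed; the message names the offender."""


class DegenerateDataError(MilknirError, ValueError):
    """The data do not support the requested operation (rank, variance...)."""
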