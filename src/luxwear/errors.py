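"""Exception hierarchy.

``DataError`` marks problems in the measured/labelled inputs (non-monotonic
timestamps, overlapping diary intervals, missing classes); ``ConfigurationError``
marks invalid caller-supplied settings (bad column mapping, epoch outside the
supported set). The CLI maps both to exit status 1.
"""


class LuxwearError(Exception):
    """Base class for all package-specific errors."""


class DataError(LuxwearError):
    """Input data violates a contract of the pipeline."""


class ConfigurationError(LuxwearError):
    """Caller-supplied configuration is invalid."""
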