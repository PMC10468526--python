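"""Exception hierarchy.

All failures raised by this package derive from :class:`AgescreenError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors. The three subclasses separate bad configuration, malformed input
files, and analysis preconditions that the data itself violates.
"""


class AgescreenError(Exception):
    """Base class for all errors raised by agescreen."""


class ConfigurationError(AgescreenError):
    """A configuration value is invalid; the message names the field."""


class InputFormatError(AgescreenError):
    """An input file is missing, unreadable, or malformed."""


class AnalysisError(AgescreenError):
    """Input data violates a precondition of an analysis step."""
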