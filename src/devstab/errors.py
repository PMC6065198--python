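"""Exception hierarchy shared across the toolkit."""


class DevstabError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(DevstabError, ValueError):
    """An argument violates a precondition (bad variance, count, index...)."""


class FormatError(DevstabError, ValueError):
    """An input file is malformed; the message names the offending row/line."""


class DesignError(DevstabError, ValueError):
    """A dataset violates the balanced-design requirements of an analysis."""


class ConfigError(DevstabError, ValueError):
    """A pipeline run configuration is invalid."""
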