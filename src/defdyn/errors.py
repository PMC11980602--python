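"""Exception hierarchy for the defdyn pipeline."""


class DefdynError(Exception):
    """Base class for all defdyn errors."""


class ConfigError(DefdynError):
    """A configuration value is out of range or inconsistent.

    The message always names the offending field.
    """


class InputError(DefdynError):
    """An input table, sequence set or file is malformed or missing."""


class AnalysisError(DefdynError):
    """A statistic is undefined for the given input (e.g. constant series)."""
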