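"""Exception hierarchy shared by all pipeline stages."""


class GermclockError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GermclockError):
    """An input file violates its declared dialect (bad value, missing
    column, malformed bin code...). The message names the offending
    coordinates where they are known."""


class ConfigError(GermclockError):
    """A configuration value is invalid or inconsistent with the data
    (unknown stage, empty universe, replicate count exceeded...)."""


class InputError(GermclockError):
    """A programmatic input violates a documented precondition
    (e.g. an impossible contingency table)."""
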