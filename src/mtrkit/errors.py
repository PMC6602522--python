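"""Exception hierarchy for mtrkit."""


class MtrkitError(Exception):
    """Base class for all mtrkit errors."""


class InvalidSequenceError(MtrkitError):
    """A coding sequence is malformed (wrong length, ambiguous bases, ...)."""


class InvalidVariantError(MtrkitError):
    """A variant description is internally inconsistent (e.g. ref == alt)."""


class InvalidParameterError(MtrkitError):
    """A numeric parameter is out of its valid range (e.g. even window size)."""


class DegenerateWindowError(MtrkitError):
    """A window has no expected variants, so no null proportion exists."""


class QueryParseError(MtrkitError):
    """A variant-query line matches none of the supported formats."""


class ConfigError(MtrkitError):
    """A run or scenario configuration violates its schema."""
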