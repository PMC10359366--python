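"""Exception hierarchy shared across the package.

``DataError`` covers malformed or inconsistent input data (bad file rows,
invariant violations at parse time, mismatched gene sets); ``ConfigError``
covers invalid configuration. The CLI maps them to distinct exit codes.
"""


class SpexError(Exception):
    """Base class for package errors."""


class ConfigError(SpexError):
    """Invalid or inconsistent configuration."""


class DataError(SpexError):
    """Malformed input data or violated data invariant."""
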