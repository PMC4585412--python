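"""Exception hierarchy shared across the package.

The CLI maps :class:`InputError` to exit code 2 and :class:`ConfigError`
to exit code 3.
"""


class LeafScoreError(Exception):
    """Base class for all package errors."""


class InputError(LeafScoreError):
    """Unreadable, malformed, or inconsistent input data."""


class ConfigError(LeafScoreError):
    """Invalid configuration value or file."""


class CapacityError(LeafScoreError):
    """Synthetic canvas too small to place the requested leaves."""
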