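"""Exception hierarchy for basalq.

All domain errors derive from :class:`BasalqError` so callers (and the CLI)
can distinguish validation problems from I/O or programming errors.
"""


class BasalqError(Exception):
    """Base class for all basalq domain errors."""


class InvalidObservationError(BasalqError, ValueError):
    """A raw clinical measurement is non-numeric, non-positive or otherwise unusable."""


class OutOfRangeError(BasalqError, ValueError):
    """A measurement falls outside the supported range under the strict policy."""


class InvalidStateError(BasalqError, ValueError):
    """A discretized state component or flat state index is out of range."""


class InvalidActionError(BasalqError, ValueError):
    """An action index is outside {1, ..., 6}."""


class OutOfSupportError(BasalqError, ValueError):
    """A dose lies outside the supported [6, 100] unit range."""


class NoDataError(BasalqError, ValueError):
    """An operation that requires data received an empty input."""
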