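"""Exception hierarchy for poifinder.

All exceptions derive from :class:`PoIFinderError` so callers (and the CLI)
can distinguish library failures from programming errors.
"""


class PoIFinderError(Exception):
    """Base class for all poifinder errors."""


class InputFormatError(PoIFinderError):
    """A CSV file or record does not match the expected layout."""


class EmptyInputError(PoIFinderError):
    """No usable data after parsing."""


class DegenerateFeatureError(PoIFinderError):
    """A feature is constant where variation is required (e.g. z-scoring)."""


class CompositeSpecError(PoIFinderError):
    """A composite specification references missing features or is empty."""


class InsufficientDataError(PoIFinderError):
    """Not enough samples remain after burn-in exclusion."""


class NotReadyError(PoIFinderError):
    """The sequential model was asked to predict before seeing enough history."""


class ModelConfigError(PoIFinderError):
    """Invalid simulation or run configuration (e.g. overlapping episodes)."""
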