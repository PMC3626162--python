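"""Exception hierarchy shared across the package.

All errors raised by scattar derive from :class:`ScattarError` so callers
(notably the CLI) can distinguish domain failures from programming errors.
"""


class ScattarError(Exception):
    """Base class for all scattar-specific errors."""


class EvidenceFormatError(ScattarError):
    """A file could not be parsed in the expected dialect.

    The message names the offending line, record or column.
    """


class VocabularyError(EvidenceFormatError):
    """An enum label outside the closed controlled vocabulary was found."""


class IntegrityError(ScattarError):
    """A database-level invariant is violated (e.g. duplicate study ids)."""


class NotFoundError(ScattarError):
    """A requested study id or country code is absent."""


class DistanceUndefinedError(ScattarError):
    """Two profiles share no present indicator dimension."""


class UnresolvableDistanceError(ScattarError):
    """An evaluation study has no country resolvable in the indicator table."""


class LayoutError(ScattarError):
    """A layout could not be computed; the message lists offending studies."""
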