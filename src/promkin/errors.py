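"""Exception hierarchy.

Every error the pipeline raises deliberately derives from :class:`PromkinError`
so callers can distinguish our diagnostics from bugs.
"""


class PromkinError(Exception):
    """Base class for all promkin errors."""


class FormatError(PromkinError):
    """A file did not conform to its expected on-disk format."""


class MissingTierError(FormatError):
    """The requested TextGrid tier does not exist."""


class InsufficientDataError(PromkinError):
    """Too little data to perform the operation (e.g. <2 rows, short track)."""


class AlignmentError(PromkinError):
    """An interval or window does not overlap the track it is applied to."""


class ParameterError(PromkinError):
    """A parameter value is outside its valid range."""


class DataError(PromkinError):
    """Input records are inconsistent or incomplete (e.g. missing annotation)."""
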