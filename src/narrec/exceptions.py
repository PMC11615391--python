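"""Exception hierarchy for narrec.

All narrec-raised errors derive from :class:`NarrecError` so callers can
catch the package's failures with a single except clause; parameter misuse
additionally derives from :class:`ValueError`.
"""


class NarrecError(Exception):
    """Base class for all narrec errors."""


class ParameterError(NarrecError, ValueError):
    """Invalid argument value (bad ranges, inconsistent sizes)."""


class DataError(NarrecError):
    """Input data violates a contract (e.g. event index out of range)."""


class EmptyTranscriptError(DataError):
    """A transcript file contained no words (e.g. a lost recording)."""


class FormatError(DataError):
    """A file could not be parsed in its declared format."""


class StructureError(DataError):
    """A dataset directory is missing required sub-directories."""


class AlignmentError(DataError):
    """Word timings are missing or do not cover the requested span."""


class DegenerateInputError(DataError):
    """Input too small for the statistical procedure (e.g. a single bin)."""
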