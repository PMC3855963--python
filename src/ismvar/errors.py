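"""Exception hierarchy shared across the package.

All errors raised by ismvar derive from :class:`IsmvarError` so callers can
catch package failures with a single except clause while still
distinguishing user mistakes (bad arguments, malformed variant strings)
from data problems (wild-type mismatches, unreadable tables).
"""


class IsmvarError(Exception):
    """Base class for all ismvar errors."""


class InvalidInputError(IsmvarError, ValueError):
    """An argument violates a precondition (empty sequence, bad alpha...)."""


class EncodingError(IsmvarError, ValueError):
    """A sequence contains a residue outside the 20-letter alphabet."""


class VariantParseError(IsmvarError, ValueError):
    """A substitution string does not match the ``X123Y`` / ``p.X123Y`` form."""


class VariantApplicationError(IsmvarError, ValueError):
    """A substitution cannot be applied to the given sequence."""


class AnnotationError(IsmvarError, ValueError):
    """A domain annotation does not match the variant's gene."""


class IngestionError(IsmvarError, ValueError):
    """A delimited input table is malformed or contains unknown tokens."""


class DimensionError(IsmvarError, ValueError):
    """Spectra or score matrices have incompatible shapes."""


class GenerationError(IsmvarError, RuntimeError):
    """The synthetic-data search could not satisfy its contract."""
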