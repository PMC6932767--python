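"""Exception hierarchy for configuration, gene-model and alignment errors."""


class EditProfileError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EditProfileError, ValueError):
    """Malformed run configuration or gene table (missing column, bad value)."""


class GeneModelError(ConfigurationError):
    """A gene region violates its invariants (CDS start/stop/frame, window bounds)."""


class RegionBoundsError(EditProfileError, ValueError):
    """A coordinate falls outside the supplied reference sequence."""


class ReferenceLookupError(EditProfileError, KeyError):
    """A named sequence or chromosome is absent from the reference/header."""


class FormatError(EditProfileError, ValueError):
    """A sequence file contains characters outside the DNA alphabet."""


class NamingError(EditProfileError, ValueError):
    """A variant cannot be expressed in region-relative allele nomenclature."""


class ChimeraError(EditProfileError):
    """A split-read group cannot be deconvoluted into a single junction event."""


class OverlapError(EditProfileError, ValueError):
    """Variants overlap on the reference and cannot be applied together."""


class EmptyInputError(EditProfileError, ValueError):
    """An operation that requires reads received none."""
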