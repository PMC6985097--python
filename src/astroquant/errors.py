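"""Exception hierarchy for astroquant.

Every error raised on a violated contract derives from :class:`AstroquantError`
so batch drivers can catch analysis failures without masking programming bugs.
"""


class AstroquantError(Exception):
    """Base class for all astroquant analysis errors."""


class InvalidSpecError(AstroquantError, ValueError):
    """A simulation spec violates its invariants (bad fractions, dimensions, durations)."""


class InvalidParameterError(AstroquantError, ValueError):
    """An analysis parameter is out of range (e.g. filter cutoff at or above Nyquist)."""


class DegenerateImageError(AstroquantError):
    """The image admits no separating threshold (constant intensities)."""


class UndefinedCorrelationError(AstroquantError):
    """Pearson correlation undefined: one input constant after masking."""


class UndefinedPercentageError(AstroquantError):
    """Percentage with a zero denominator (no nuclei counted)."""


class NormalizationError(AstroquantError):
    """F/F0 normalization impossible: baseline mean non-positive or too few samples."""


class UndefinedFeatureError(AstroquantError):
    """A kinetic feature was requested for a trace on which it is undefined."""
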