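"""Exception hierarchy for the dyadcoh pipeline."""


class DyadcohError(Exception):
    """Base class for all dyadcoh errors."""


class InvalidConfigError(DyadcohError):
    """A configuration value violates its contract (e.g. non-positive duration)."""


class CorruptDataError(DyadcohError):
    """Input data violate a physical invariant (e.g. non-positive intensity)."""


class FormatError(DyadcohError):
    """An on-disk file does not follow the expected layout."""


class AlignmentError(DyadcohError):
    """Two recordings cannot be brought onto a common timeline."""


class InsufficientDataError(DyadcohError):
    """A recording or track is too short for the requested operation."""


class NumericalConfigError(DyadcohError):
    """A numerical configuration is degenerate (e.g. singular extinction matrix)."""


class ModelSpecError(DyadcohError):
    """A statistical model cannot be fit as specified (e.g. rank deficiency)."""


class DegenerateTestError(DyadcohError):
    """A hypothesis test is undefined on the given data (e.g. zero-variance differences)."""


class InvalidInputError(DyadcohError):
    """A value is outside its documented domain (e.g. p-value outside [0, 1])."""
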