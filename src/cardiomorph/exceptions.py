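"""Exception hierarchy shared across the package."""


class CardiomorphError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CardiomorphError, ValueError):
    """A phantom or model specification violates its invariants."""


class DegenerateProfileError(CardiomorphError, ValueError):
    """A profile carries no usable intensity (all zero / empty)."""


class AlignmentError(CardiomorphError, ValueError):
    """Profiles cannot be placed on a common grid (empty overlap)."""


class UndefinedRegionError(CardiomorphError, ValueError):
    """A morphometric quantity was requested on an empty region."""


class LabelingError(CardiomorphError, ValueError):
    """A label stack is missing a class required by an operation."""


class PlacementError(CardiomorphError, RuntimeError):
    """Non-overlapping object placement failed after bounded retries."""


class SingularDesignError(CardiomorphError, ValueError):
    """Design matrix is rank deficient on the observed groups."""


class FormatError(CardiomorphError, ValueError):
    """A file on disk does not match its declared metadata."""


class ConfigError(CardiomorphError, ValueError):
    """A run configuration is malformed or contains unknown keys."""
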