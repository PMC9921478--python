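"""Exception hierarchy shared by all pipeline stages."""


class GaitStabError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GaitStabError, ValueError):
    """A trajectory/stride-table file is missing a required column."""


class FormatError(GaitStabError, ValueError):
    """A file parsed but violates the format contract (grid, finiteness)."""


class ParameterError(GaitStabError, ValueError):
    """An analysis parameter is outside its admissible range."""


class NoGaitError(GaitStabError, RuntimeError):
    """No alternating gait pattern could be detected in the trajectory."""


class NoStraightStridesError(GaitStabError, RuntimeError):
    """Turn exclusion flagged every stride of a trial."""


class UnsynchronizedError(GaitStabError, RuntimeError):
    """No heel strikes of the two systems matched within tolerance."""


class InsufficientDataError(GaitStabError, ValueError):
    """Fewer observations than a statistic requires."""


class InsufficientStridesError(InsufficientDataError):
    """Fewer complete strides than the analysis window requires."""


class DegenerateStrideError(GaitStabError, ValueError):
    """A stride has no usable CoM displacement to define a walking frame."""


class UndefinedICCError(GaitStabError, ValueError):
    """Intraclass correlation undefined (zero total variance)."""
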