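"""Exception types shared across the package."""


class AfmRigidError(Exception):
    """Base class for all afmrigid errors."""


class FormatError(AfmRigidError, ValueError):
    """A file could not be parsed in the expected format."""


class EmptyModelError(AfmRigidError, ValueError):
    """An atomic model contains no atoms."""


class DegenerateGeometryError(AfmRigidError, ValueError):
    """A point set is too degenerate (collinear/coincident) for the operation."""


class ShapeMismatchError(AfmRigidError, ValueError):
    """Atom counts or array shapes of two operands do not match."""


class EmptySimImageError(AfmRigidError, ValueError):
    """The pseudo-AFM image has no non-zero pixel, so no trim window exists."""


class UndefinedScoreError(AfmRigidError, ValueError):
    """A similarity score is undefined (zero norm or zero variance window).

    The exhaustive search treats this condition as a worst-possible cost.
    """


class SearchError(AfmRigidError, ValueError):
    """The search grids are empty or otherwise unusable."""
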