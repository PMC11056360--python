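"""Exception hierarchy shared across the package."""


class BrimplanError(Exception):
    """Base class for all package errors."""


class GeometryError(BrimplanError, ValueError):
    """Invalid geometric input or operation."""


class DegenerateInputError(GeometryError):
    """Input has no well-defined answer (too few points, collinear, zero-length...)."""


class NoIntersectionError(GeometryError):
    """A requested intersection does not exist within tolerance."""


class ConvergenceError(GeometryError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ConstructionError(BrimplanError, ValueError):
    """A synthetic-model construction step is geometrically infeasible."""


class LandmarkError(BrimplanError, RuntimeError):
    """A brim landmark could not be located on the model."""


class ModelFileError(BrimplanError, ValueError):
    """A model file is malformed; message names the offending field."""


class PlanError(BrimplanError, ValueError):
    """A screw plan request is invalid (overhang, bad reference hole...)."""
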