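"""Exception hierarchy shared across the package."""


class BrainSexMapError(Exception):
    """Base class for package errors."""


class DegenerateInputError(BrainSexMapError):
    """Input is structurally valid but statistically degenerate (empty mask,
    zero variance, too few samples)."""


class PlacementError(BrainSexMapError):
    """Atlas regions could not be placed disjointly inside the brain envelope."""


class SizingError(BrainSexMapError):
    """Requested phantom brain does not fit inside the voxel grid."""


class ShapeError(BrainSexMapError):
    """Grids that must share a shape/spacing do not."""


class ConfigurationError(BrainSexMapError):
    """Invalid run/training configuration; carries an aggregated error list."""

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class RegistrationConvergenceError(BrainSexMapError):
    """Optimiser hit its iteration cap; ``transform`` holds the best estimate."""

    def __init__(self, message, transform):
        super().__init__(message)
        self.transform = transform


class NumericError(BrainSexMapError):
    """Non-finite values where finite ones are required."""
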