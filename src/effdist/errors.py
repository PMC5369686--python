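"""Exception hierarchy for effdist."""


class EffdistError(Exception):
    """Base class for all effdist errors."""


class CapacityError(EffdistError):
    """A requested problem size exceeds what the chosen algorithm supports."""


class ConstantFieldError(EffdistError):
    """An operation is undefined on a constant (zero-variance) field."""


class RasterFormatError(EffdistError):
    """A raster file or array violates the cost-raster contract."""


class NodePlacementError(EffdistError):
    """Focal nodes cannot be placed or remapped as requested."""


class NodeCollisionError(NodePlacementError):
    """Two focal nodes map to the same cell after spatial aggregation."""


class SolverError(EffdistError):
    """The linear solver failed to reach the requested residual."""

    def __init__(self, message: str, achieved_residual: float | None = None):
        super().__init__(message)
        self.achieved_residual = achieved_residual
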