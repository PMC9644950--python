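"""Exception types shared across the pipeline."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested operation (constant image,
    empty mask, empty segment list, ...)."""


class VoxelBudgetError(ValueError):
    """A requested render would exceed the configured voxel budget."""


class FitFailureError(RuntimeError):
    """A model fit failed to converge or the geometry is unfittable."""


class UndefinedGeometryError(ValueError):
    """Geometric quantity undefined (e.g. radial angle on the bone axis)."""


class OutOfRangeError(ValueError):
    """Value outside the supported interpolation/argument range."""


class PipelineStageError(RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
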