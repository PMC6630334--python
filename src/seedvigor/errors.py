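"""Exception types shared across the pipeline stages."""


class SeedVigorError(Exception):
    """Base class for all package-specific errors."""


class DegenerateReferenceError(SeedVigorError):
    """White and dark reference coincide at some band; calibration undefined."""


class CorruptFileError(SeedVigorError):
    """ENVI header and binary payload are inconsistent."""


class FormatError(SeedVigorError):
    """A required field is missing or malformed in an input file."""


class EmptyWindowError(SeedVigorError):
    """A spectral trim window retains no bands."""


class PlacementError(SeedVigorError):
    """Seed placement by rejection sampling failed within the attempt budget."""


class RankDeficiencyError(SeedVigorError):
    """Projection chain exhausted the column space before reaching the requested size."""

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


class DegenerateFitError(SeedVigorError):
    """Scatter-correction regression produced a (near-)zero multiplicative term."""


class InternalInconsistencyError(SeedVigorError):
    """An invariant that the pipeline itself must maintain was violated."""
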