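"""Exception hierarchy for the facial-color screening pipeline.

Every stage raises a subclass of :class:`NBDSError` so the pipeline driver
can isolate per-sample failures while letting programming errors propagate.
"""


class NBDSError(Exception):
    """Base class for all pipeline errors."""


class InputValidationError(NBDSError, ValueError):
    """An argument violates a documented precondition."""


class FittingError(NBDSError):
    """A regression design matrix is rank-deficient beyond tolerance."""


class DetectionError(NBDSError):
    """Pupil localization did not produce exactly two plausible candidates."""

    def __init__(self, n_candidates: int, message: str | None = None):
        self.n_candidates = n_candidates
        super().__init__(
            message
            or f"expected exactly 2 plausible pupil candidates, found {n_candidates}"
        )


class BlockBoundsError(NBDSError):
    """A requested key-block window falls outside the image raster."""


class GamutError(NBDSError, ValueError):
    """A color-gamut table is degenerate or malformed."""


class NumericalError(NBDSError):
    """A solver failed (singular system, non-convergence)."""


class ProfileError(NBDSError, ValueError):
    """A synthetic class profile leaves the probability simplex."""
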