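"""Exception hierarchy for rategls.

All errors raised by the package derive from :class:`RateGLSError` so callers
can catch everything from this package with a single except clause.
"""


class RateGLSError(Exception):
    """Base class for all rategls errors."""


class NewickParseError(RateGLSError):
    """The Newick string/file could not be parsed."""


class MissingBranchLengthError(RateGLSError):
    """An edge of the tree has no branch length."""


class DuplicateTipLabelError(RateGLSError):
    """Two or more tips share the same label."""


class NonUltrametricError(RateGLSError):
    """Root-to-tip distances differ by more than the tolerance."""


class SingularMatrixError(RateGLSError):
    """A required matrix is singular or not positive definite (after jitter).

    Trees with zero-length terminal branches or duplicated topological
    positions produce singular shared-branch matrices; a tiny diagonal jitter
    is attempted once before this is raised.
    """


class LabelMismatchError(RateGLSError):
    """Tip labels of the tree and the trait table do not match one-to-one."""


class NegativeRateError(RateGLSError):
    """A model implies a negative evolutionary rate variance a + b*x < 0."""


class NonPositivePredictorError(RateGLSError):
    """A geometric-Brownian-motion predictor must be strictly positive."""


class SmallSigma2Error(RateGLSError):
    """Predictor diffusion variance too small for the geometric model."""


class ConvergenceError(RateGLSError):
    """An iterative procedure failed to converge."""


class ValidationError(RateGLSError):
    """Generic input-validation failure (shapes, parameter ranges, files)."""
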