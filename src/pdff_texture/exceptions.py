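"""Exception hierarchy.

All exceptions derive from :class:`PdffTextureError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
input-format problems from domain violations and degenerate data.
"""


class PdffTextureError(Exception):
    """Base class for all errors raised by this package."""


class VolumeFormatError(PdffTextureError):
    """A volume file is missing, not 3D, or carries an invalid header."""


class GridAlignmentError(PdffTextureError):
    """Two grids that must share shape and spacing do not."""


class DomainError(PdffTextureError, ValueError):
    """An argument is outside its mathematical domain (e.g. negative signal)."""


class EmptyRoiError(PdffTextureError):
    """A mask contains no foreground voxel where one is required."""


class DegenerateDataError(PdffTextureError):
    """Data admit no answer (zero variance sample, all directions skipped)."""


class SchemaError(PdffTextureError):
    """A cohort table or record set violates the expected schema."""


class ContractViolation(PdffTextureError):
    """An internal invariant (e.g. normalized probabilities) was violated."""


class PhantomConfigError(PdffTextureError):
    """A synthetic-phantom configuration is geometrically impossible."""


class ToleranceError(PdffTextureError):
    """An iterative adjustment failed to converge to its tolerance."""
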