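"""Exception hierarchy.

Everything raised on purpose by phantomforge derives from
:class:`PhantomForgeError`; parameter/contract violations additionally
derive from :class:`ValueError` so that generic callers behave sensibly.
"""


class PhantomForgeError(Exception):
    """Base class for all phantomforge errors."""


class ValidationError(PhantomForgeError, ValueError):
    """Input data violates a declared invariant (e.g. unknown organ label)."""


class ShapeMismatchError(PhantomForgeError, ValueError):
    """Raw volume size inconsistent with the declared shape/dtype."""


class FeasibilityError(PhantomForgeError):
    """A requested plan or geometry cannot be realised."""


class EmptyRegionError(PhantomForgeError, ValueError):
    """An operation was asked to work on an empty label region."""


class ParameterError(PhantomForgeError, ValueError):
    """A scalar parameter is outside its allowed range."""


class WatertightError(PhantomForgeError):
    """Mesh is open / non-manifold where a closed surface is required."""


class InvertedWindingError(WatertightError):
    """Mesh is closed but wound inside-out (negative signed volume)."""


class ExtractionError(PhantomForgeError):
    """Surface extraction produced a non-manifold result."""


class ExtrusionError(PhantomForgeError):
    """Shell extrusion could not produce a valid offset surface."""


class ResolutionError(PhantomForgeError):
    """Overlap resolution exhausted its travel budget."""


class AssemblyError(PhantomForgeError):
    """Two parts of an assembled scene overlap."""


class StlParseError(PhantomForgeError):
    """Malformed STL payload.

    Attributes
    ----------
    byte_offset : int or None
        Offset in the file at which the inconsistency was detected.
    """

    def __init__(self, message, byte_offset=None):
        super().__init__(message)
        self.byte_offset = byte_offset


class MeasurementError(PhantomForgeError, ValueError):
    """Physically impossible measurement (e.g. full weight below empty)."""


class IncompleteRecordError(PhantomForgeError):
    """A dispense record lacks the fields needed for the requested quantity."""


class AlignmentError(PhantomForgeError):
    """Two tables do not share the same (compartment, scan) keys."""


class MappingError(PhantomForgeError):
    """A labelled compartment has no concentration assigned."""


class DivergenceError(PhantomForgeError):
    """A time-integrated activity does not converge (non-decaying tail)."""


class ConciseParseError(PhantomForgeError, ValueError):
    """String does not match the value(uncertainty) notation."""
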