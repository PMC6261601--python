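"""Exception hierarchy.

Every error the toolkit raises deliberately derives from :class:`LptcError`,
so callers can catch one base class at pipeline level.
"""


class LptcError(Exception):
    """Base class for all lptc errors."""


class NmlParseError(LptcError):
    """Malformed NML XML; message names the offending line when known."""


class IntegrityError(LptcError):
    """Skeleton references an entity that does not exist (e.g. edge to a missing node)."""


class StructureError(LptcError):
    """A tree does not have the structure an operation requires (cycle, disconnection)."""


class UnresolvedMatchError(LptcError):
    """Ambiguous endpoint correspondence when merging dataset parts."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class ValidationError(LptcError):
    """Input values violate a precondition (e.g. zero radii where radii are required)."""


class DegenerateOutlineError(LptcError):
    """Plate outline cannot be split into two surfaces."""


class ModelError(LptcError):
    """Layer model is geometrically inconsistent (surfaces cross, zero thickness)."""


class EmptyHistogramError(LptcError):
    """No in-footprint nodes to build a layer histogram from."""


class ResourceError(LptcError):
    """Requested computation exceeds a configured resource budget."""


class UnknownLabelError(LptcError):
    """Requested label is not present in the label volume."""


class GeometryError(LptcError):
    """Image pair has no usable overlap region."""


class ConnectivityError(LptcError):
    """Tile measurement graph is disconnected."""

    def __init__(self, message, components=()):
        super().__init__(message)
        self.components = list(components)


class SpecError(LptcError):
    """A synthetic-data specification is infeasible."""
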