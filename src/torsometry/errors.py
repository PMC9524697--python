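"""Exception hierarchy.

All package errors derive from :class:`TorsometryError` so callers can catch
one base class; the CLI maps ``ValidationError`` to exit code 1 and everything
else to exit code 2.
"""


class TorsometryError(Exception):
    """Base class for all torsometry errors."""


class FormatError(TorsometryError):
    """An input file could not be parsed (unreadable mesh, malformed CSV/JSON)."""


class ValidationError(TorsometryError):
    """An input value violates a documented invariant or precondition."""


class GeometryError(TorsometryError):
    """A geometric precondition failed (e.g. polar origin outside the contour)."""


class EmptySliceError(TorsometryError):
    """A slicing plane does not intersect the mesh."""


class TopologyError(TorsometryError):
    """A mesh section produced an open or self-intersecting polyline."""
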