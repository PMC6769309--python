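"""Exception hierarchy for topohet.

All errors derive from :class:`TopohetError` so callers can catch the
package's failures with one clause; each subclass also derives from the
closest builtin (``ValueError``) for duck-typed handling.
"""


class TopohetError(Exception):
    """Base class for all topohet errors."""


class DataFormatError(TopohetError, ValueError):
    """A file or record does not parse (bad cell, short GMT line, ...)."""


class IdentifierError(TopohetError, ValueError):
    """Duplicate or unknown gene/sample/set identifiers."""


class GroupContractError(TopohetError, ValueError):
    """The two-group, equal-size sample contract is violated.

    Equal group sizes are structural to the method: the number of
    connected components of a point cloud, and hence every dimension-0
    summary, depends on the number of points, so unequal groups would
    make the group-difference statistics incomparable.
    """


class ConstantVectorError(TopohetError, ValueError):
    """A gene or sample vector has zero variance; its Pearson
    correlation, and hence its dissimilarity to anything, is undefined."""


class CapacityError(TopohetError, ValueError):
    """A full Vietoris-Rips enumeration would exceed the simplex ceiling;
    use the lazy-witness construction instead."""


class ValidationError(TopohetError, ValueError):
    """Invalid configuration or argument value."""


class AlignmentError(TopohetError, ValueError):
    """Vector/matrix not aligned to the model's gene universe."""
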