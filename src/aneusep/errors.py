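"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad meshes, schema violations,
degenerate picks); ``ComputationError`` covers failures of an otherwise
well-posed computation (no path, non-separating curve, failed projection).
The CLI maps the two branches to exit codes 2 and 3.
"""


class AneusepError(Exception):
    """Base class for all package errors."""


class ValidationError(AneusepError):
    """Input does not satisfy a documented precondition or invariant."""


class MeshValidationError(ValidationError):
    """A triangle mesh violates a structural invariant; names the element."""


class SchemaError(ValidationError):
    """A JSON document is missing fields or holds out-of-range values."""


class DegeneratePickError(ValidationError):
    """Fewer than three distinct snapped vertices."""


class DegeneratePlaneError(ValidationError):
    """Plane fit attempted on (near-)collinear points."""


class ComputationError(AneusepError):
    """A well-formed request that cannot be satisfied on this input."""


class NoPathError(ComputationError):
    """Graph vertices lie in different connected components."""


class NonSimpleCurveError(ComputationError):
    """A neck curve would traverse some mesh edge twice."""


class NonSeparatingCurveError(ComputationError):
    """The neck curve does not split the surface into >= 2 face components."""


class ProjectionError(ComputationError):
    """Curve projection onto its fitted plane self-intersects."""
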