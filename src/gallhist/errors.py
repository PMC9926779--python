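"""Exception hierarchy.

Every error carries a short machine-readable ``code`` so callers (and the
CLI) can branch on the failure kind without string matching.
"""


class GallhistError(Exception):
    """Base class for all errors raised by this package."""

    code = "ERROR"

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class NotRootedDAGError(GallhistError):
    code = "NOT_ROOTED_DAG"


class DegreeViolationError(GallhistError):
    code = "DEGREE_VIOLATION"


class NestedCyclesError(GallhistError):
    code = "NESTED_CYCLES"


class SharedCycleVerticesError(GallhistError):
    code = "SHARED_CYCLE_VERTICES"


class TemporallyInconsistentError(GallhistError):
    code = "TEMPORALLY_INCONSISTENT"


class ParseError(GallhistError):
    code = "PARSE_ERROR"


class UnmatchedHybridTagError(ParseError):
    code = "UNMATCHED_HYBRID_TAG"


class NotAGalledTreeError(ParseError):
    """The text parsed to a network that fails galled-tree validation."""

    code = "NOT_A_GALLED_TREE"

    def __init__(self, message: str = "", report=None):
        super().__init__(message)
        self.report = report


class HasGallsError(GallhistError):
    code = "HAS_GALLS"


class SizeLimitError(GallhistError):
    code = "SIZE_LIMIT"


class InfeasibleError(GallhistError):
    code = "INFEASIBLE"


class DomainError(GallhistError):
    code = "DOMAIN"
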