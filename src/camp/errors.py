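"""Exception hierarchy shared across the package."""


class CampError(Exception):
    """Base class for all package-specific errors."""


class OboParseError(CampError):
    """Raised when an OBO flat file cannot be parsed."""


class OntologyStructureError(CampError):
    """Raised when an ontology violates a structural invariant (e.g. a cyclic is_a graph)."""


class UnknownConceptError(CampError, KeyError):
    """Raised when a CURIE resolves to no concept (neither primary id nor alt_id)."""

    def __init__(self, curie: str, message: str | None = None):
        super().__init__(message or f"unknown concept: {curie!r}")
        self.curie = curie


class AxiomParseError(CampError):
    """Raised on a malformed row in a cross-ontology axiom table."""


class AnnotationParseError(CampError):
    """Raised when an annotation/association file is missing required columns or is malformed."""


class DirectionMismatchError(CampError):
    """Raised when a cross-mapping's (source, target) direction does not match its use."""


class MixedOntologyError(CampError):
    """Raised when profiles from different ontologies are combined without translation."""


class DegenerateLabelsError(CampError):
    """Raised when an evaluation requires both classes but only one is present."""
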