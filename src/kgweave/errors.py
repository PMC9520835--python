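"""Exception hierarchy for kgweave.

Every error raised by the toolkit derives from :class:`KGWeaveError` so that
callers (and the CLI) can catch toolkit failures without masking genuine bugs.
"""


class KGWeaveError(Exception):
    """Base class for all kgweave errors."""


class MalformedCurieError(KGWeaveError):
    """An identifier string is not a valid PREFIX:LOCAL_ID CURIE."""

    def __init__(self, text: str, reason: str = ""):
        self.text = text
        msg = f"malformed CURIE: {text!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class SchemaError(KGWeaveError):
    """A serialized document violates the published schema.

    ``path`` is a JSON-path-like locator of the offending element.
    """

    def __init__(self, message: str, path: str = "$"):
        self.path = path
        super().__init__(f"{message} (at {path})")


class SerializationError(KGWeaveError):
    """A value cannot be represented in the target serialization."""


class ModelError(KGWeaveError):
    """The semantic-model file is structurally invalid."""


class CycleError(ModelError):
    """A hierarchy in the semantic model contains a cycle."""

    def __init__(self, kind: str, cycle: list):
        self.cycle = cycle
        super().__init__(f"cycle in {kind} hierarchy: {' -> '.join(cycle)}")


class ConsistencyError(ModelError):
    """Cross-field consistency violated (e.g. an inverse pair without
    exactly one canonical member)."""


class ModelLookupError(KGWeaveError):
    """A category or predicate is not present in the semantic model."""


class IngestError(KGWeaveError):
    """A source file could not be ingested."""


class UnmappedPrefixError(IngestError):
    """An ontology IRI has no configured CURIE prefix."""

    def __init__(self, iri: str):
        self.iri = iri
        super().__init__(f"no CURIE prefix configured for IRI: {iri}")


class ConfigError(KGWeaveError):
    """The build configuration is invalid (duplicate ranks/names, bad paths)."""


class ParameterError(KGWeaveError):
    """A generator or estimator parameter is out of range."""


class EstimationError(KGWeaveError):
    """A statistical fit cannot be computed from the given data."""


class IndexError_(KGWeaveError):
    """The graph cannot be indexed (e.g. duplicate node identifiers)."""


class QueryValidationError(KGWeaveError):
    """A query graph violates the one-hop query contract."""


class PlanError(KGWeaveError):
    """The build plan is invalid (cyclic or missing dependencies)."""


class StageFailure(KGWeaveError):
    """A build stage failed during execution."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
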