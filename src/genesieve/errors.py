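"""Exception hierarchy for the prioritization pipeline.

Every error that a pipeline stage can raise deliberately derives from
:class:`GenesieveError`, so callers can distinguish framework failures
from programming errors.
"""


class GenesieveError(Exception):
    """Base class for all framework errors."""


class ConfigError(GenesieveError):
    """Invalid configuration value or unknown rule/stage name."""


class UnboundPlaceholderError(GenesieveError):
    """A prompt template was rendered without binding a required placeholder."""

    def __init__(self, placeholder: str):
        self.placeholder = placeholder
        super().__init__(f"unbound placeholder: {placeholder!r}")


class MalformedResponseError(GenesieveError):
    """A backend response lacked the structured fields required by its stage."""


class ScoreRangeError(GenesieveError):
    """A parsed criterion score fell outside the 0-10 rubric range."""


class ScriptLookupError(GenesieveError):
    """A scripted backend had no entry for the requested key."""


class DuplicateDocumentError(GenesieveError):
    """Two corpus records share the same document id."""


class CorpusParseError(GenesieveError):
    """A corpus JSONL line could not be parsed."""


class EmbedderMismatchError(GenesieveError):
    """An index was queried with an embedder other than the one it was built with."""


class RetrievalError(GenesieveError):
    """Dense retrieval was attempted against an empty index."""


class AttributionError(GenesieveError):
    """A judgment cited a source id that is not in its context bundle."""


class MalformedVerdictError(GenesieveError):
    """A faithfulness judge response was not parseable as Pass/Fail."""


class GateViolationError(GenesieveError):
    """A Fail-verdict instance reached a stage reserved for passing instances."""


class IsolationError(GenesieveError):
    """A context bundle was used for a (gene, criterion) query it does not belong to."""


class ProvenanceError(GenesieveError):
    """A downstream priority set contains a gene absent from its upstream set."""


class NoEnrichedClusterError(GenesieveError):
    """No cluster reached the enrichment significance threshold."""
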