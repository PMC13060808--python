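"""Exception hierarchy shared across the rescue-rank pipeline.

Every error that the batch loops are expected to survive (per-article,
per-hit) derives from :class:`RescueRankError` and carries enough context
(article id, taxon id, step name) to be logged and reported to the user
without aborting the run.
"""

from __future__ import annotations


class RescueRankError(Exception):
    """Base class for all rescue-rank errors."""


class ConfigurationError(RescueRankError):
    """Invalid configuration: bad weights, unparseable column map, missing paths."""


class TaxonomyStructureError(RescueRankError):
    """Structurally invalid taxonomy input: cycles, dangling parents, multiple roots."""


class UnresolvableTaxonError(RescueRankError):
    """A taxon and its entire supplied lineage are absent from the tree."""

    def __init__(self, taxon_id: int | str, message: str | None = None) -> None:
        self.taxon_id = taxon_id
        super().__init__(message or f"taxon {taxon_id!r} not resolvable in tree")


class DomainError(RescueRankError):
    """A numeric argument is outside its documented domain."""


class JatsParseError(RescueRankError):
    """Irrecoverably malformed article XML."""

    def __init__(self, article_id: str, message: str | None = None) -> None:
        self.article_id = article_id
        super().__init__(message or f"article {article_id}: irrecoverably malformed XML")


class MissingSectionError(RescueRankError):
    """No section title matched the methods keyword."""

    def __init__(self, article_id: str, message: str | None = None) -> None:
        self.article_id = article_id
        super().__init__(message or f"article {article_id}: no methods section found")


class ProtocolValidationError(RescueRankError):
    """A protocol table violates a field invariant (pH range, empty step label)."""


class EmptyProtocolError(RescueRankError):
    """The extractor found no purification-related text in a methods section."""

    def __init__(self, article_id: str = "", message: str | None = None) -> None:
        self.article_id = article_id
        super().__init__(message or f"article {article_id}: no purification text found")


class AgentFailureError(RescueRankError):
    """A backend repeatedly produced output that failed schema validation."""


class InputError(RescueRankError):
    """User input could not be classified or located."""
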