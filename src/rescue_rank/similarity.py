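"""Filtering, scoring and ranking of BLAST hits.

The composite score combines sequence identity with evolutionary
proximity of the subject organism:

    S_seq     = pident / 100
    S_taxa    = 0.5                          if distance = 0
                1 - distance / maxdistance   if distance > 0
    S_overall = w_seq * S_seq + w_taxa * S_taxa      (defaults 0.5 / 0.5)

where ``distance`` is the rank-penalized taxonomy-tree distance between
the query and subject organisms and ``maxdistance`` the penalized tree
diameter.  Paralogs (hits from the query's own organism) have their
taxonomic component halved; organisms resolved by lineage fallback lose
a small decrement per fallback hop.  Hits are pre-filtered on identity,
e-value and query coverage and capped at a best-by-bitscore maximum
before scoring.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, DomainError
from .taxonomy import (
    RankPenaltySchedule,
    TaxonomicDistance,
    TaxonomyTree,
    UnresolvableTaxonError,
    max_distance,
    penalized_distance,
    resolve_with_fallback,
)

logger = logging.getLogger(__name__)

#: Column order of ``blastp -outfmt 6`` plus the two extra columns the
#: pipeline needs (per-subject query coverage and the subject taxon id).
DEFAULT_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qcovs", "staxids",
)

_REQUIRED_COLUMNS = {"qseqid", "sseqid", "pident", "evalue", "bitscore"}


class BlastHit(BaseModel):
    """One filtered-candidate alignment from a BLAST tabular row."""

    query_id: str
    subject_id: str
    pident: float = Field(ge=0, le=100)
    evalue: float = Field(ge=0)
    qcov: float = Field(ge=0, le=100)
    bitscore: float
    subject_taxon: int | str
    subject_organism_equals_query: bool = False


class FilterCriteria(BaseModel):
    """Retrieval thresholds applied before scoring.

    Defaults: identity > 20%, e-value < 1e-3, coverage > 75%, at most 50
    hits kept (best by bitscore).  ``strict`` controls whether the
    threshold comparisons are strict (the default) or inclusive.
    """

    min_pident: float = 20.0
    max_evalue: float = 1e-3
    min_qcov: float = 75.0
    max_hits: int = Field(default=50, gt=0)
    strict: bool = True


class SimilarityWeights(BaseModel):
    """Relative weight of sequence identity vs taxonomic proximity."""

    w_seq: float = Field(default=0.5, ge=0, le=1)
    w_taxa: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _sum_to_one(self) -> "SimilarityWeights":
        if abs(self.w_seq + self.w_taxa - 1.0) > 1e-9:
            raise ConfigurationError(
                f"weights must sum to 1, got {self.w_seq} + {self.w_taxa}"
            )
        return self


class ScoredHit(BaseModel):
    """A hit carrying all score components for auditability."""

    hit: BlastHit
    s_seq: float
    s_taxa_raw: float
    s_taxa: float
    s_overall: float
    is_paralog: bool = False
    fallback_steps: int = 0


def parse_blast_table(
    source: str | Path | TextIO,
    columns: Sequence[str] = DEFAULT_COLUMNS,
    query_length: int | None = None,
) -> list[BlastHit]:
    """Parse outfmt-6-style tab-separated BLAST output.

    ``columns`` maps positions to field names; it must cover at least
    qseqid, sseqid, pident, evalue and bitscore.  Coverage comes from a
    ``qcovs`` column when present, otherwise from ``length / query_length``
    if ``query_length`` is given.  Malformed rows are logged and skipped;
    an empty input yields an empty list.
    """
    missing = _REQUIRED_COLUMNS - set(columns)
    if missing:
        raise ConfigurationError(f"column map lacks required columns: {sorted(missing)}")
    if isinstance(source, Path) or (
        isinstance(source, str) and source.strip() and "\n" not in source and "\t" not in source
    ):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    idx = {name: i for i, name in enumerate(columns)}
    hits: list[BlastHit] = []
    skipped = 0
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if "qcovs" in idx:
                qcov = float(fields[idx["qcovs"]])
            elif query_length:
                qcov = 100.0 * float(fields[idx["length"]]) / query_length
            else:
                qcov = 100.0
            taxon_field = fields[idx["staxids"]] if "staxids" in idx else ""
            taxon_field = taxon_field.split(";")[0]
            subject_taxon: int | str = (
                int(taxon_field) if taxon_field.isdigit() else taxon_field
            )
            hits.append(
                BlastHit(
                    query_id=fields[idx["qseqid"]],
                    subject_id=fields[idx["sseqid"]],
                    pident=float(fields[idx["pident"]]),
                    evalue=float(fields[idx["evalue"]]),
                    qcov=qcov,
                    bitscore=float(fields[idx["bitscore"]]),
                    subject_taxon=subject_taxon,
                )
            )
        except (ValueError, IndexError) as exc:
            skipped += 1
            logger.warning("skipping malformed BLAST row %d: %s", lineno, exc)
    if skipped:
        logger.warning("parsed %d hits, skipped %d malformed rows", len(hits), skipped)
    return hits


def filter_hits(hits: Iterable[BlastHit], criteria: FilterCriteria | None = None) -> list[BlastHit]:
    """Apply the retrieval thresholds and the best-by-bitscore cap.

    With strict (default) comparisons a hit survives iff
    ``pident > min_pident``, ``evalue < max_evalue`` and
    ``qcov > min_qcov``.  If more than ``max_hits`` survive, the best
    ``max_hits`` by bitscore are kept (ties: smaller e-value, then
    lexicographic subject id).
    """
    criteria = criteria or FilterCriteria()
    if criteria.strict:
        kept = [
            h for h in hits
            if h.pident > criteria.min_pident
            and h.evalue < criteria.max_evalue
            and h.qcov > criteria.min_qcov
        ]
    else:
        kept = [
            h for h in hits
            if h.pident >= criteria.min_pident
            and h.evalue <= criteria.max_evalue
            and h.qcov >= criteria.min_qcov
        ]
    if len(kept) > criteria.max_hits:
        kept.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        kept = kept[: criteria.max_hits]
    return kept


def sequence_similarity(pident: float) -> float:
    """Percent identity normalized to [0, 1]."""
    if not 0.0 <= pident <= 100.0:
        raise DomainError(f"pident must be in [0, 100], got {pident}")
    return pident / 100.0


def taxonomic_similarity(
    distance: TaxonomicDistance,
    maxdistance: float,
    schedule: RankPenaltySchedule | None = None,
) -> float:
    """Taxonomic proximity component in [0, 1].

    0.5 at distance zero (the organism itself, before the paralog
    penalty); otherwise ``1 - distance/maxdistance``.  Each lineage
    fallback hop subtracts ``missing_lineage_decrement``; the result is
    clamped to [0, 1].
    """
    if maxdistance <= 0:
        raise DomainError(f"maxdistance must be > 0, got {maxdistance}")
    schedule = schedule or RankPenaltySchedule()
    if distance.raw_distance == 0:
        s = 0.5
    else:
        s = 1.0 - distance.raw_distance / maxdistance
    s -= schedule.missing_lineage_decrement * distance.fallback_steps
    return min(1.0, max(0.0, s))


def paralog_penalty(s_taxa_raw: float, same_organism: bool) -> float:
    """Halve the taxonomic component for hits from the query's own organism."""
    if not 0.0 <= s_taxa_raw <= 1.0:
        raise DomainError(f"s_taxa must be in [0, 1], got {s_taxa_raw}")
    return s_taxa_raw / 2.0 if same_organism else s_taxa_raw


def overall_score(
    s_seq: float, s_taxa: float, weights: SimilarityWeights | None = None
) -> float:
    """Weighted combination of the two components (defaults: equal weights)."""
    weights = weights or SimilarityWeights()
    return weights.w_seq * s_seq + weights.w_taxa * s_taxa


def score_hits(
    hits: Iterable[BlastHit],
    tree: TaxonomyTree,
    query_taxon: int,
    schedule: RankPenaltySchedule | None = None,
    weights: SimilarityWeights | None = None,
    lineages: Mapping[int | str, Sequence[int]] | None = None,
    maxdistance: float | None = None,
) -> list[ScoredHit]:
    """Score each (already filtered) hit against the query organism.

    ``lineages`` maps subject taxon ids absent from the tree to their
    ancestor-id lists (immediate parent first) for fallback resolution.
    Hits whose organism cannot be resolved at all are excluded and
    logged, per the retrieval contract.
    """
    schedule = schedule or RankPenaltySchedule()
    weights = weights or SimilarityWeights()
    lineages = lineages or {}
    if maxdistance is None:
        maxdistance = max_distance(tree, schedule)
    query_node, _ = resolve_with_fallback(
        tree, query_taxon, lineages.get(query_taxon, ())
    )
    scored: list[ScoredHit] = []
    for hit in hits:
        taxon = hit.subject_taxon
        try:
            subject_node, steps = resolve_with_fallback(
                tree, int(taxon), lineages.get(taxon, ())
            )
        except (UnresolvableTaxonError, ValueError, TypeError):
            logger.warning(
                "excluding hit %s: organism %r not resolvable", hit.subject_id, taxon
            )
            continue
        dist = penalized_distance(tree, query_node.taxon_id, subject_node.taxon_id, schedule)
        dist = dist.model_copy(update={"fallback_steps": steps})
        same_org = hit.subject_organism_equals_query or (
            steps == 0 and subject_node.taxon_id == query_node.taxon_id
        )
        s_seq = sequence_similarity(hit.pident)
        s_taxa_raw = 0.5 if dist.raw_distance == 0 else 1.0 - dist.raw_distance / maxdistance
        s_taxa = taxonomic_similarity(dist, maxdistance, schedule)
        s_taxa = paralog_penalty(s_taxa, same_org)
        scored.append(
            ScoredHit(
                hit=hit.model_copy(update={"subject_organism_equals_query": same_org}),
                s_seq=s_seq,
                s_taxa_raw=s_taxa_raw,
                s_taxa=s_taxa,
                s_overall=overall_score(s_seq, s_taxa, weights),
                is_paralog=same_org,
                fallback_steps=steps,
            )
        )
    return scored


def rank_hits(
    scored: Iterable[ScoredHit], min_score: float = 0.0, limit: int | None = None
) -> list[ScoredHit]:
    """Sort by descending composite score, threshold, and truncate.

    Ties break on higher sequence component, then lexicographic subject
    id, so ranking is deterministic.
    """
    kept = [s for s in scored if s.s_overall >= min_score]
    kept.sort(key=lambda s: (-s.s_overall, -s.s_seq, s.hit.subject_id))
    if limit is not None:
        kept = kept[:limit]
    return kept


def write_ranked_hits(
    ranked: Sequence[ScoredHit], out_tsv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> None:
    """Dump ranked hits with all score components (TSV and/or JSON)."""
    if out_tsv is not None:
        lines = ["subject_id\tpident\tevalue\tqcov\ts_seq\ts_taxa_raw\ts_taxa\ts_overall\tis_paralog\tfallback_steps"]
        for s in ranked:
            lines.append(
                f"{s.hit.subject_id}\t{s.hit.pident:g}\t{s.hit.evalue:g}\t{s.hit.qcov:g}"
                f"\t{s.s_seq:.6f}\t{s.s_taxa_raw:.6f}\t{s.s_taxa:.6f}\t{s.s_overall:.6f}"
                f"\t{int(s.is_paralog)}\t{s.fallback_steps}"
            )
        Path(out_tsv).write_text("\n".join(lines) + "\n")
    if out_json is not None:
        Path(out_json).write_text(
            json.dumps([s.model_dump() for s in ranked], indent=2, sort_keys=True) + "\n"
        )
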