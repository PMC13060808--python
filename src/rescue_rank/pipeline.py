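"""End-to-end orchestration of the purification-rescue workflow.

Stages run in order: parse BLAST hits → filter → score and rank against
the taxonomy tree → resolve citations → parse articles → extract
purification text → summarize into six-column tables → (when a failed
protocol is provided) optimize → render the consolidated report.  Every
per-article failure (malformed XML, missing methods section, no
purification text) is logged in the run ledger and skipped; the run
completes with however many articles succeed.

The ledger keeps per-stage conservation counts: at every stage,
``retained + excluded == input``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Literal, Optional

from Bio import SeqIO
from pydantic import BaseModel, Field

from .agents import (
    AgentBackend,
    RulesBackend,
    extract_purification_text,
    summarize_protocol,
    optimize_protocol,
)
from .errors import (
    ConfigurationError,
    EmptyProtocolError,
    InputError,
    JatsParseError,
    MissingSectionError,
)
from .litmine import classify_accessibility, find_methods_section, parse_jats
from .protocol_model import (
    OptimizationReport,
    ProtocolTable,
    Provenance,
    RescueReport,
    render_report,
    validate_table,
    write_protocol_csv,
)
from .similarity import (
    FilterCriteria,
    SimilarityWeights,
    filter_hits,
    parse_blast_table,
    rank_hits,
    score_hits,
)
from .taxonomy import RankPenaltySchedule, load_taxonomy

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Everything one run needs; defaults reproduce the documented
    retrieval thresholds and equal component weights."""

    query: Optional[Path] = None
    hits: Path
    taxonomy: Path
    articles: Optional[Path] = None
    citations: Optional[Path] = None
    failed_protocol: Optional[Path] = None
    annotations: Optional[Path] = None
    out_dir: Optional[Path] = None

    criteria: FilterCriteria = Field(default_factory=FilterCriteria)
    weights: SimilarityWeights = Field(default_factory=SimilarityWeights)
    schedule: RankPenaltySchedule = Field(default_factory=RankPenaltySchedule)
    query_taxon: Optional[int] = None
    min_score: float = 0.0
    limit: int = 50
    article_limit: int = 10
    backend: str = "rules"
    run_optimizer: bool = True


class StageCount(BaseModel):
    input: int
    retained: int
    excluded: int
    reasons: dict[str, int] = {}


class RunLedger(BaseModel):
    """Per-stage conservation counts and per-article outcomes."""

    stages: dict[str, StageCount] = {}
    article_outcomes: dict[str, str] = {}

    def record(self, stage: str, input_n: int, retained: int, reasons: dict[str, int] | None = None) -> None:
        self.stages[stage] = StageCount(
            input=input_n,
            retained=retained,
            excluded=input_n - retained,
            reasons=reasons or {},
        )


_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


def detect_input(value: str, internal_pattern: str = r"[A-Za-z]{2,10}\.\d{5}") -> Literal["fasta", "structure_id", "internal_id"]:
    """Classify a user-supplied target by shape.

    A leading '>' or a pure residue-alphabet string is a FASTA sequence;
    a 4-character alphanumeric token starting with a digit is a
    structure id; the configurable pattern marks internal target ids.
    """
    value = value.strip()
    if not value:
        raise InputError("empty input")
    if value.startswith(">"):
        return "fasta"
    if re.fullmatch(r"[0-9][A-Za-z0-9]{3}", value):
        return "structure_id"
    if re.fullmatch(internal_pattern, value):
        return "internal_id"
    if len(value) >= 10 and all(c.upper() in _RESIDUES for c in value if not c.isspace()):
        return "fasta"
    raise InputError(
        f"could not classify input {value[:40]!r}: expected a FASTA sequence, "
        "a 4-character structure id, or an internal target id"
    )


def _load_failed_protocol(path: Path, backend: AgentBackend) -> ProtocolTable:
    text = path.read_text().strip()
    table = summarize_protocol(text, backend=backend)
    table.provenance = Provenance(failed_baseline=True, article_title="failed baseline")
    return validate_table(table)


def _load_annotations(path: Path | None) -> list[str]:
    if path is None or not Path(path).exists():
        return []
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.replace(": ", ":"))
    return out


def run_pipeline(config: PipelineConfig) -> tuple[RescueReport, RunLedger]:
    """Execute the full rescue workflow; returns (report, ledger).

    Raises :class:`ConfigurationError` before any work if the taxonomy
    or hit files are missing.  Zero hits after filtering still yields a
    report (stating that no candidates passed).
    """
    for required, label in ((config.taxonomy, "taxonomy"), (config.hits, "hits")):
        if required is None or not Path(required).exists():
            raise ConfigurationError(f"{label} file missing: {required}")
    backend: AgentBackend = RulesBackend() if config.backend == "rules" else RulesBackend()
    ledger = RunLedger()

    query_id = "target"
    if config.query is not None and Path(config.query).exists():
        records = list(SeqIO.parse(str(config.query), "fasta"))
        if records:
            query_id = records[0].id

    tree = load_taxonomy(Path(config.taxonomy))
    hits = parse_blast_table(Path(config.hits))
    ledger.record("parse_hits", len(hits), len(hits))

    kept = filter_hits(hits, config.criteria)
    ledger.record("filter", len(hits), len(kept))

    query_taxon = config.query_taxon
    if query_taxon is None:
        # default: the first leaf in the tree, matching the fixture convention
        query_taxon = sorted(tree.leaves())[0]
    scored = score_hits(kept, tree, query_taxon, config.schedule, config.weights)
    ranked = rank_hits(scored, config.min_score, config.limit)
    ledger.record("score_rank", len(kept), len(ranked))

    # citation resolution: map ranked subjects onto article files
    article_jobs: list[tuple[str, Path, dict]] = []  # (subject_id, path, hit info)
    excluded_reasons: dict[str, int] = {}
    if config.articles is not None and Path(config.articles).exists():
        articles_dir = Path(config.articles)
        citations = {}
        if config.citations is not None and Path(config.citations).exists():
            citations = json.loads(Path(config.citations).read_text())
        if citations:
            for s in ranked:
                meta = citations.get(s.hit.subject_id)
                if meta is None:
                    continue
                record = classify_accessibility(
                    structure_id=s.hit.subject_id,
                    has_primary_citation=meta.get("has_primary_citation", False),
                    in_pmc=meta.get("in_pmc", False),
                    open_license=meta.get("open_license", False),
                    article_id=meta.get("article_id"),
                )
                if record.status != "accessible":
                    excluded_reasons[record.status] = excluded_reasons.get(record.status, 0) + 1
                    ledger.article_outcomes[s.hit.subject_id] = record.status
                    continue
                path = articles_dir / f"{record.article_id}.xml"
                if path.exists():
                    article_jobs.append((s.hit.subject_id, path, {
                        "title_hint": "", "organism": str(s.hit.subject_taxon),
                        "score": s.s_overall,
                    }))
        else:
            for i, path in enumerate(sorted(articles_dir.glob("*.xml"))):
                organism = str(ranked[i].hit.subject_taxon) if i < len(ranked) else ""
                score = ranked[i].s_overall if i < len(ranked) else None
                subject = ranked[i].hit.subject_id if i < len(ranked) else path.stem
                article_jobs.append((subject, path, {"organism": organism, "score": score}))
    total_considered = len(article_jobs) + sum(excluded_reasons.values())
    if len(article_jobs) > config.article_limit:
        excluded_reasons["over_article_limit"] = len(article_jobs) - config.article_limit
        article_jobs = article_jobs[: config.article_limit]
    ledger.record("resolve_citations", total_considered, len(article_jobs), excluded_reasons)

    # mine each article, surviving per-article failures
    tables: list[ProtocolTable] = []
    mine_reasons: dict[str, int] = {}
    for subject_id, path, info in article_jobs:
        article_id = path.stem
        try:
            doc = parse_jats(path.read_text(errors="replace"), article_id)
            methods = find_methods_section(doc)
            protocol_text = extract_purification_text(methods, backend=backend)
            table = summarize_protocol(protocol_text, backend=backend)
            table.provenance = Provenance(
                article_title=doc.title,
                url=f"https://www.ncbi.nlm.nih.gov/pmc/articles/{article_id}/",
                organism=info.get("organism", ""),
                similarity_score=info.get("score"),
            )
            tables.append(validate_table(table))
            ledger.article_outcomes[article_id] = "parsed"
        except JatsParseError:
            logger.warning("article %s: malformed XML, skipping", article_id)
            ledger.article_outcomes[article_id] = "malformed_xml"
            mine_reasons["malformed_xml"] = mine_reasons.get("malformed_xml", 0) + 1
        except MissingSectionError:
            ledger.article_outcomes[article_id] = "missing_methods"
            mine_reasons["missing_methods"] = mine_reasons.get("missing_methods", 0) + 1
        except EmptyProtocolError:
            ledger.article_outcomes[article_id] = "no_purification_text"
            mine_reasons["no_purification_text"] = mine_reasons.get("no_purification_text", 0) + 1
    ledger.record("mine_articles", len(article_jobs), len(tables), mine_reasons)

    # optimization (only when a failed protocol is provided)
    optimization: OptimizationReport | None = None
    failed_table: ProtocolTable | None = None
    if (
        config.run_optimizer
        and config.failed_protocol is not None
        and Path(config.failed_protocol).exists()
    ):
        failed_table = _load_failed_protocol(Path(config.failed_protocol), backend)
        annotations = _load_annotations(config.annotations)
        optimization = optimize_protocol(failed_table, tables, annotations, backend=backend)
    ledger.record("optimize", 1 if failed_table is not None else 0, 1 if optimization is not None else 0)

    report = render_report(
        ranked_hits=[
            {
                "subject_id": s.hit.subject_id,
                "pident": s.hit.pident,
                "s_seq": s.s_seq,
                "s_taxa_raw": s.s_taxa_raw,
                "s_taxa": s.s_taxa,
                "s_overall": s.s_overall,
                "is_paralog": s.is_paralog,
                "fallback_steps": s.fallback_steps,
            }
            for s in ranked
        ],
        tables=tables,
        optimization=optimization,
        failed_baseline=failed_table,
        query_id=query_id,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(report.to_markdown())
        (out / "ledger.json").write_text(
            json.dumps(ledger.model_dump(), indent=2, sort_keys=True) + "\n"
        )
        for i, table in enumerate(tables):
            write_protocol_csv(table, out / f"protocol_{i:02d}.csv")
    return report, ledger
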