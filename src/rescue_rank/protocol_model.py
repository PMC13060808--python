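"""The standardized purification-protocol table and the protocol diff.

Every mined protocol is normalized to an ordered table with six columns:
purification step, buffer name, buffer composition, pH, salt type and
buffer supplement.  Tables carry provenance (source article title, URL,
organism, similarity score) or are marked as the failed baseline.  The
diff aligns steps between a failed protocol and the successful ones by
step category (lysis / capture / wash / elution / cleavage-dialysis /
polish) and reports per-parameter differences: pH, salt type, named
component concentrations parsed out of the composition text, and
supplements present in successes but absent from the failed protocol.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, Field

from .errors import ProtocolValidationError

logger = logging.getLogger(__name__)

#: Fixed column headers, in the canonical order.
PROTOCOL_COLUMNS: tuple[str, ...] = (
    "Purification Step",
    "Buffer Name",
    "Buffer Composition",
    "pH",
    "Salt Type",
    "Buffer Supplement",
)

#: Keyword lexicon mapping step labels onto alignment categories.
STEP_CATEGORIES: dict[str, tuple[str, ...]] = {
    "lysis": ("lysis", "lyse", "lysed", "sonicat", "homogen", "french press"),
    "capture": (
        "bind", "binding", "equilibr", "histrap", "ni-nta", "ni sepharose",
        "nickel", "imac", "affinity", "resin", "load", "talon", "strep",
    ),
    "wash": ("wash",),
    "elution": ("elut",),
    "cleavage_dialysis": ("dialys", "cleav", "tev", "3c protease", "thrombin"),
    "polish": (
        "size-exclusion", "size exclusion", "gel filtration", "superdex",
        "sephacryl", "sec ", "polish",
    ),
}

#: number + unit + component, tolerant of punctuation; covers styles like
#: "500 mM Imidazole", "5% glycerol", "1.3 mg/ml protease inhibitor".
_CONC_RE = re.compile(
    r"(?P<value>\d+(?:\.\d+)?)\s*(?P<unit>mM|M|%|mg/ml|mg/mL|[muµ]M)\s+"
    r"(?P<component>[A-Za-zβ][\w()\-/β]*(?:\s+inhibitor(?:\s+cocktail)?)?)",
    re.IGNORECASE,
)


class ProtocolStep(BaseModel):
    """One row of the six-column table."""

    purification_step: str
    buffer_name: Optional[str] = None
    buffer_composition: str = ""
    ph: Optional[float] = None
    salt_type: Optional[str] = None
    buffer_supplement: Optional[str] = None


class Provenance(BaseModel):
    """Where a mined protocol came from."""

    article_title: str = ""
    url: str = ""
    organism: str = ""
    similarity_score: Optional[float] = None
    failed_baseline: bool = False


class ProtocolDifference(BaseModel):
    """One parameter-level discrepancy between failed and successful protocols."""

    parameter: str
    step_category: str = ""
    failed_value: Optional[str] = None
    successful_values: list[str] = []
    recommendation: str = ""
    confidence: Optional[Literal["high", "medium", "low"]] = None


class ProtocolTable(BaseModel):
    """Ordered purification steps plus source provenance."""

    steps: list[ProtocolStep]
    provenance: Provenance = Field(default_factory=Provenance)


class OptimizationReport(BaseModel):
    """Diff-driven recommendations plus a revised protocol."""

    differences: list[ProtocolDifference] = []
    revised_protocol: list[ProtocolStep] = []
    annotations_considered: list[str] = []


def validate_table(table: ProtocolTable) -> ProtocolTable:
    """Check the row invariants; returns the table unchanged if valid.

    Raises :class:`ProtocolValidationError` naming the offending step and
    field for an empty step label or a pH outside [0, 14].
    """
    for i, step in enumerate(table.steps, 1):
        if not step.purification_step or not step.purification_step.strip():
            raise ProtocolValidationError(
                f"step {i}: purification_step must be non-empty"
            )
        if step.ph is not None and not 0.0 <= step.ph <= 14.0:
            raise ProtocolValidationError(
                f"step {i} ({step.purification_step}): ph {step.ph} outside [0, 14]"
            )
    return table


def step_category(label: str) -> str | None:
    """Map a free-text step label onto an alignment category."""
    lowered = f"{label.lower()} "
    for category, keywords in STEP_CATEGORIES.items():
        if any(k in lowered for k in keywords):
            return category
    return None


def parse_concentrations(text: str) -> dict[str, tuple[float, str]]:
    """Extract named component concentrations from composition text.

    Returns ``{component_lowercase: (value, unit)}``; the first mention
    of a component wins.
    """
    out: dict[str, tuple[float, str]] = {}
    for m in _CONC_RE.finditer(text):
        component = m.group("component").lower().rstrip(",;.")
        if component not in out:
            out[component] = (float(m.group("value")), m.group("unit"))
    return out


def _supplements(step: ProtocolStep) -> set[str]:
    if not step.buffer_supplement or step.buffer_supplement.strip().lower() == "none":
        return set()
    parts = re.split(r",|;| and ", step.buffer_supplement)
    return {p.strip().lower() for p in parts if p.strip()}


def diff_protocols(
    failed: ProtocolTable, successes: Sequence[ProtocolTable]
) -> list[ProtocolDifference]:
    """Per-parameter differences between a failed protocol and successes.

    Steps are aligned by category; within an aligned category the diff
    covers pH, salt type, shared-component concentrations, and
    supplements that successes use but the failed protocol lacks.
    Identical protocols produce an empty list.  If no step aligns at all
    the list is empty and a notice is logged.
    """
    diffs: list[ProtocolDifference] = []
    failed_by_cat: dict[str, ProtocolStep] = {}
    for step in failed.steps:
        cat = step_category(step.purification_step)
        if cat and cat not in failed_by_cat:
            failed_by_cat[cat] = step
    aligned_any = False
    for cat, fstep in failed_by_cat.items():
        matches = [
            s
            for table in successes
            for s in table.steps
            if step_category(s.purification_step) == cat
        ]
        if not matches:
            continue
        aligned_any = True
        # pH
        ph_vals = [s.ph for s in matches if s.ph is not None]
        if fstep.ph is not None and ph_vals and all(abs(v - fstep.ph) > 1e-9 for v in ph_vals):
            diffs.append(
                ProtocolDifference(
                    parameter="ph",
                    step_category=cat,
                    failed_value=f"{fstep.ph:g}",
                    successful_values=[f"{v:g}" for v in ph_vals],
                )
            )
        # salt type
        salts = [s.salt_type for s in matches if s.salt_type]
        if fstep.salt_type and salts and all(
            s.lower() != fstep.salt_type.lower() for s in salts
        ):
            diffs.append(
                ProtocolDifference(
                    parameter="salt_type",
                    step_category=cat,
                    failed_value=fstep.salt_type,
                    successful_values=sorted(set(salts)),
                )
            )
        # named-component concentrations
        fconc = parse_concentrations(fstep.buffer_composition)
        for component, (fv, funit) in sorted(fconc.items()):
            sv = [
                conc
                for s in matches
                for comp, conc in parse_concentrations(s.buffer_composition).items()
                if comp == component and conc[1].lower() == funit.lower()
            ]
            if sv and all(abs(v - fv) > 1e-9 for v, _ in sv):
                diffs.append(
                    ProtocolDifference(
                        parameter=f"concentration:{component}",
                        step_category=cat,
                        failed_value=f"{fv:g} {funit}",
                        successful_values=[f"{v:g} {u}" for v, u in sv],
                    )
                )
        # supplements present in successes, absent from failed
        fsupp = _supplements(fstep)
        ssupp: dict[str, int] = {}
        for s in matches:
            for supp in _supplements(s):
                ssupp[supp] = ssupp.get(supp, 0) + 1
        for supp in sorted(ssupp):
            if supp not in fsupp:
                diffs.append(
                    ProtocolDifference(
                        parameter=f"supplement:{supp}",
                        step_category=cat,
                        failed_value=None,
                        successful_values=[supp] * ssupp[supp],
                    )
                )
    if not aligned_any:
        logger.info("no alignable steps between failed protocol and successes")
    return diffs


# ---------------------------------------------------------------- reports


class RescueReport(BaseModel):
    """The consolidated final report: ranked homologs, mined protocol
    tables, the failed baseline, and the optimization analysis."""

    query_id: str = ""
    ranked_hits: list[dict] = []
    protocol_tables: list[ProtocolTable] = []
    failed_baseline: Optional[ProtocolTable] = None
    optimization: Optional[OptimizationReport] = None

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RescueReport":
        return cls.model_validate(json.loads(text))

    def to_markdown(self) -> str:
        return render_markdown(self)


def _step_row(step: ProtocolStep) -> list[str]:
    return [
        step.purification_step,
        step.buffer_name or "None",
        step.buffer_composition or "None",
        f"{step.ph:g}" if step.ph is not None else "None",
        step.salt_type or "None",
        step.buffer_supplement or "None",
    ]


def _markdown_table(table: ProtocolTable) -> str:
    lines = [
        "| " + " | ".join(PROTOCOL_COLUMNS) + " |",
        "|" + "---|" * len(PROTOCOL_COLUMNS),
    ]
    for step in table.steps:
        cells = [c.replace("|", "/") for c in _step_row(step)]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_markdown(report: RescueReport) -> str:
    """Render the consolidated report as Markdown."""
    out: list[str] = [f"# Purification rescue report: {report.query_id or 'target'}", ""]
    out.append("## Ranked homologs")
    if report.ranked_hits:
        out.append("| rank | subject | S_seq | S_taxa | S_overall |")
        out.append("|---|---|---|---|---|")
        for i, hit in enumerate(report.ranked_hits, 1):
            out.append(
                f"| {i} | {hit.get('subject_id', '?')} | {hit.get('s_seq', 0):.3f} "
                f"| {hit.get('s_taxa', 0):.3f} | {hit.get('s_overall', 0):.3f} |"
            )
    else:
        out.append("No candidate homologs passed the filters.")
    out.append("")
    out.append("## Mined purification protocols")
    if report.protocol_tables:
        for table in report.protocol_tables:
            prov = table.provenance
            out.append(
                f"### {prov.article_title or 'untitled source'}"
                + (f" ({prov.organism})" if prov.organism else "")
            )
            if prov.url:
                out.append(f"Source: {prov.url}")
            if prov.similarity_score is not None:
                out.append(f"Similarity score: {prov.similarity_score:.3f}")
            out.append("")
            out.append(_markdown_table(table))
            out.append("")
    else:
        out.append("No accessible literature yielded a purification protocol.")
        out.append("")
    if report.failed_baseline is not None:
        out.append("## Failed protocol (baseline)")
        out.append(_markdown_table(report.failed_baseline))
        out.append("")
    if report.optimization is not None:
        out.append("## Optimization analysis")
        if report.optimization.differences:
            out.append(
                "| parameter | step | failed | successful | recommendation | confidence |"
            )
            out.append("|---|---|---|---|---|---|")
            for d in report.optimization.differences:
                out.append(
                    f"| {d.parameter} | {d.step_category} | {d.failed_value or '—'} "
                    f"| {', '.join(d.successful_values) or '—'} "
                    f"| {d.recommendation} | {d.confidence or '—'} |"
                )
        else:
            out.append("No parameter differences detected.")
        if report.optimization.revised_protocol:
            out.append("")
            out.append("### Revised protocol")
            out.append(
                _markdown_table(
                    ProtocolTable(steps=report.optimization.revised_protocol)
                )
            )
        if report.optimization.annotations_considered:
            out.append("")
            out.append(
                "Annotations considered: "
                + ", ".join(report.optimization.annotations_considered)
            )
        out.append("")
    return "\n".join(out)


def render_report(
    ranked_hits: Sequence[dict],
    tables: Sequence[ProtocolTable],
    optimization: OptimizationReport | None = None,
    failed_baseline: ProtocolTable | None = None,
    query_id: str = "",
) -> RescueReport:
    """Assemble the consolidated report object (Markdown/JSON via its methods)."""
    return RescueReport(
        query_id=query_id,
        ranked_hits=list(ranked_hits),
        protocol_tables=list(tables),
        failed_baseline=failed_baseline,
        optimization=optimization,
    )


def write_protocol_csv(table: ProtocolTable, path: str | Path) -> None:
    """Write a table as CSV with the six fixed headers."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PROTOCOL_COLUMNS)
        for step in table.steps:
            writer.writerow(_step_row(step))


def read_protocol_csv(path: str | Path) -> ProtocolTable:
    """Read a six-column protocol CSV back into a table."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != PROTOCOL_COLUMNS:
            raise ProtocolValidationError(
                f"unexpected header {header!r}; expected {list(PROTOCOL_COLUMNS)}"
            )
        steps = []
        for row in reader:
            if not row:
                continue
            step_label, name, comp, ph, salt, supp = row
            steps.append(
                ProtocolStep(
                    purification_step=step_label,
                    buffer_name=None if name == "None" else name,
                    buffer_composition="" if comp == "None" else comp,
                    ph=None if ph == "None" else float(ph),
                    salt_type=None if salt == "None" else salt,
                    buffer_supplement=None if supp == "None" else supp,
                )
            )
    return ProtocolTable(steps=steps)
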