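"""Agent contracts for extraction, summarization and optimization.

Three specialized agents turn mined literature into actionable output:

* the **extractor** reduces a methods section to only the sentences
  describing the purification protocol;
* the **summarizer** converts protocol text into the standardized
  six-column table;
* the **optimizer** compares the failed protocol against the successful
  ones and produces recommendations with confidence labels.

Each agent is a task (role + prompt + payload + expected output schema)
executed by a backend.  The default backend is deterministic and
rule-based: it grounds every value it emits verbatim in its input text,
which is the mechanical counterpart of schema-validated hallucination
guards around a language model.  A remote model can be plugged in behind
the same interface (:class:`CallableBackend`); whatever the backend,
output failing schema validation is retried a bounded number of times
and then surfaced as an :class:`AgentFailureError` — nonconforming
output never propagates downstream.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Any, Callable, Protocol, Sequence

from pydantic import BaseModel, ValidationError

from .errors import AgentFailureError, EmptyProtocolError
from .litmine import MethodsText
from .protocol_model import (
    OptimizationReport,
    ProtocolDifference,
    ProtocolStep,
    ProtocolTable,
    diff_protocols,
)

logger = logging.getLogger(__name__)


class AgentRole(str, Enum):
    extractor = "extractor"
    summarizer = "summarizer"
    optimizer = "optimizer"


#: Expected output type per role; used for schema validation of any backend.
OUTPUT_SCHEMAS: dict[AgentRole, type] = {
    AgentRole.extractor: str,
    AgentRole.summarizer: ProtocolTable,
    AgentRole.optimizer: OptimizationReport,
}


class AgentTask(BaseModel):
    """One unit of agent work: role, prompt, payload, expected schema."""

    role: AgentRole
    instructions: str = ""
    payload: Any = None

    @property
    def output_schema(self) -> type:
        return OUTPUT_SCHEMAS[self.role]


class AgentBackend(Protocol):
    """Anything that can execute an :class:`AgentTask`."""

    name: str
    deterministic: bool

    def run(self, task: AgentTask) -> Any: ...


def load_prompt(role: AgentRole) -> str:
    """The versioned prompt template shipped for a role."""
    return (
        resources.files("rescue_rank").joinpath(f"prompts/{role.value}.txt").read_text()
    )


@lru_cache(maxsize=None)
def load_lexicon(name: str) -> tuple[str, ...]:
    """A shipped lexicon file: one term per line, '#' comments, order kept."""
    text = resources.files("rescue_rank").joinpath(f"lexicons/{name}.txt").read_text()
    return tuple(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[str]:
    """Split on sentence punctuation; joining with single spaces gives the
    whitespace-normalized original back."""
    return [s for s in _SENTENCE_SPLIT.split(text.strip()) if s]


def _find_first(term_list: Sequence[str], text: str) -> re.Match | None:
    """Earliest case-insensitive occurrence of any term; ties favor the
    term listed first."""
    lowered = text.lower()
    best: tuple[int, int] | None = None
    for prio, term in enumerate(term_list):
        pos = lowered.find(term.lower())
        if pos >= 0 and (best is None or (pos, prio) < best):
            best = (pos, prio)
    if best is None:
        return None
    pos, prio = best
    term = term_list[prio]
    return re.compile(re.escape(term), re.IGNORECASE).search(text, pos)


def _find_all(term_list: Sequence[str], text: str) -> list[str]:
    """All matched terms as they appear in the text, in order, without
    overlapping duplicates (e.g. 'protease inhibitor cocktail' suppresses
    the shorter 'protease inhibitor')."""
    found: list[tuple[int, int, str]] = []
    lowered = text.lower()
    for term in term_list:
        start = 0
        tl = term.lower()
        while True:
            pos = lowered.find(tl, start)
            if pos < 0:
                break
            found.append((pos, pos + len(term), text[pos : pos + len(term)]))
            start = pos + 1
    found.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    out: list[tuple[int, int, str]] = []
    for start, end, verbatim in found:
        if any(start >= s and end <= e for s, e, _ in out):
            continue
        out.append((start, end, verbatim))
    return [v for _, _, v in out]


# ------------------------------------------------------------ rules backend


class RulesBackend:
    """Deterministic lexicon/regex backend: a pure function of its input."""

    name = "rules"
    deterministic = True

    def __init__(self, extraction_threshold: int = 1):
        self.extraction_threshold = extraction_threshold

    def run(self, task: AgentTask) -> Any:
        if task.role is AgentRole.extractor:
            return self._extract(task.payload)
        if task.role is AgentRole.summarizer:
            return self._summarize(task.payload)
        return self._optimize(**task.payload)

    # -- extractor

    def _extract(self, methods_text: str) -> str:
        lexicon = load_lexicon("purification")
        kept = []
        for sentence in split_sentences(methods_text):
            lowered = sentence.lower()
            score = sum(1 for term in lexicon if term.lower() in lowered)
            if score >= self.extraction_threshold:
                kept.append(sentence)
        return " ".join(kept)

    # -- summarizer

    _PH_RE = re.compile(r"pH\s*(\d+(?:\.\d+)?)", re.IGNORECASE)

    def _summarize(self, protocol_text: str) -> ProtocolTable:
        step_terms = load_lexicon("steps")
        groups: list[tuple[str, list[str]]] = []  # (verbatim label, sentences)
        for sentence in split_sentences(protocol_text):
            m = _find_first(step_terms, sentence)
            if m is not None:
                groups.append((m.group(0), [sentence]))
            elif groups:
                groups[-1][1].append(sentence)
            else:
                groups.append(("unspecified", [sentence]))
        if not any(label != "unspecified" for label, _ in groups):
            logger.warning("protocol text could not be segmented into steps")
        steps = [self._make_step(label, " ".join(sents)) for label, sents in groups]
        return ProtocolTable(steps=steps)

    def _make_step(self, label: str, text: str) -> ProtocolStep:
        ph = None
        ph_match = self._PH_RE.search(text)
        if ph_match:
            candidate = float(ph_match.group(1))
            if 0.0 <= candidate <= 14.0:
                ph = candidate
            else:
                logger.warning("implausible pH %r left unset: %s", ph_match.group(1), text[:60])
        salt_match = _find_first(load_lexicon("salts"), text)
        salt = salt_match.group(0) if salt_match else None
        name_match = re.search(r"\b([A-Za-z][A-Za-z-]*[ -]buffer)\b", text)
        buffer_name = name_match.group(1) if name_match else None
        spans = _conc_spans(text)
        composition = text[spans[0][0] : spans[-1][1]] if spans else ""
        supplements = _find_all(load_lexicon("additives"), text)
        supplement = ", ".join(dict.fromkeys(supplements)) or None
        return ProtocolStep(
            purification_step=label,
            buffer_name=buffer_name,
            buffer_composition=composition,
            ph=ph,
            salt_type=salt,
            buffer_supplement=supplement,
        )

    # -- optimizer

    def _optimize(
        self,
        failed: ProtocolTable,
        successes: Sequence[ProtocolTable],
        annotations: Sequence[str] = (),
    ) -> OptimizationReport:
        diffs = diff_protocols(failed, list(successes))
        for d in diffs:
            n_support = len(d.successful_values)
            d.confidence = "high" if n_support >= 3 else "medium" if n_support == 2 else "low"
            d.recommendation = _recommendation_for(d)
        annotation_labels = [str(a) for a in annotations]
        for label in annotation_labels:
            key = label.split(":", 1)[0].strip().lower()
            if "transmembrane" in key:
                diffs.append(
                    ProtocolDifference(
                        parameter="annotation:transmembrane",
                        failed_value=None,
                        successful_values=[],
                        recommendation=(
                            "Target has predicted transmembrane span(s) "
                            f"({label}); include a mild detergent (e.g. 0.5% "
                            "CHAPS or 1% DDM) in lysis and purification "
                            "buffers. Annotation-driven, not observed in the "
                            "mined protocols."
                        ),
                        confidence="low",
                    )
                )
            elif "signal" in key:
                diffs.append(
                    ProtocolDifference(
                        parameter="annotation:signal_peptide",
                        failed_value=None,
                        successful_values=[],
                        recommendation=(
                            f"Target carries a predicted signal peptide ({label}); "
                            "consider truncating it from the expression construct "
                            "or targeting periplasmic extraction. Annotation-driven."
                        ),
                        confidence="low",
                    )
                )
        revised = _revise_protocol(failed, diffs)
        return OptimizationReport(
            differences=diffs,
            revised_protocol=revised,
            annotations_considered=annotation_labels,
        )


def _conc_spans(text: str):
    from .protocol_model import _CONC_RE

    return [(m.start(), m.end()) for m in _CONC_RE.finditer(text)]


def _recommendation_for(diff: ProtocolDifference) -> str:
    values = ", ".join(diff.successful_values)
    if diff.parameter == "ph":
        return (
            f"Adjust {diff.step_category} pH from {diff.failed_value} toward the "
            f"successful value(s): {values}."
        )
    if diff.parameter == "salt_type":
        return (
            f"Replace {diff.failed_value} with the salt used in successful "
            f"protocols ({values}) in the {diff.step_category} step."
        )
    if diff.parameter.startswith("concentration:"):
        component = diff.parameter.split(":", 1)[1]
        return (
            f"Adjust {component} in the {diff.step_category} step from "
            f"{diff.failed_value} toward the successful range: {values}."
        )
    if diff.parameter.startswith("supplement:"):
        supplement = diff.parameter.split(":", 1)[1]
        return (
            f"Add {supplement} to the {diff.step_category} buffer; present in "
            f"{len(diff.successful_values)} successful protocol(s), absent from "
            "the failed one."
        )
    return f"Review {diff.parameter}: failed={diff.failed_value}, successful={values}."


def _mode(values: Sequence[str]) -> str:
    counts = Counter(values)
    top = max(counts.values())
    return sorted(v for v, c in counts.items() if c == top)[0]


def _revise_protocol(
    failed: ProtocolTable, diffs: Sequence[ProtocolDifference]
) -> list[ProtocolStep]:
    """Failed steps with consensus successful values substituted in."""
    from .protocol_model import step_category

    revised = [s.model_copy(deep=True) for s in failed.steps]
    for diff in diffs:
        if not diff.successful_values or not diff.step_category:
            continue
        consensus = _mode(diff.successful_values)
        for step in revised:
            if step_category(step.purification_step) != diff.step_category:
                continue
            if diff.parameter == "ph":
                step.ph = float(consensus)
            elif diff.parameter == "salt_type":
                step.salt_type = consensus
            elif diff.parameter.startswith("concentration:"):
                component = diff.parameter.split(":", 1)[1]
                pattern = re.compile(
                    r"\d+(?:\.\d+)?\s*(?:mM|M|%|mg/ml|mg/mL|[muµ]M)(?=\s+"
                    + re.escape(component) + r")",
                    re.IGNORECASE,
                )
                step.buffer_composition = pattern.sub(consensus, step.buffer_composition)
            elif diff.parameter.startswith("supplement:"):
                supplement = diff.parameter.split(":", 1)[1]
                step.buffer_supplement = (
                    f"{step.buffer_supplement}, {supplement}"
                    if step.buffer_supplement
                    else supplement
                )
    return revised


# ------------------------------------------------------------ remote backend


class CallableBackend:
    """Pluggable model backend: wraps any prompt→text completion function.

    The completion is expected to return the output as JSON (or plain
    text for the extractor role).  Schema conformance is enforced by
    :func:`run_task`, not here, so any model endpoint can be adapted by
    supplying ``complete``.
    """

    deterministic = False

    def __init__(self, complete: Callable[[str], str], name: str = "remote"):
        self.complete = complete
        self.name = name

    def run(self, task: AgentTask) -> Any:
        prompt = task.instructions or load_prompt(task.role)
        raw = self.complete(f"{prompt}\n\n{json.dumps(str(task.payload))}")
        if task.role is AgentRole.extractor:
            return raw
        schema = task.output_schema
        return schema.model_validate_json(raw)  # type: ignore[union-attr]


def _validate_output(task: AgentTask, output: Any) -> Any:
    schema = task.output_schema
    if schema is str:
        if not isinstance(output, str):
            raise TypeError(f"extractor output must be text, got {type(output).__name__}")
        return output
    if isinstance(output, schema):
        return output
    return schema.model_validate(output)  # type: ignore[union-attr]


def run_task(task: AgentTask, backend: AgentBackend, retries: int = 2) -> Any:
    """Execute a task, enforcing the output schema with bounded retries."""
    last_error: Exception | None = None
    for attempt in range(retries + 1):
        try:
            return _validate_output(task, backend.run(task))
        except (ValidationError, ValueError, TypeError) as exc:
            last_error = exc
            logger.warning(
                "backend %s produced nonconforming %s output (attempt %d/%d): %s",
                backend.name, task.role.value, attempt + 1, retries + 1, exc,
            )
    raise AgentFailureError(
        f"backend {backend.name} failed schema validation for role "
        f"{task.role.value} after {retries + 1} attempts: {last_error}"
    )


# ------------------------------------------------------------ public ops


def extract_purification_text(
    methods: MethodsText | str, backend: AgentBackend | None = None
) -> str:
    """Reduce a methods section to its purification-protocol sentences.

    The output is always a subset of the input sentences (no synthesis).
    Raises :class:`EmptyProtocolError` when nothing scores above the
    purification lexicon threshold.
    """
    backend = backend or RulesBackend()
    text = methods.text if isinstance(methods, MethodsText) else methods
    task = AgentTask(role=AgentRole.extractor, instructions=load_prompt(AgentRole.extractor), payload=text)
    result = run_task(task, backend)
    if not result.strip() or result.strip() == "NONE":
        raise EmptyProtocolError(message="no purification-related sentences found")
    return result


def summarize_protocol(
    protocol_text: str, backend: AgentBackend | None = None
) -> ProtocolTable:
    """Convert protocol text into the standardized six-column table."""
    backend = backend or RulesBackend()
    task = AgentTask(
        role=AgentRole.summarizer,
        instructions=load_prompt(AgentRole.summarizer),
        payload=protocol_text,
    )
    return run_task(task, backend)


def optimize_protocol(
    failed: ProtocolTable,
    successes: Sequence[ProtocolTable],
    annotations: Sequence[str] = (),
    backend: AgentBackend | None = None,
) -> OptimizationReport:
    """Compare failed vs successful protocols and build recommendations.

    With no successes the report carries annotation-driven
    recommendations only, at low confidence.
    """
    backend = backend or RulesBackend()
    task = AgentTask(
        role=AgentRole.optimizer,
        instructions=load_prompt(AgentRole.optimizer),
        payload={
            "failed": failed,
            "successes": list(successes),
            "annotations": list(annotations),
        },
    )
    return run_task(task, backend)
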