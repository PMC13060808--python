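"""Full-text article handling: JATS parsing, methods-section location,
and citation-accessibility classification.

Archived full-text articles arrive as JATS XML.  The pipeline needs only
the title and the titled section tree; the methods section is located by
searching the section titles for the keyword "method" (case-insensitive
substring, so "Materials and Methods" and "Experimental methods" both
match).  Parsing is tolerant: recoverable defects (undeclared entities,
stray markup) become warnings, while irrecoverable files raise a
:class:`JatsParseError` carrying the article id so a batch loop can log
the failure and continue with the remaining articles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Literal, Sequence

from lxml import etree
from pydantic import BaseModel, model_validator

from .errors import JatsParseError, MissingSectionError

logger = logging.getLogger(__name__)


class ArticleDocument(BaseModel):
    """A parsed article: title plus titled sections in document order.

    ``section_depths`` records each section's nesting level so that a
    matched parent section can absorb its subsections without
    double-counting; ``sections`` bodies contain only the section's own
    text, excluding nested subsections.
    """

    article_id: str
    title: str = ""
    sections: list[tuple[str, str]] = []
    section_depths: list[int] = []
    warnings: list[str] = []


class MethodsText(BaseModel):
    """Concatenated text of the matched methods section(s)."""

    text: str
    matched_titles: list[str]


AccessStatus = Literal["accessible", "no_primary_citation", "not_in_pmc", "no_open_license"]


class CitationRecord(BaseModel):
    """Accessibility of a structure entry's primary citation."""

    structure_id: str
    article_id: str | None = None
    status: AccessStatus

    @model_validator(mode="after")
    def _accessible_has_article(self) -> "CitationRecord":
        if self.status == "accessible" and not self.article_id:
            raise ValueError("accessible citation must carry an article_id")
        return self


def _local(tag: object) -> str:
    """Tag name with any namespace stripped."""
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _own_text(sec: etree._Element) -> str:
    """Text of a <sec>, excluding its <title> and any nested <sec>."""
    parts: list[str] = []
    if sec.text and sec.text.strip():
        parts.append(sec.text.strip())
    for child in sec:
        name = _local(child.tag)
        if name in ("sec", "title"):
            if child.tail and child.tail.strip():
                parts.append(child.tail.strip())
            continue
        chunk = " ".join(t.strip() for t in child.itertext() if t.strip())
        if chunk:
            parts.append(chunk)
        if child.tail and child.tail.strip():
            parts.append(child.tail.strip())
    return " ".join(parts)


def parse_jats(xml_text: str | bytes, article_id: str) -> ArticleDocument:
    """Parse a JATS article into its title and titled sections.

    Entity resolution and network access are disabled; namespaces are
    ignored when matching tags.  Recoverable parse defects are collected
    as warnings.  Raises :class:`JatsParseError` when no document tree
    can be recovered at all.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8", errors="replace")
    warnings: list[str] = []
    strict = etree.XMLParser(resolve_entities=False, no_network=True, huge_tree=False)
    try:
        root = etree.fromstring(xml_text, parser=strict)
    except etree.XMLSyntaxError as exc:
        # A document cut off mid-stream (unclosed tags at EOF, or text
        # ending mid-tag) is not trustworthy even if tag-soup recovery
        # could close it; defects that leave the document complete are
        # recovered with warnings.
        fatal = (
            any(e.type_name == "ERR_TAG_NOT_FINISHED" for e in strict.error_log)
            or not xml_text.rstrip().endswith(b">")
        )
        recovering = etree.XMLParser(
            recover=True, resolve_entities=False, no_network=True, huge_tree=False
        )
        try:
            root = etree.fromstring(xml_text, parser=recovering)
        except etree.XMLSyntaxError:
            root = None
        if root is None or fatal:
            raise JatsParseError(article_id, f"article {article_id}: {exc}") from exc
        warnings = [str(entry) for entry in recovering.error_log]
    title = ""
    for el in root.iter():
        if _local(el.tag) == "article-title":
            title = " ".join(t.strip() for t in el.itertext() if t.strip())
            break
    sections: list[tuple[str, str]] = []
    depths: list[int] = []

    def walk(el: etree._Element, depth: int) -> None:
        for child in el:
            if _local(child.tag) == "sec":
                sec_title = ""
                for sub in child:
                    if _local(sub.tag) == "title":
                        sec_title = " ".join(
                            t.strip() for t in sub.itertext() if t.strip()
                        )
                        break
                sections.append((sec_title, _own_text(child)))
                depths.append(depth)
                walk(child, depth + 1)
            else:
                walk(child, depth)

    walk(root, 0)
    if not sections:
        warnings.append("no <sec> elements found")
    return ArticleDocument(
        article_id=article_id,
        title=title,
        sections=sections,
        section_depths=depths,
        warnings=warnings,
    )


def find_methods_section(
    doc: ArticleDocument, keywords: Sequence[str] = ("method",)
) -> MethodsText:
    """Locate the methods section(s) by keyword in the section titles.

    A section matches when its title contains any keyword
    (case-insensitive substring).  A matched section contributes its
    whole subtree; subsections of a matched section are never counted
    twice even if their own titles also match.

    Raises :class:`MissingSectionError` when nothing matches.
    """
    lowered = [k.lower() for k in keywords]
    matched_titles = [
        t for t, _ in doc.sections if any(k in t.lower() for k in lowered)
    ]
    if not matched_titles:
        raise MissingSectionError(doc.article_id)
    chunks: list[str] = []
    i = 0
    n = len(doc.sections)
    while i < n:
        title, body = doc.sections[i]
        depth = doc.section_depths[i]
        if any(k in title.lower() for k in lowered):
            # absorb the whole subtree of the matched section
            if body:
                chunks.append(body)
            j = i + 1
            while j < n and doc.section_depths[j] > depth:
                if doc.sections[j][1]:
                    chunks.append(doc.sections[j][1])
                j += 1
            i = j
        else:
            i += 1
    return MethodsText(text=" ".join(chunks), matched_titles=matched_titles)


def classify_accessibility(
    structure_id: str,
    has_primary_citation: bool,
    in_pmc: bool,
    open_license: bool,
    article_id: str | None = None,
) -> CitationRecord:
    """Assign exactly one accessibility status, by precedence.

    A structure entry without a primary citation at all is
    ``no_primary_citation``; one whose citation is not archived in the
    open-access full-text archive is ``not_in_pmc``; one archived but
    without a license permitting programmatic retrieval is
    ``no_open_license``; everything else is ``accessible``.
    """
    if not has_primary_citation:
        status: AccessStatus = "no_primary_citation"
    elif not in_pmc:
        status = "not_in_pmc"
    elif not open_license:
        status = "no_open_license"
    else:
        status = "accessible"
    return CitationRecord(structure_id=structure_id, article_id=article_id, status=status)


def parse_articles(
    paths: Iterable[str | Path],
) -> tuple[list[ArticleDocument], list[tuple[str, str]]]:
    """Parse a batch of article files, surviving per-file failures.

    Returns the successfully parsed documents plus a list of
    ``(article_id, reason)`` failures; no exception escapes the loop.
    """
    docs: list[ArticleDocument] = []
    failures: list[tuple[str, str]] = []
    for path in paths:
        path = Path(path)
        article_id = path.stem
        try:
            docs.append(parse_jats(path.read_text(errors="replace"), article_id))
        except JatsParseError as exc:
            logger.warning("article %s failed to parse: %s", article_id, exc)
            failures.append((article_id, str(exc)))
        except OSError as exc:
            logger.warning("article %s unreadable: %s", article_id, exc)
            failures.append((article_id, str(exc)))
    return docs, failures


def write_extraction_records(
    records: Iterable[dict], out_path: str | Path
) -> None:
    """Write per-article extraction records as JSONL."""
    with open(out_path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
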