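"""Taxonomy trees and rank-penalized evolutionary distances.

A query organism and each BLAST subject organism are placed on a rooted
taxonomy tree (NCBI-taxdump-style or a simple 4-column TSV).  The distance
between two organisms is the unique up-to-LCA-and-down path through the
tree, where every traversed node charges a penalty that grows with the
height of its rank, and crossing between domains of life adds a single
large surcharge.  Organisms absent from the tree are resolved by walking
up a caller-supplied lineage until an ancestor is found; each hop is
counted so the similarity layer can discount the score accordingly.

Node-counting convention: the penalized distance between ``a`` and ``b``
is the sum of the per-rank penalty of every node on the path *excluding
the lowest common ancestor*.  Equivalently each parent-child edge on the
path costs the child's rank penalty.  This makes the distance a true tree
metric: ``d(a, a) = 0``, ``d(a, b) = d(b, a)``, adjacent nodes are one
penalty apart, and the triangle inequality holds.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path
from typing import Iterable, Literal, Mapping, TextIO

from pydantic import BaseModel, Field, NonNegativeFloat, NonNegativeInt, model_validator

from .errors import DomainError, TaxonomyStructureError, UnresolvableTaxonError

logger = logging.getLogger(__name__)

Rank = Literal[
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
    "no_rank",
]

#: Rank strings seen in NCBI dumps that map onto the controlled vocabulary.
RANK_ALIASES: dict[str, Rank] = {
    "superkingdom": "domain",
    "domain": "domain",
    "kingdom": "kingdom",
    "phylum": "phylum",
    "class": "class",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "strain": "strain",
    "subspecies": "strain",
    "no rank": "no_rank",
    "no_rank": "no_rank",
    "clade": "no_rank",
}


class TaxonNode(BaseModel):
    """One taxon: an organism or clade with a rank and a parent."""

    taxon_id: int = Field(gt=0)
    name: str = ""
    rank: Rank = "no_rank"
    parent_id: int | None = None


class TaxonomyTree(BaseModel):
    """Rooted tree of ranked taxa with O(depth) ancestor walks."""

    nodes: dict[int, TaxonNode]
    root_id: int

    @model_validator(mode="after")
    def _check_structure(self) -> "TaxonomyTree":
        root = self.nodes.get(self.root_id)
        if root is None:
            raise TaxonomyStructureError(f"root id {self.root_id} not among nodes")
        if root.parent_id not in (None, root.taxon_id):
            raise TaxonomyStructureError("root node must be parentless or self-parenting")
        for node in self.nodes.values():
            if node.taxon_id == self.root_id:
                continue
            if node.parent_id is None:
                raise TaxonomyStructureError(
                    f"node {node.taxon_id} has no parent but is not the root"
                )
            if node.parent_id not in self.nodes:
                raise TaxonomyStructureError(
                    f"node {node.taxon_id} has dangling parent_id {node.parent_id}"
                )
        # Cycle check: every parent chain must terminate at the root.
        for start in self.nodes:
            seen: set[int] = set()
            cur = start
            while cur != self.root_id:
                if cur in seen:
                    raise TaxonomyStructureError(f"cyclic parent chain at node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id  # type: ignore[assignment]
        return self

    def __contains__(self, taxon_id: object) -> bool:
        return taxon_id in self.nodes

    def ancestors(self, taxon_id: int) -> list[int]:
        """Path of ids from ``taxon_id`` (inclusive) up to the root (inclusive)."""
        if taxon_id not in self.nodes:
            raise UnresolvableTaxonError(taxon_id)
        chain = [taxon_id]
        cur = taxon_id
        while cur != self.root_id:
            cur = self.nodes[cur].parent_id  # type: ignore[assignment]
            chain.append(cur)
        return chain

    def domain_of(self, taxon_id: int) -> int | None:
        """The id of the domain-rank ancestor (or self), if any."""
        for tid in self.ancestors(taxon_id):
            if self.nodes[tid].rank == "domain":
                return tid
        return None

    def leaves(self) -> list[int]:
        has_child: set[int] = set()
        for node in self.nodes.values():
            if node.parent_id is not None and node.taxon_id != self.root_id:
                has_child.add(node.parent_id)
        return [tid for tid in self.nodes if tid not in has_child]


#: Default traversal cost per rank; higher taxonomy levels cost more so that
#: paths through distant clades score as less similar.
DEFAULT_RANK_PENALTIES: dict[str, float] = {
    "species": 1.0,
    "strain": 1.0,
    "no_rank": 1.0,
    "genus": 2.0,
    "family": 3.0,
    "order": 4.0,
    "class": 5.0,
    "phylum": 6.0,
    "kingdom": 8.0,
    "domain": 10.0,
}


class RankPenaltySchedule(BaseModel):
    """Traversal costs per rank plus the domain-crossing surcharge.

    ``missing_lineage_decrement`` is the amount subtracted from the
    taxonomic similarity score per lineage-fallback hop taken while
    resolving an organism absent from the tree.
    """

    per_rank_penalty: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_RANK_PENALTIES)
    )
    domain_crossing_penalty: float = 16.0
    missing_lineage_decrement: NonNegativeFloat = 0.05

    @model_validator(mode="after")
    def _check_penalties(self) -> "RankPenaltySchedule":
        for rank, cost in self.per_rank_penalty.items():
            if cost <= 0:
                raise DomainError(f"penalty for rank {rank!r} must be > 0, got {cost}")
        if self.domain_crossing_penalty < max(self.per_rank_penalty.values()):
            raise DomainError(
                "domain_crossing_penalty must be >= the largest per-rank penalty"
            )
        return self

    def cost(self, rank: str) -> float:
        return self.per_rank_penalty.get(rank, self.per_rank_penalty.get("no_rank", 1.0))

    @classmethod
    def from_config(cls, source: str | Path | TextIO) -> "RankPenaltySchedule":
        """Read a flat ``key = value`` config (rank costs plus the two extras)."""
        text = _read_text(source)
        per_rank = dict(DEFAULT_RANK_PENALTIES)
        crossing = 16.0
        decrement = 0.05
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "domain_crossing_penalty":
                crossing = float(value)
            elif key == "missing_lineage_decrement":
                decrement = float(value)
            else:
                per_rank[key] = float(value)
        return cls(
            per_rank_penalty=per_rank,
            domain_crossing_penalty=crossing,
            missing_lineage_decrement=decrement,
        )


class TaxonomicDistance(BaseModel):
    """The penalized path between two resolved organisms."""

    raw_distance: NonNegativeFloat
    path: list[int]
    crossed_domain: bool = False
    fallback_steps: NonNegativeInt = 0


def _read_text(source: str | Path | TextIO) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            return source
        return Path(source).read_text()
    return source.read()


def load_taxonomy(
    source: str | Path | TextIO,
    names: str | Path | TextIO | None = None,
) -> TaxonomyTree:
    """Load a taxonomy tree from tabular node records.

    Two dialects are accepted and auto-detected per line:

    * NCBI-taxdump ``nodes.dmp`` style: fields separated by ``\\t|\\t``
      (``taxon_id | parent_id | rank | ...``), optionally with a matching
      ``names.dmp`` passed as ``names``.
    * A simplified 4-column TSV: ``taxon_id, parent_id, rank, name``.

    The root row is self-parenting or has an empty parent field.  Unknown
    rank strings map to ``no_rank`` with a logged warning.
    """
    text = _read_text(source)
    nodes: dict[int, TaxonNode] = {}
    root_id: int | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "|" in line:
            fields = [f.strip() for f in line.strip().rstrip("|").split("|")]
        else:
            fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise TaxonomyStructureError(f"line {lineno}: expected >= 3 columns")
        taxon_id = int(fields[0])
        parent_field = fields[1]
        rank_str = fields[2].lower()
        name = fields[3] if len(fields) > 3 else ""
        rank = RANK_ALIASES.get(rank_str)
        if rank is None:
            logger.warning("line %d: unknown rank %r mapped to no_rank", lineno, rank_str)
            rank = "no_rank"
        parent_id = int(parent_field) if parent_field else None
        if parent_id is None or parent_id == taxon_id:
            if root_id is not None and root_id != taxon_id:
                raise TaxonomyStructureError(
                    f"multiple roots: {root_id} and {taxon_id}"
                )
            root_id = taxon_id
            parent_id = None
        if taxon_id in nodes:
            raise TaxonomyStructureError(f"duplicate taxon_id {taxon_id}")
        nodes[taxon_id] = TaxonNode(
            taxon_id=taxon_id, parent_id=parent_id, rank=rank, name=name
        )
    if root_id is None:
        raise TaxonomyStructureError("no root row (self-parenting or parentless)")
    if names is not None:
        for raw in _read_text(names).splitlines():
            if not raw.strip():
                continue
            fields = [f.strip() for f in raw.strip().rstrip("|").split("|")]
            tid = int(fields[0])
            name_class = fields[3].lower() if len(fields) > 3 else "scientific name"
            if tid in nodes and (not nodes[tid].name or name_class == "scientific name"):
                nodes[tid].name = fields[1]
    return TaxonomyTree(nodes=nodes, root_id=root_id)


def resolve_with_fallback(
    tree: TaxonomyTree,
    taxon_id: int,
    lineage: Iterable[int] = (),
) -> tuple[TaxonNode, int]:
    """Resolve a taxon against the tree, walking up its lineage if absent.

    ``lineage`` is ordered from immediate parent to root.  Returns the
    first entry found in the tree together with the number of hops
    consumed (0 if the taxon itself is present).

    Raises :class:`UnresolvableTaxonError` when neither the taxon nor any
    lineage entry is in the tree; the caller excludes the hit and logs it.
    """
    if taxon_id in tree:
        return tree.nodes[taxon_id], 0
    for steps, ancestor in enumerate(lineage, start=1):
        if ancestor in tree:
            logger.info(
                "taxon %s absent from tree; resolved to ancestor %s after %d step(s)",
                taxon_id, ancestor, steps,
            )
            return tree.nodes[ancestor], steps
    raise UnresolvableTaxonError(taxon_id)


def penalized_distance(
    tree: TaxonomyTree,
    a: int,
    b: int,
    schedule: RankPenaltySchedule | None = None,
) -> TaxonomicDistance:
    """Rank-penalized distance along the unique tree path from ``a`` to ``b``.

    Every node on the path except the lowest common ancestor contributes
    its rank penalty; if the two organisms fall under different
    domain-rank ancestors the domain-crossing surcharge is added once.
    """
    schedule = schedule or RankPenaltySchedule()
    chain_a = tree.ancestors(a)  # raises UnresolvableTaxonError if absent
    chain_b = tree.ancestors(b)
    set_a = {tid: i for i, tid in enumerate(chain_a)}
    lca = next(tid for tid in chain_b if tid in set_a)
    up = chain_a[: set_a[lca]]          # a .. just below LCA
    down = chain_b[: chain_b.index(lca)]  # b .. just below LCA
    path = up + [lca] + list(reversed(down))
    raw = sum(schedule.cost(tree.nodes[tid].rank) for tid in up + down)
    dom_a, dom_b = tree.domain_of(a), tree.domain_of(b)
    crossed = dom_a is not None and dom_b is not None and dom_a != dom_b
    if crossed:
        raw += schedule.domain_crossing_penalty
    return TaxonomicDistance(raw_distance=raw, path=path, crossed_domain=crossed)


def max_distance(
    tree: TaxonomyTree,
    schedule: RankPenaltySchedule | None = None,
    exact_leaf_limit: int = 400,
    floor: float = 1.0,
) -> float:
    """Penalized diameter of the tree, used to normalize distances to [0, 1].

    Computed exactly (all leaf pairs) for trees with at most
    ``exact_leaf_limit`` leaves, and by a deepest-leaves-per-domain
    heuristic above that.  A single-node tree returns ``floor`` so that
    division by the result is always defined.
    """
    schedule = schedule or RankPenaltySchedule()
    leaves = tree.leaves()
    if len(leaves) <= 1:
        return floor
    if len(leaves) <= exact_leaf_limit:
        candidates = leaves
    else:
        # Deepest leaf per domain plus the two deepest overall: diameter
        # endpoints of a positively node-weighted tree are always leaves,
        # and the crossing surcharge is maximized by pairing domains.
        depth = {
            leaf: sum(
                schedule.cost(tree.nodes[t].rank) for t in tree.ancestors(leaf)[:-1]
            )
            for leaf in leaves
        }
        by_domain: dict[int | None, int] = {}
        for leaf in leaves:
            dom = tree.domain_of(leaf)
            if dom not in by_domain or depth[leaf] > depth[by_domain[dom]]:
                by_domain[dom] = leaf
        candidates = list(set(by_domain.values()))
        candidates += sorted(leaves, key=depth.get, reverse=True)[:2]
        candidates = list(dict.fromkeys(candidates))
    best = 0.0
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            d = penalized_distance(tree, a, b, schedule).raw_distance
            if d > best:
                best = d
    return max(best, floor)


def write_taxonomy_tsv(tree: TaxonomyTree, path: str | Path) -> None:
    """Write the simplified 4-column TSV dialect (root row self-parenting)."""
    buf = StringIO()
    for tid in sorted(tree.nodes):
        node = tree.nodes[tid]
        parent = node.parent_id if node.parent_id is not None else tid
        buf.write(f"{tid}\t{parent}\t{node.rank}\t{node.name}\n")
    Path(path).write_text(buf.getvalue())
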