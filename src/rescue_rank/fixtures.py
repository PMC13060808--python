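"""Synthetic test-data generation with machine-readable ground truth.

Everything the pipeline consumes — taxonomy trees, BLAST hit tables,
JATS articles with planted purification protocols, a failed-protocol
text, citation metadata, annotations — can be generated synthetically so
the whole workflow runs and is testable offline.  Every generated bundle
is accompanied by a manifest recording the planted ground truth:
pairwise leaf distances (computed by an independent brute-force path
oracle over a networkx graph, not by the distance implementation under
test), the exact scores each surviving hit must receive (straight-line
transcription of the scoring formulas), and the six-column rows each
planted protocol must summarize to.

Generation is fully deterministic under a fixed seed.  The fixtures
emulate the *structure* of real archives (tree shapes, tabular hit
columns, JATS section nesting, protocol phrasing variety), not the
content of real PDB entries or articles.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from typing import Sequence

import networkx as nx
from pydantic import BaseModel, Field

from .errors import ConfigurationError
from .taxonomy import (
    RankPenaltySchedule,
    TaxonomyTree,
    load_taxonomy,
    write_taxonomy_tsv,
)

#: Ranks used below the domain level, shallowest first.
_RANK_CHAIN = ("phylum", "class", "order", "family", "genus", "species")


class FixtureSpec(BaseModel):
    """Shape and content parameters for one synthetic bundle."""

    seed: int = 0
    # taxonomy shape
    domains: int = Field(default=2, ge=1)
    depth: int = Field(default=4, ge=1, le=len(_RANK_CHAIN))
    branching: int = Field(default=2, ge=1)
    # hit table composition
    n_hits_passing: int = 20
    n_fail_pident: int = 5
    n_fail_evalue: int = 5
    n_fail_qcov: int = 5
    n_paralogs: int = 1
    # articles
    n_articles: int = 3
    malformed_rate: float = Field(default=0.0, ge=0.0, le=1.0)


# ------------------------------------------------------- brute-force oracle


def oracle_distance(
    tree: TaxonomyTree, a: int, b: int, schedule: RankPenaltySchedule
) -> float:
    """Brute-force penalized distance via explicit graph search.

    Builds an undirected networkx graph of the tree, enumerates the
    shortest path, identifies the LCA as the path node closest to the
    root, and sums rank penalties over every other path node, adding the
    crossing surcharge when the two endpoints sit under different
    domain-rank ancestors.  Used for fixture manifests and as the
    independent cross-check of the implementation's ancestor-chain walk.
    """
    graph = nx.Graph()
    graph.add_nodes_from(tree.nodes)
    for node in tree.nodes.values():
        if node.parent_id is not None and node.taxon_id != tree.root_id:
            graph.add_edge(node.taxon_id, node.parent_id)
    path = nx.shortest_path(graph, a, b)
    root_depth = nx.single_source_shortest_path_length(graph, tree.root_id)
    lca = min(path, key=lambda n: root_depth[n])
    raw = sum(
        schedule.cost(tree.nodes[n].rank) for n in path if n != lca
    )

    def domain_of(n: int) -> int | None:
        cur = n
        while True:
            if tree.nodes[cur].rank == "domain":
                return cur
            if cur == tree.root_id:
                return None
            cur = tree.nodes[cur].parent_id  # type: ignore[assignment]

    dom_a, dom_b = domain_of(a), domain_of(b)
    if dom_a is not None and dom_b is not None and dom_a != dom_b:
        raw += schedule.domain_crossing_penalty
    return raw


# ------------------------------------------------------------- taxonomy


def make_taxonomy(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, dict]:
    """Emit a synthetic taxonomy TSV plus a ground-truth manifest.

    The manifest lists every pairwise leaf distance twice: under unit
    penalties (all ranks cost 1, crossing surcharge 1) and under the
    default penalty schedule, both computed by the brute-force oracle.
    """
    if spec.domains < 1:
        raise ConfigurationError("tree must have at least one domain")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[int, int, str, str]] = [(1, 1, "no_rank", "root")]
    next_id = 2
    ranks = _RANK_CHAIN[-spec.depth :]
    frontier: list[tuple[int, int]] = []  # (taxon_id, domain ordinal)
    for d in range(spec.domains):
        rows.append((next_id, 1, "domain", f"Domain_{d}"))
        frontier.append((next_id, d))
        next_id += 1
    for rank in ranks:
        new_frontier: list[tuple[int, int]] = []
        for parent, dom in frontier:
            for c in range(spec.branching):
                rows.append((next_id, parent, rank, f"{rank}_{dom}_{next_id}_{c}"))
                new_frontier.append((next_id, dom))
                next_id += 1
        frontier = new_frontier
    tree_path = out_dir / "tree.tsv"
    tree_path.write_text(
        "".join(f"{t}\t{p}\t{r}\t{n}\n" for t, p, r, n in rows)
    )
    tree = load_taxonomy(tree_path)
    leaves = sorted(tree.leaves())
    unit = RankPenaltySchedule(
        per_rank_penalty={r: 1.0 for r in set(x[2] for x in rows)},
        domain_crossing_penalty=1.0,
    )
    default = RankPenaltySchedule()
    unit_d: dict[str, float] = {}
    default_d: dict[str, float] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            key = f"{a}-{b}"
            unit_d[key] = oracle_distance(tree, a, b, unit)
            default_d[key] = oracle_distance(tree, a, b, default)
    manifest = {
        "tree_file": tree_path.name,
        "n_nodes": len(rows),
        "leaves": leaves,
        "unit_distances": unit_d,
        "default_distances": default_d,
        "default_maxdistance": max(default_d.values()) if default_d else 1.0,
    }
    return tree_path, manifest


def leaf_distance(manifest: dict, a: int, b: int, which: str = "default") -> float:
    """Look a leaf-pair distance up in a taxonomy manifest."""
    if a == b:
        return 0.0
    key = f"{min(a, b)}-{max(a, b)}"
    return manifest[f"{which}_distances"][key]


# ------------------------------------------------------------- hit tables


def make_hits(
    spec: FixtureSpec, tree_manifest: dict, out_dir: str | Path
) -> tuple[Path, dict]:
    """Emit an outfmt-6-style hit table plus exact expected scores.

    A spec-controlled number of rows violates each filter threshold; the
    manifest records which rows must survive filtering and, for those,
    the exact score components under default weights — computed here as
    a straight-line transcription of the scoring formulas against the
    oracle distances, independently of the scoring implementation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed ^ 0x5EED)
    leaves: list[int] = list(tree_manifest["leaves"])
    query_taxon = leaves[0]
    maxdistance = float(tree_manifest["default_maxdistance"])

    rows: list[dict] = []

    def add_row(kind: str, *, pident=None, evalue=None, qcov=None, taxon=None):
        i = len(rows)
        pident = pident if pident is not None else round(rng.uniform(25.0, 95.0), 1)
        evalue = evalue if evalue is not None else 10 ** rng.uniform(-50, -4)
        qcov = qcov if qcov is not None else round(rng.uniform(80.0, 100.0), 1)
        taxon = taxon if taxon is not None else rng.choice(leaves[1:])
        rows.append(
            {
                "subject_id": f"SBJ{i:03d}_A",
                "pident": pident,
                "evalue": evalue,
                "qcov": qcov,
                "bitscore": round(rng.uniform(80.0, 600.0), 1),
                "taxon": taxon,
                "kind": kind,
            }
        )

    for _ in range(spec.n_paralogs):
        add_row("paralog", taxon=query_taxon)
    for _ in range(spec.n_hits_passing - spec.n_paralogs):
        add_row("passing")
    for _ in range(spec.n_fail_pident):
        add_row("fail_pident", pident=round(rng.uniform(5.0, 19.9), 1))
    for _ in range(spec.n_fail_evalue):
        add_row("fail_evalue", evalue=10 ** rng.uniform(-2.9, 0.9))
    for _ in range(spec.n_fail_qcov):
        add_row("fail_qcov", qcov=round(rng.uniform(10.0, 74.9), 1))
    rng.shuffle(rows)

    lines = []
    for row in rows:
        length = int(300 * row["qcov"] / 100)
        lines.append(
            "\t".join(
                [
                    "QUERY",
                    row["subject_id"],
                    f"{row['pident']:.1f}",
                    str(length),
                    str(int(length * (100 - row["pident"]) / 100)),
                    "1",
                    "1",
                    str(length),
                    "1",
                    str(length),
                    f"{row['evalue']:.3e}",
                    f"{row['bitscore']:.1f}",
                    f"{row['qcov']:.1f}",
                    str(row["taxon"]),
                ]
            )
        )
    hits_path = out_dir / "hits.tsv"
    hits_path.write_text("\n".join(lines) + "\n")

    # Straight-line transcription of the three scoring formulas.
    expected = {}
    survivors = []
    for row in rows:
        passes = (
            row["pident"] > 20.0 and row["evalue"] < 1e-3 and row["qcov"] > 75.0
        )
        if not passes:
            continue
        survivors.append(row)
    if len(survivors) > 50:
        survivors.sort(key=lambda r: (-r["bitscore"], r["evalue"], r["subject_id"]))
        survivors = survivors[:50]
    for row in survivors:
        s_seq = row["pident"] / 100.0
        d = leaf_distance(tree_manifest, query_taxon, row["taxon"], "default")
        s_taxa_raw = 0.5 if d == 0 else 1.0 - d / maxdistance
        s_taxa = min(1.0, max(0.0, s_taxa_raw))
        if row["taxon"] == query_taxon:
            s_taxa = s_taxa / 2.0
        expected[row["subject_id"]] = {
            "s_seq": s_seq,
            "s_taxa_raw": s_taxa_raw,
            "s_taxa": s_taxa,
            "s_overall": 0.5 * s_seq + 0.5 * s_taxa,
            "is_paralog": row["taxon"] == query_taxon,
            "taxon": row["taxon"],
        }
    manifest = {
        "hits_file": hits_path.name,
        "query_taxon": query_taxon,
        "n_rows": len(rows),
        "surviving_ids": sorted(expected),
        "expected_scores": expected,
        "maxdistance": maxdistance,
    }
    return hits_path, manifest


# ------------------------------------------------------------- articles

_CLONING_SENTENCES = (
    "The gene encoding the target was amplified by PCR from genomic DNA.",
    "The amplicon was inserted into the pET28a vector and verified by Sanger sequencing.",
    "Transformed BL21(DE3) cells were grown at 37 degrees and induced with IPTG overnight.",
    "Site-directed mutagenesis was carried out following the manufacturer's instructions.",
)

_SUPPLEMENT_POOL = (
    ("5% glycerol", "glycerol"),
    ("1 mM DTT", "DTT"),
    ("1 mM TCEP", "TCEP"),
    ("0.5% CHAPS", "CHAPS"),
)

_METHODS_TITLES = ("Materials and Methods", "Methods", "METHODS", "Experimental methods")


def _protocol_steps(rng: random.Random, imidazole_mm: int, supplements: Sequence[int]):
    """Planted step parameters + sentence template realizations.

    Returns (sentences, expected_rows).  Templates are engineered so the
    step keyword whose verbatim span becomes the step label is the
    earliest lexicon match in each sentence.
    """
    agent = rng.choice(("HEPES", "Tris-HCl"))
    salt_conc = rng.choice((150, 300, 500))
    base = f"{rng.choice((20, 25, 50))} mM {agent}"
    supp = [_SUPPLEMENT_POOL[i] for i in supplements]
    supp_text = ", ".join(s[0] for s in supp)
    supp_names = ", ".join(s[1] for s in supp) or None

    lys_comp = f"{base}, {salt_conc} mM NaCl" + (f", {supp_text}" if supp else "")
    lys_ph = rng.choice((7.0, 7.4, 8.0))
    variant = rng.randrange(2)
    if variant == 0:
        lys_sentence = (
            f"Cells were lysed in resuspension buffer containing {lys_comp}, pH {lys_ph}."
        )
        lys_label, lys_buffer = "lysed", "resuspension buffer"
    else:
        lys_sentence = f"Cell pellets were sonicated in {lys_comp}, pH {lys_ph}."
        lys_label, lys_buffer = "sonicated", None

    elu_comp = f"{base}, {salt_conc} mM NaCl, {imidazole_mm} mM Imidazole"
    elu_ph = rng.choice((7.0, 7.5))
    if variant == 0:
        elu_sentence = f"The protein was eluted with {elu_comp}, pH {elu_ph}."
    else:
        elu_sentence = f"Target protein was eluted using a gradient of {elu_comp}, pH {elu_ph}."
    elu_label = "eluted"

    sec_comp = f"{base}, {salt_conc} mM NaCl"
    sec_ph = rng.choice((7.0, 7.5, 8.0))
    if variant == 0:
        sec_sentence = (
            f"Size-exclusion chromatography was performed on a Superdex 75 column in "
            f"{sec_comp}, pH {sec_ph}."
        )
        sec_label = "Size-exclusion"
    else:
        sec_sentence = f"Gel filtration on a Superdex 200 column used {sec_comp}, pH {sec_ph}."
        sec_label = "Gel filtration"

    sentences = [lys_sentence, elu_sentence, sec_sentence]
    rows = [
        {
            "purification_step": lys_label,
            "buffer_name": lys_buffer,
            "buffer_composition": lys_comp,
            "ph": lys_ph,
            "salt_type": "NaCl",
            "buffer_supplement": supp_names,
        },
        {
            "purification_step": elu_label,
            "buffer_name": None,
            "buffer_composition": elu_comp,
            "ph": elu_ph,
            "salt_type": "NaCl",
            "buffer_supplement": None,
        },
        {
            "purification_step": sec_label,
            "buffer_name": None,
            "buffer_composition": sec_comp,
            "ph": sec_ph,
            "salt_type": "NaCl",
            "buffer_supplement": None,
        },
    ]
    return sentences, rows


def _jats_xml(article_id: str, title: str, methods_title: str, cloning: str,
              protocol_paragraph: str, nested: bool) -> str:
    if nested:
        methods_body = (
            f"<p>{cloning}</p>"
            f"<sec><title>Protein purification</title><p>{protocol_paragraph}</p></sec>"
        )
    else:
        methods_body = f"<p>{cloning} {protocol_paragraph}</p>"
    return (
        "<?xml version='1.0' encoding='UTF-8'?>\n"
        "<article>"
        "<front><article-meta><title-group>"
        f"<article-title>{title}</article-title>"
        "</title-group></article-meta></front>"
        "<body>"
        "<sec><title>Introduction</title><p>Background on the target protein family.</p></sec>"
        f"<sec><title>{methods_title}</title>{methods_body}</sec>"
        "<sec><title>Results</title><p>Structure determination proceeded smoothly.</p></sec>"
        "<sec><title>Discussion</title><p>Implications are discussed.</p></sec>"
        "</body></article>"
    )


def make_articles(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, dict]:
    """Emit JATS article files with planted protocols plus ground truth.

    ``malformed_rate`` of the files (rounded to the nearest count) are
    truncated mid-tag so they fail parsing; the manifest records which.
    """
    out_dir = Path(out_dir)
    articles_dir = out_dir / "articles"
    articles_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed ^ 0xA47)
    n_malformed = round(spec.n_articles * spec.malformed_rate)
    malformed_idx = set(rng.sample(range(spec.n_articles), n_malformed))
    records = []
    for i in range(spec.n_articles):
        article_id = f"PMC{900000 + i}"
        imidazole = 500  # successful protocols share the elution concentration
        supplements = (0, 1) if rng.random() < 0.5 else (0,)  # glycerol always planted
        sentences, rows = _protocol_steps(rng, imidazole, supplements)
        protocol_paragraph = " ".join(sentences)
        title = f"Crystal structure of synthetic target homolog {i}"
        methods_title = _METHODS_TITLES[i % len(_METHODS_TITLES)]
        xml = _jats_xml(
            article_id,
            title,
            methods_title,
            rng.choice(_CLONING_SENTENCES),
            protocol_paragraph,
            nested=bool(i % 2),
        )
        malformed = i in malformed_idx
        if malformed:
            xml = xml[: int(len(xml) * 0.6)]
        (articles_dir / f"{article_id}.xml").write_text(xml)
        records.append(
            {
                "article_id": article_id,
                "title": title,
                "methods_title": methods_title,
                "malformed": malformed,
                "protocol_text": protocol_paragraph,
                "expected_rows": rows,
            }
        )
    manifest = {
        "articles_dir": articles_dir.name,
        "n_articles": spec.n_articles,
        "n_malformed": n_malformed,
        "articles": records,
    }
    return articles_dir, manifest


def make_failed_protocol(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, dict]:
    """Emit a failed-protocol text with planted differences vs successes.

    The failed protocol elutes at 250 mM imidazole where every generated
    success uses 500 mM, and its lysis buffer lacks the glycerol that
    successes include — one concentration difference and one
    missing-supplement difference by construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed ^ 0xFA11)
    sentences, rows = _protocol_steps(rng, imidazole_mm=250, supplements=())
    text = " ".join(sentences)
    path = out_dir / "failed_protocol.txt"
    path.write_text(text + "\n")
    manifest = {
        "failed_protocol_file": path.name,
        "protocol_text": text,
        "expected_rows": rows,
        "planted_differences": [
            {"parameter": "concentration:imidazole", "failed": "250 mM", "successful": "500 mM"},
            {"parameter": "supplement:glycerol"},
        ],
    }
    return path, manifest


# ------------------------------------------------------------- full bundle


def make_bundle(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Generate every input the pipeline needs, plus manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _, tax_manifest = make_taxonomy(spec, out_dir)
    _, hit_manifest = make_hits(spec, tax_manifest, out_dir)
    _, art_manifest = make_articles(spec, out_dir)
    _, failed_manifest = make_failed_protocol(spec, out_dir)

    (out_dir / "query.fasta").write_text(
        ">QUERY synthetic rescue target\n"
        "MKVLAAGITGLDGSGKTTVLNAVAHEMGFAHLDTGALYRAVTLAAIRAGVDLEDEAGLTE\n"
        "LAARHPIQFGRDGEYRLFLDGEDVSREIRTPEVSNAASKVAAIPEVRAALLARQRAFAES\n"
    )
    (out_dir / "annotations.txt").write_text(
        "transmembrane: 35-57\nsignal_peptide: 1-22\n"
    )
    # Citation metadata: the best-scoring subjects point at the generated
    # articles; two more carry each inaccessible status for classification.
    order = sorted(
        hit_manifest["expected_scores"].items(),
        key=lambda kv: (-kv[1]["s_overall"], kv[0]),
    )
    citations: dict[str, dict] = {}
    art_ids = [a["article_id"] for a in art_manifest["articles"]]
    for (subject_id, _), article_id in zip(order, art_ids):
        citations[subject_id] = {
            "article_id": article_id,
            "has_primary_citation": True,
            "in_pmc": True,
            "open_license": True,
        }
    extras = [
        {"has_primary_citation": False, "in_pmc": False, "open_license": False},
        {"has_primary_citation": True, "in_pmc": False, "open_license": False},
        {"has_primary_citation": True, "in_pmc": True, "open_license": False},
    ]
    for (subject_id, _), meta in zip(order[len(art_ids) :], extras):
        citations[subject_id] = {"article_id": None, **meta}
    (out_dir / "citations.json").write_text(json.dumps(citations, indent=2, sort_keys=True))

    manifest = {
        "spec": spec.model_dump(),
        "taxonomy": tax_manifest,
        "hits": hit_manifest,
        "articles": art_manifest,
        "failed_protocol": failed_manifest,
        "citations": citations,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_random_tree(
    rng: random.Random, n_nodes: int, n_domains: int = 2
) -> TaxonomyTree:
    """A random well-formed tree for property tests: root, ``n_domains``
    domain children, then nodes attached uniformly with random ranks."""
    rows = [(1, 1, "no_rank", "root")]
    ids = [1]
    for d in range(min(n_domains, max(n_nodes - 1, 0))):
        rows.append((2 + d, 1, "domain", f"D{d}"))
        ids.append(2 + d)
    ranks = list(_RANK_CHAIN) + ["strain", "no_rank"]
    while len(rows) < n_nodes:
        nid = len(rows) + 1
        parent = rng.choice(ids[1:] if len(ids) > 1 else ids)
        rows.append((nid, parent, rng.choice(ranks), f"n{nid}"))
        ids.append(nid)
    text = "".join(f"{t}\t{p}\t{r}\t{n}\n" for t, p, r, n in rows)
    return load_taxonomy(text)
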