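# Methods

This note documents the models and procedures implemented in
`rescue-rank`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic test data does and
does not demonstrate.

## Composite similarity score

A failed purification target is compared against BLAST hits (typically
PDB chains) on two axes.

**Sequence component.** `S_seq = pident / 100`, the BLAST percent
identity rescaled to [0, 1]. No length or bitscore correction is
applied; coverage and significance are handled by the pre-filter
instead (identity > 20 %, e-value < 10⁻³, coverage > 75 %, best 50 by
bitscore). The threshold comparisons are strict by default (a hit at
exactly 20 % identity is excluded); a `strict=False` flag makes them
inclusive. Ties within the 50-hit cap break on smaller e-value, then
lexicographic subject id, so filtering is deterministic.

**Taxonomic component.** Both organisms are placed on a rooted taxonomy
tree; the distance is the unique up-to-LCA-and-down path with
rank-dependent node costs:

| rank | cost |
|---|---|
| species / strain / unranked | 1 |
| genus | 2 |
| family | 3 |
| order | 4 |
| class | 5 |
| phylum | 6 |
| kingdom | 8 |
| domain | 10 |
| domain crossing (once per path) | 16 |

All costs are configurable through a flat `rank = cost` file. The
magnitudes encode one judgement: each step up the hierarchy is a larger
evolutionary jump, and crossing domains of life is the largest jump of
all (the surcharge is constrained to be at least the largest per-rank
cost). Then

```
S_taxa = 0.5                      at distance 0
         1 − distance/maxdistance at distance > 0
```

so the closest non-identical organisms score near 1, the most distant
score near 0, and the query's own organism sits at 0.5 *before* the
paralog penalty — same-organism hits are paralogs with an elevated risk
of divergent function, so their taxonomic component is halved (0.5 →
0.25 for an exact-organism hit).

**Node-counting convention.** The distance sums the rank cost of every
node on the path *excluding the lowest common ancestor* — equivalently,
each parent-child edge costs its child's rank penalty. This makes the
distance a true tree metric: `d(a,a) = 0`, `d(a,b) = d(b,a)` regardless
of endpoint ranks, adjacent nodes are one penalty apart, and the
triangle inequality holds. (Charging "all nodes except the start"
instead would break symmetry whenever the endpoints carry different
rank costs; the two conventions coincide for the usual leaf-vs-leaf
comparisons.)

**maxdistance.** Defined as the penalized diameter of the tree, computed
exactly over all leaf pairs for trees with ≤ 400 leaves and by a
deepest-leaf-per-domain candidate heuristic above that; a single-node
tree returns a floor of 1.0 so division is always defined. The diameter
guarantees `S_taxa ∈ [0, 1]` for in-tree pairs in exact mode; outputs
are clamped to [0, 1] regardless.

**Lineage fallback.** Organisms absent from the tree are resolved by
walking a caller-supplied lineage (immediate parent first) until an
ancestor is found; each hop subtracts `missing_lineage_decrement`
(default 0.05) from `S_taxa`, before clamping and before the paralog
halving. The decrement is deliberately small and proportional: a
one-step fallback is nearly free, a long climb costs real score.
Organisms with no resolvable lineage are excluded and logged rather
than scored.

**Combination.** `S_overall = w_seq·S_seq + w_taxa·S_taxa` with weights
constrained to sum to 1 (defaults 0.5/0.5). Ranking sorts descending on
`S_overall` with deterministic tie-breaks (higher `S_seq`, then subject
id), applies a user threshold, and truncates to a user limit.

## Literature mining

Articles are JATS XML. Parsing is two-stage: a strict parse first; on
failure, defects that leave the document complete (undeclared entities,
stray markup) are recovered with warnings, while truncated documents
(unfinished tags at end of input, or input not ending in `>`) are
rejected with an error carrying the article id. Batch processing
catches per-article errors, logs them, and continues — no malformed file
aborts a run. Entity resolution and network access are disabled during
parsing; namespaces are ignored when matching tags.

The methods section is located by case-insensitive substring search for
the keyword `method` over section titles (configurable, repeatable), so
"Methods", "Materials and Methods", "METHODS" and "Experimental
methods" all match. A matched section contributes its entire subtree;
nested matches inside an already-matched section are not double-counted.

Citation accessibility is classified into exactly one of four statuses
by precedence: no primary citation → not archived in PMC → archived but
no open license → accessible. Only accessible citations are mined.

## Agents

The extraction, summarization and optimization steps are specified as
agent tasks with typed output schemas, executed by a backend. The
shipped default is a deterministic rule backend; a remote model can be
plugged in by wrapping any prompt→text completion callable. Whatever
the backend, output failing schema validation is retried twice and then
surfaced as an agent failure — nonconforming output never flows
downstream. Prompt texts are versioned template files under
`src/rescue_rank/prompts/`, and the rule backend's vocabularies are
editable text files under `src/rescue_rank/lexicons/`.

The rule backend is grounded by construction:

* **extractor** — splits the methods text into sentences and keeps those
  containing at least one purification-lexicon term (column, resin,
  elution, imidazole, dialysis, …). The output is a subset of input
  sentences in original order; if nothing matches, the article is
  excluded with a logged error rather than summarized from nothing.
* **summarizer** — starts a new step at each sentence containing a
  step-boundary keyword (lysed, equilibrated, washed, eluted, dialyzed,
  size-exclusion, …); the matched text becomes the step label verbatim.
  Within a step: pH via a `pH <number>` pattern (implausible values
  outside [0, 14] are warned about and left unset, mirroring OCR-style
  artifacts like "pH 70" seen in real summaries); salt type as the
  first match from a priority-ordered salt lexicon; buffer composition
  as the verbatim span from the first to the last
  `number unit component` match; supplements as the additive-lexicon
  terms present, joined as a list. Text with no step keyword at all
  yields a single bare step with a warning.
* **optimizer** — wraps the protocol diff and attaches rule-templated
  recommendations. Confidence is high when ≥ 3 successful protocols
  support a difference, medium at 2, low at 1. Structural annotations
  add recommendations independent of any diff: transmembrane spans
  trigger a detergent recommendation, signal peptides a construct
  truncation recommendation, both labelled annotation-driven and low
  confidence. The revised protocol substitutes the consensus (modal,
  ties lexicographic) successful value into the failed steps.

## Protocol tables and diffing

Tables have exactly six columns — purification step, buffer name, buffer
composition, pH, salt type, buffer supplement — with absent cells
rendered as `None`. Validation rejects empty step labels and pH outside
[0, 14], naming the offending step and field.

Diffing aligns steps by category using a keyword lexicon
(lysis / capture / wash / elution / cleavage-dialysis / polish); the
alignment lexicon is an explicit design choice, since source protocols
align only implicitly. Within aligned categories the diff covers pH,
salt type, named-component concentrations parsed with a
`number + unit (mM, M, %, mg/ml, µM) + component` grammar, and
supplements present in successes but absent from the failed protocol.
A concentration difference is reported only when every successful value
differs from the failed one and units agree. Swapping failed and
successful inputs flips each difference's direction, which the tests
check explicitly.

## Pipeline

Stages run in a fixed order (parse → filter → score/rank → resolve
citations → mine → summarize → optimize → render) with a run ledger
recording `retained + excluded = input` at every stage and a per-article
outcome map. The optimizer stage runs only when a failed protocol is
provided and can be disabled without affecting upstream outputs. Under
the rule backend the whole pipeline is a pure function of its inputs:
re-runs produce byte-identical JSON reports. Citation resolution is
offline: an optional JSON file maps subject ids to citation metadata
and article files; without it, articles are consumed in rank order.
Live retrieval from structure/article archives is deliberately out of
scope — adapters can be built behind the same interfaces.

## Synthetic data

The fixture generator emits complete input bundles with ground-truth
manifests: trees of configurable shape (default 2 domains × depth 4 ×
branching 2, 63 nodes); hit tables where a controlled number of rows
violates each retrieval threshold (default 20 passing including one
paralog, 5 failures per threshold); articles with planted protocols
(default 3; successful protocols always elute at 500 mM imidazole and
include glycerol in lysis); and a failed protocol eluting at 250 mM
imidazole without glycerol, so one concentration and one supplement
difference exist by construction. Manifest distances are computed by an
independent brute-force path oracle (networkx breadth-first search,
summing node costs along the explicit path), and manifest scores by a
straight-line transcription of the three scoring formulas — neither
reuses the implementation under test. Sentence templates rotate per
seed so the summarizer is exercised on phrasing variety rather than a
single format.

What passing tests show: the scoring arithmetic, filtering rules, XML
fault tolerance, grounding and determinism hold on inputs with the
structure of real data. What they do not show: performance on real
article prose (fixture sentences are template-generated and far more
regular than published methods sections), real taxonomy dumps (the NCBI
tree is much deeper and uses many more rank names than the controlled
vocabulary), or the judgement quality of a remote-model backend, which
is intentionally untested here.

## Numerical and degenerate-input choices

* Score comparisons use exact floating arithmetic; no tolerance is
  applied internally. Clamping bounds `S_taxa` to [0, 1].
* Unknown rank strings map to the unranked cost with a warning; unknown
  components in concentration parsing are simply not diffed.
* Empty hit tables, zero surviving hits, zero accessible articles and
  missing failed protocols all produce complete (if short) reports, not
  errors; only structurally invalid configuration (missing tree or hit
  file, weights not summing to 1, cyclic trees) fails fast.
* Problem sizes in the test suite (trees ≤ 200 nodes for all-pairs
  oracle comparison over 20 seeds, a 100-article grounding corpus) were
  chosen to exercise every code path exhaustively at desk scale.

## Known limitations

* The rank-penalty magnitudes, the diameter definition of
  `maxdistance`, and the 0.05 fallback decrement are explicit package
  defaults, not community constants; conclusions sensitive to them
  should sweep the configuration.
* The rule-based summarizer extracts only what its lexicons name; novel
  additives or salts require editing the lexicon files.
* Step alignment is categorical, not positional: protocols with two
  wash steps at different stringencies are compared as one category.
* The heuristic `maxdistance` path (trees beyond the exact-leaf limit)
  can in principle undershoot the true diameter on adversarial
  topologies; scores remain bounded because `S_taxa` is clamped.
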