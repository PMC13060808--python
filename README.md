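# rescue-rank

Tools for rescuing failed recombinant-protein purifications by learning
from the literature of close homologs.

When a target protein expresses solubly but fails large-scale
purification, the standard bench workflow is: find similar proteins that
*have* been purified (usually via structures deposited in the PDB), pull
the purification protocols out of their primary citations, and compare
the critical parameters — buffers, pH, salt, imidazole, additives —
against the failed protocol. `rescue-rank` automates that workflow
offline: it ranks BLAST homologs by a composite sequence-plus-taxonomy
score, mines purification protocols out of full-text JATS XML, normalizes
them into a standardized six-column table, and diffs the failed protocol
against the successful ones to produce concrete, confidence-labelled
recommendations.

## The score

Candidate homologs come from a BLAST search, pre-filtered to percent
identity > 20 %, e-value < 10⁻³, query coverage > 75 %, and capped at the
best 50 hits by bitscore. Each surviving hit is scored:

```
S_seq     = pident / 100

S_taxa    = 0.5                            if distance = 0
            1 − distance / maxdistance     if distance > 0

S_overall = w_seq · S_seq + w_taxa · S_taxa        (defaults 0.5 / 0.5)
```

`distance` is the rank-penalized path length between the query and
subject organisms on a taxonomy tree: every node traversed charges a
cost that grows with its rank (species 1 … kingdom 8), and crossing
between domains of life adds a single large surcharge (16).
`maxdistance` is the penalized diameter of the tree, so `S_taxa` is
normalized to [0, 1]. Hits from the query's own organism are paralogs
and have `S_taxa` halved; organisms missing from the tree are resolved
by walking up their lineage, losing a small decrement per hop. Hits are
ranked by `S_overall`, thresholded, and truncated to a user limit.

## The mining pipeline

For each ranked homolog with an accessible primary citation, the
pipeline parses the article XML (tolerantly — recoverable defects become
warnings, truncated files are logged and skipped), locates the methods
section by the keyword `method` in section titles, extracts only the
purification-related sentences, and summarizes them into a table with
six columns: **purification step, buffer name, buffer composition, pH,
salt type, buffer supplement**. The extraction and summarization agents
are deterministic and grounded: every value they emit appears verbatim
in the source text. A remote language-model backend can be plugged in
behind the same schema-validated interface; outputs that fail validation
are retried and never propagated.

If a failed protocol is supplied, the optimizer aligns steps by category
(lysis / capture / wash / elution / cleavage / polish) and reports
parameter-level differences with confidence labels (high ≥ 3 supporting
protocols, medium 2, low 1), plus annotation-driven hazards (signal
peptides, transmembrane spans → detergent recommendations).

## Worked example

Everything runs offline against generated inputs with known ground
truth:

```
rescue-rank fixtures --out demo --seed 0
rescue-rank run --hits demo/hits.tsv --taxonomy demo/tree.tsv \
    --query demo/query.fasta --articles demo/articles \
    --citations demo/citations.json \
    --failed-protocol demo/failed_protocol.txt \
    --annotations demo/annotations.txt --out demo/report
```

prints the per-stage ledger:

```
report written to demo/report/
  parse_hits: 35/35 retained
  filter: 20/35 retained
  score_rank: 20/20 retained
  resolve_citations: 3/6 retained
  mine_articles: 3/3 retained
  optimize: 1/1 retained
```

35 synthetic BLAST rows are parsed; 15 were planted to violate one
retrieval threshold each, so 20 survive the filter. Three of the six
best-scoring subjects have accessible citations, all three articles mine
cleanly, and the optimizer runs against the failed protocol. The report
(`demo/report/report.md`) opens with the ranking:

```
| rank | subject | S_seq | S_taxa | S_overall |
|---|---|---|---|---|
| 1 | SBJ006_A | 0.771 | 0.786 | 0.778 |
| 2 | SBJ003_A | 0.528 | 0.643 | 0.585 |
| 3 | SBJ011_A | 0.322 | 0.786 | 0.554 |
```

— subject `SBJ006_A` has 77.1 % identity (`S_seq` 0.771) and a close
organism (`S_taxa` 0.786), averaging to `S_overall` 0.778. The
optimization section flags, among others, the planted elution
difference:

```
Adjust imidazole in the elution step from 250 mM toward the successful
range: 500 mM, 500 mM, 500 mM.   (confidence: high)
```

high confidence because all three mined protocols agree.

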