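# grnkit

Tooling for building and scoring three-node TF–gene–miRNA regulatory
motifs ("GRNs") in multi-condition expression studies:

- **Interaction catalog** (`grnkit.catalog`) — load an entity lexicon
  (official symbols, classes, aliases), normalize edge lists to official
  symbols, filter edges by evidence (TFBS Z ≥ 2.33, MEM p ≤ 0.05, CoMeTa
  score ≥ 4, all inclusive), and tag reciprocal TF⇋miRNA pairs as
  feedback vs. feed-forward edges.
- **Co-expression filter** (`grnkit.coexpression`) — quantile or
  log2-shift normalization, Pearson confirmation of edges on control
  samples (two-sided p ≤ 0.05, optional sign constraint), and
  per-condition expression summaries.
- **Motif builder** (`grnkit.motifs`) — enumerate every (TF, gene, miRNA)
  trio induced by the retained edges and classify it into exactly one of
  five classes (closed loop CL1, semi-closed CL2, common-gene G,
  common-TF TFC, common-miRNA MIR) with precedence CL1 > CL2 > G > TFC >
  MIR, so per-class counts always partition the total.
- **Disease association** (`grnkit.mining`) — dictionary-based whole-token
  mining of gene/TF symbols from an abstract corpus, and GRN filtering by
  the mined lists.
- **Integrity ranking** (`grnkit.integrity`) — the integrity score
  `N = (r_tf·e_tf)(r_mir·e_mir) + (r_mir·e_mir)(r_gene·e_gene) +
  (r_gene·e_gene)(r_tf·e_tf)` with default weights (1, 0.75, 0.5),
  regulatory fold change `RFC = N_MS / N_control` (RFC > 1 up, < 1 down),
  top-k up/down selection per motif type per contrast, and Venn-style
  overlap summaries across contrasts.
- **Enrichment** (`grnkit.enrichment`) — pathway assignment per GRN as the
  intersection of its members' pathway sets (miRNAs via a target-gene
  map), plus hypergeometric over-representation on GMT gene sets.
- **qPCR validation** (`grnkit.qpcr`) — 2^−ΔCt relative expression,
  Student's t group comparisons (pooled and per-condition), qPCR-based
  RFCs through the integrity score, and concordance accuracy of direction
  calls against array-based calls.
- **Synthetic data** (`grnkit.simulate`) — seed-deterministic generators
  for every input (network with planted motifs, paired gene/miRNA
  expression with planted fold changes, abstract corpus, pathway/GMT
  annotations, Ct tables), each emitting ground truth for testing.

## CLI

The `grn` command chains the pipeline stage by stage:

```sh
grn simulate --seed 1 --out-dir fixtures/
grn filter-interactions --edges fixtures/edges.tsv --lexicon fixtures/lexicon.tsv \
    --z 2.33 --mem-p 0.05 --cometa 4 -o filtered.tsv
grn coexpress --edges filtered.tsv --gene-expr fixtures/gene_expr.tsv \
    --mirna-expr fixtures/mirna_expr.tsv --samples fixtures/samples.tsv \
    --normalize none --p 0.05 -o coexpressed.tsv --summaries summaries.tsv
grn build-motifs --edges coexpressed.tsv -o grns.tsv --census census.json
grn mine --corpus fixtures/abstracts.txt --lexicon fixtures/lexicon.tsv -o assoc.tsv
grn filter-grns --grns grns.tsv --assoc assoc.tsv --mode any -o grns_ms.tsv
grn score --grns grns_ms.tsv --summaries summaries.tsv -o scores.tsv
grn rank --scores scores.tsv --k-up 10 --k-down 10 -o top.tsv
grn pathways --top grns_ms.tsv --gmt fixtures/pathways.gmt \
    --mir-targets fixtures/mir_targets.tsv -o grn_pathways.tsv
grn qpcr --ct fixtures/ct.tsv --grns grns_ms.tsv -o qpcr_stats.tsv --rfc-out qpcr_rfc.tsv
```

All inputs are plain TSV/GMT/text; `grn simulate` writes a complete,
internally consistent set with a `truth.json` ground-truth record.

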