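# genesetnet

Offline gene-set analytics over weighted interaction networks:

* **Corpus I/O** — GMT gene-set collections (set type encoded as a
  `type=P|A|G` description token), 2/3-column interaction and regulation
  edge TSVs, plain gene lists. Symbols are uppercased and trimmed at ingest.
* **Cohesion scoring** — each set's covered gene pairs and trios (edges and
  triangles of its induced subgraph) are tested against a hypergeometric
  sampling null over the background network; the score is the sum of the
  two −log10 upper tails (probabilities floored at 1e-320).
* **Size normalization** — a polynomial trend of log2(score) versus
  log2(size) is fitted corpus-wide (default degree 3) and removed, yielding
  a normalized score whose rank correlation with set size is ≈ 0.
* **Gene prioritization** — random-walk-with-restart weights on the set's
  confidence-weighted induced subgraph (default restart 0.7), multiplied by
  a logarithmic boost for genes recurring across many sets.
* **Enrichment** — hypergeometric upper-tail tests of a query list against
  the corpus with BH-FDR across tested sets and a two-stage filter chain
  (type/size pre-filters; similarity, overlap, cohesion, FDR post-filters).
* **Set-to-set networks** — undirected *m-type* edges from surprising
  member overlap (dual −log10 PMF / tail thresholds, defaults 5 and 10) and
  directed *r-type* edges from enriched cross-set regulation (PMF and tail
  < 0.05), with singleton/multi endpoint classification and GraphML/SIF
  export.
* **Synthetic data** — a seed-deterministic generator of corpora,
  scale-free-like interaction networks with planted cohesive modules, and
  regulation networks with planted cross-set regulation, so the whole suite
  runs without downloads.

## CLI

All subcommands write their outputs plus a `manifest.json` into `--out`;
identical configurations produce byte-identical outputs.

```sh
# generate a reference synthetic dataset (GMT + PPI + regulation + truth)
genesetnet simulate --seed 7 --out sim/

# cohesion scores, then fit the size normalizer and add normalized scores
genesetnet score --gmt sim/corpus.gmt --ppi sim/ppi.tsv --out scored/
genesetnet normalize --scores scored/cohesion.csv --degree 3 --out normed/

# rank genes inside one set
genesetnet rank --gmt sim/corpus.gmt --ppi sim/ppi.tsv --set-id SYN00003 \
    --restart 0.7 --out ranks/

# enrich a query gene list
genesetnet enrich --gmt sim/corpus.gmt --query genes.txt \
    --scores normed/cohesion.csv --fdr 0.05 --similarity 0.1 --out enr/

# build m-type / r-type set-to-set networks
genesetnet net --gmt sim/corpus.gmt --regulation sim/regulation.tsv \
    --format graphml --out nets/

# corpus summary counts
genesetnet summary --gmt sim/corpus.gmt --scores normed/cohesion.csv --out stats/
```

`genesetnet <subcommand> --help` lists every threshold flag.

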