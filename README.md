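# colocnet

Network colocalization of gene sets implicated by two independent
association studies (e.g., common-variant and rare-variant gene-level
results) on a molecular interaction network.

The pipeline:

1. **Seed selection** — gene-level p-value tables are thresholded into seed
   sets: common-variant genes at `p < 2.6e-6`; rare-variant genes by
   Benjamini–Hochberg FDR < 0.25 across burden/SKAT-O/SKAT tests (lenient)
   or per-test Bonferroni at 0.05 (stringent), union over tests. Seeds are
   intersected with the network (at least 6 required).
2. **Propagation** — random walk with restart (`alpha = 0.5`,
   column-stochastic transition `W = A D^-1`, uniform seed mass summing
   to 1), iterated to a `1e-10` fixed point; a dense linear-solve oracle
   (`propagate_exact`) backs the iterative implementation.
3. **NPS scoring** — per-gene network proximity score: the z-score of the
   log observed heat against 1,000 propagations of degree-matched random
   seed sets (genes binned by degree, ≥ 10 per bin). Scores from the two
   sources combine as an elementwise product. Seed sets larger than 500
   genes go through a weighted-subsampling consensus (100 subsamples
   weighted by −log10 p, per-gene 75th percentile).
4. **Colocalization** — genes with `nps_combined > 3`, `nps_common > 1.5`
   and `nps_rare > 1.5` form the colocalized network. Its size and mean
   combined score are tested against 10,000 label permutations (genes
   seeded in both inputs are permuted within their own stratum); one-sided
   Z-test p-values per the original procedure, plus exact rank-based
   permutation p-values.
5. **Enrichment** — upper-tail hypergeometric tests against GMT catalogs,
   and a tissue differential-expression mode (per-label Welch t-test vs all
   other labels, Bonferroni p < 0.05, |logFC| ≥ 0.58).

A fully seeded synthetic-data module (`colocnet.synth`) generates
heavy-tailed networks with a planted dense module, score tables whose
planted genes deterministically pass the selection thresholds, annotation
catalogs and expression matrices with planted differential expression, so
the entire pipeline is testable offline.

## CLI

Each stage is a subcommand; all take `--config` (YAML), `--seed`,
`--out-dir`, `--log-level`:

```bash
colocnet simulate --spec spec.yaml --out-dir fixture/ --seed 1
colocnet seeds --common-table fixture/scores_common.tsv \
               --rare-table fixture/scores_rare.tsv \
               --network fixture/network.tsv --out-dir out/
colocnet propagate --network fixture/network.tsv --seeds out/seeds_common.txt
colocnet nps --network fixture/network.tsv \
             --seeds-common out/seeds_common.txt --seeds-rare out/seeds_rare.txt \
             --null-reps 1000 --seed 7 --out-dir out/
colocnet coloc --nps-table out/nps_table.tsv --network fixture/network.tsv \
               --permutations 10000 --seed 7 --out-dir out/
colocnet enrich --genes out/selected_genes.txt --catalog fixture/catalog.gmt
colocnet run --config pipeline.yaml --out-dir out/ --seed 7   # all stages
```

`run` expects a YAML config naming `network`, `common_scores`,
`rare_scores`, optional `catalog`, and any of `alpha`, `null_reps`,
`n_permutations`, `thresholds {combined_min, common_min, rare_min}`,
`rare_mode`, `null_excludes_seeds`. It writes all stage artifacts plus a
`manifest.json` recording parameters, RNG seeds and software version;
reruns with the same config are byte-identical.

## Layout

```
src/colocnet/
  core.py         domain types + TSV/SIF/GMT readers and writers
  seeds.py        BH FDR, threshold rules, network mapping
  propagation.py  RWR fixed point + dense oracle
  nps.py          degree binning, null ensembles, NPS, consensus
  coloc.py        network extraction, permutation test, full pipeline
  enrichment.py   hypergeometric tests, DEG calling
  synth.py        seeded synthetic data with ground truth
  cli.py          click CLI
```
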