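# mitochapnet

Pan-cancer chaperone–client co-expression network analysis as a tested,
reusable pipeline:

1. **coexpression** — per-cohort Spearman correlation between a chaperone
   panel and a client panel, with Bonferroni-corrected significance zeroing
   and a positivity filter (negative correlations are discarded).
2. **pancancer** — cell-wise median of the filtered per-cohort matrices
   (zeros included), plus degree summaries. With an odd cohort count a
   pan-cancer weight is positive exactly when the pair is significant in a
   strict majority of cohorts.
3. **community** — weighted bipartite network construction and community
   detection by minimizing the two-level map equation L (bits), with an
   exhaustive set-partition oracle for small graphs.
4. **nulltest** — a two-stage permutation null: curveball shuffling of the
   binary interaction matrix (row/column sums preserved exactly), uniform
   redistribution of the observed weights over the shuffled one-cells,
   re-optimized detection per replicate, and a counting p-value.
5. **downstream** — hierarchical clustering of interaction profiles
   (Newick export) and pairwise client-set partitions (both / only-A /
   only-B / neither).
6. **synthetic** — multi-cohort expression generators and planted weighted
   bipartite networks with ground-truth module labels, so the whole pipeline
   is testable without any external download.

## CLI

Each stage is a subcommand; `run-all` chains them and writes a manifest with
per-stage output digests:

```sh
# synthetic bundle -> full pipeline
cat > cfg.yaml <<EOF
synthetic:
  n_cohorts: 13
  n_samples_per_cohort: 200
  n_chaperones: 15
  n_clients: 90
  n_modules: 3
n_sim: 1000
n_restarts: 8
EOF
mitochapnet run-all --config cfg.yaml --seed 1 --out results/

# or stage by stage
mitochapnet simulate --seed 1 --out data/
mitochapnet correlate --expr data/cohort01.tsv \
    --chaperones data/chaperones.txt --clients data/clients.txt \
    --out corr01.tsv
mitochapnet aggregate corr*.tsv --out pancancer.tsv
mitochapnet detect --pancancer-tsv pancancer.tsv --seed 1 --out partition.json
mitochapnet nulltest --pancancer-tsv pancancer.tsv --n-sim 1000 --seed 1 \
    --out null.json
mitochapnet cluster --matrix-tsv pancancer.tsv --axis chaperone_by_client \
    --out dendrogram.nwk
mitochapnet venn --pancancer-tsv pancancer.tsv --chap-a CHAP001 \
    --chap-b CHAP002 --out venn.json
```

Real cohort data can be supplied as TSV expression tables (first column gene
ID, header row of sample IDs) plus one-gene-per-line panel files via
`cohort_tsvs` / `chaperone_panel` / `client_panel` in the config.

All defaults match the study settings: alpha 0.05 with Bonferroni correction
over all chaperone×client pairs, median over cohorts, 1000 randomizations,
curveball trades = 5 × number of chaperone rows. The p-value direction
defaults to counting random networks whose re-optimized partition is at
least as good (L_sim ≤ L_obs); `--direction as_printed` counts L_sim > L_obs
instead.

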