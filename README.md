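# dietshift

Analysis toolkit for paired gut-microbiome diet-intervention studies:

* **data_model** — abundance tables (TSV / BIOM 2.x) with ranked lineages,
  rank aggregation with `_u` pooling of unclassified taxa, the low-abundance
  prevalence filter (retain taxa at ≥ 0.2% relative abundance in ≥ 15
  samples), Bacteroidetes:Firmicutes ratios, pairing manifests, newick trees.
* **distances** — root Jensen–Shannon divergence (log base 2), Bray–Curtis,
  and generalized UniFrac (branch-incidence compilation of the tree, α
  configurable, default 0.5).
* **typing** — enterotyping (genus-level JSD + deterministic PAM + k by
  Calinski–Harabasz on a PCoA embedding) and *permatyping*: bootstrap
  re-clustering with maximal-overlap cluster matching; samples whose
  assignment is stable in < 80% of replicates are left unclassified.
  Driver-taxon ranking and permatype transition analysis (Fisher's exact
  test) included.
* **response** — per-subject paired dissimilarity, responder /
  non-responder discovery (PAM over the scalar dissimilarities, k by mean
  silhouette; the lower-mean cluster is "non_responder"), a Mann–Whitney +
  Benjamini–Hochberg baseline marker screen, and a repeated-split
  random-forest evaluation of baseline predictability (mean ROC AUC).
* **permanova_power** — PERMANOVA (pseudo-F, R², permutation p, ω²) with a
  subject-paired permutation scheme, plus Monte-Carlo power and
  sample-size estimation for two-group designs calibrated to a published
  dissimilarity distribution and ω² effect size.
* **stats** — Shannon, bias-corrected Chao1, rarefaction, CLR transform,
  paired CLR + Wilcoxon signed-rank + BH testing, co-occurrence
  "cooperatives" (connected components with > 2 members) and their
  abundances.
* **synthetic_data** — paired-cohort generator with planted community
  types, bimodal paired-shift magnitudes (calibrated per subject by
  bisection on the generalized UniFrac distance), group-specific
  Bacteroidetes:Firmicutes ratios and a recorded truth object for
  recovery tests.
* **pipeline** / **cli** — end-to-end orchestration with deterministic,
  seed-derived stage randomness and a reproducible summary JSON.

## Command line

```sh
# generate a synthetic paired cohort (tables, tree, pairing manifest, truth)
dietshift synth cohort --seed 1 --out cohort/

# enterotype / permatype a table
dietshift typing fit --table cohort/table.tsv --lineage-sep '|' --out labels.tsv
dietshift typing permatype --table cohort/table.tsv --lineage-sep '|' \
    --bootstrap 100 --threshold 0.8 --seed 1 --out permatypes.tsv

# PERMANOVA power and minimal sample size
dietshift power estimate --mean 0.52 --sd 0.06 --omega2 0.006 --n 70 \
    --reps 500 --perms 200 --seed 1
dietshift power size --target 0.8 --grid 30:110:10 --seed 1

# full pipeline from a JSON config
dietshift pipeline run --config run.json
```

A pipeline config is a JSON object with at least `table`, `pairs` and
`tree` paths; see `dietshift.pipeline.RunConfig` for all options and
defaults.

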