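# coexmap

Co-expression module analysis for treatment × gene log2 fold-change
matrices: unsigned module discovery (soft-power adjacency, topological
overlap, tree cut, eigengene-correlation merging), eigengene scoring,
projection of external or targeted-panel data onto frozen modules,
cross-dataset module preservation, hypergeometric pathway / TF-regulon
enrichment with a surrogate TF activity score, seed-module correlation
clustering, and donor-trait association — plus seeded synthetic-data
generators that make every stage testable without any external download.

## Library overview

| module                | contents |
|-----------------------|----------|
| `coexmap.types`       | `FoldChangeMatrix`, `Module`/`ModuleSet`, `EigengeneMatrix`, `ProjectedScores`, `TraitMatrix`, … |
| `coexmap.io`          | TSV/CSV grids, GMT gene sets, regulon tables, ortholog maps, trait tables, versioned module JSON |
| `coexmap.discovery`   | `filter_genes`, `select_soft_power`, `build_network`, `detect_modules`, `merge_and_label`, `build_modules` |
| `coexmap.eigengenes`  | `standardize_reference`, `compute_module_scores`, `compute_gene_stats`, `flag_perturbations` |
| `coexmap.project`     | `project_external` (zero-fill for absent genes), `coverage_report`, `panel_coreg_quality` |
| `coexmap.preserve`    | `map_orthologs`, `compute_preservation` (permutation Z-summary / medianRank), `classify_preservation` |
| `coexmap.enrich`      | `ora_module`, `enrich_modules`, `tf_enrichment`, `tf_activity` (surrogate NES) |
| `coexmap.cluster`     | `condition_similarity`, `impute_conditions` (iterative SVD), `expand_seed_modules`, `cluster_modules` (Ward D2 on 1−cor) |
| `coexmap.traits`      | `compute_summary_scores` (cluster means, avgAbsEG), `associate_traits` (Cohen's d + covariate-adjusted logistic regression, BH) |
| `coexmap.simulate`    | `generate_reference`, `generate_panel_study`, `generate_donor_cohort`, `shuffle_gene_labels` |

Typical flow:

```python
from coexmap import discovery, eigengenes, project, simulate

fc, truth = simulate.generate_reference(seed=1)       # or io.read_foldchange_table(...)
modules, report = discovery.build_modules(fc)         # filter -> beta -> TOM -> cut -> merge
zfc = eigengenes.standardize_reference(fc.subset_genes(modules.universe))
egs, _ = eigengenes.compute_module_scores(modules, zfc)
scores = project.project_external(modules, external_fc)  # frozen-module scoring
```

## CLI

The console script `coexmap` wraps each stage:

```bash
coexmap simulate reference --n-genes 2000 --seed 1 --out-dir scratch/ref
coexmap build    --fc scratch/ref/fc.tsv --adjp scratch/ref/adjp.tsv --out modules.json
coexmap score    --fc scratch/ref/fc.tsv --modules modules.json --out egs.tsv
coexmap project  --modules modules.json --fc external_fc.tsv --out scores.tsv
coexmap preserve --ref-fc scratch/ref/fc.tsv --test-fc other_fc.tsv \
                 --modules modules.json --n-perm 200 --seed 1 --out preservation.tsv
coexmap enrich   --modules modules.json --gmt pathways.gmt --regulons regulons.tsv
coexmap tf-activity --regulons regulons.tsv --fc external_fc.tsv --modules modules.json
coexmap correlate --egs egs.tsv --method pearson
coexmap cluster  --egs egs.tsv --seeds seeds.txt --r-min 0.7 --k 8 --out clusters.tsv
coexmap associate --scores scores.tsv --clusters clusters.tsv --traits traits.tsv \
                  --time "24 hr" --level cluster --out associations.tsv
```

File formats: fold-change and adjusted-p grids are TSV/CSV with a header
row (conditions × genes by default; `NA` = missing); gene sets are GMT;
regulons a 4-column TSV (tf, target, mode `+1/-1` or `A/I`, confidence
`A–E`); ortholog maps 2-column TSV; traits a donor × trait TSV of
`{0,1,NA}`. Condition ids of the form `<compound>_<dose>_<time>` are parsed
into metadata automatically.

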