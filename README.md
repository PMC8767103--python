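# repnet

Analysis of tumor-infiltrating B-cell-receptor (BCR) repertoires from bulk
RNA-seq clonotype tables.

Bulk RNA-seq of tumor tissue captures a thin but informative slice of the
infiltrating B-cell compartment: reads covering the rearranged
immunoglobulin heavy (IGH), kappa (IGK) and lambda (IGL) loci can be
extracted and assembled into per-sample clonotype tables (chain, V gene,
J gene, CDR3 nucleotide sequence, read count). `repnet` turns such tables —
or the output of its own ground-truth simulator — into repertoire-level
features and downstream statistics, for researchers studying B-cell
involvement in the tumor microenvironment.

## What it computes

**Clones and networks.** Reads are grouped into clones when they share the
same V and J gene, the same CDR3 length, and at least 90% CDR3 nucleotide
identity. Equivalently, each sample × chain becomes a similarity network:
vertices are unique clonotypes sized by read count, edges join
90%-identical clonotypes, and clones are the connected components
(single-linkage), so somatic-hypermutation lineages appear as clusters.

**Repertoire features**, per sample and chain:

- *expression* — chain reads / total sequenced reads;
- *Shannon entropy* `H = −Σᵢ pᵢ log₂ pᵢ` over read-weighted clone
  proportions, from 0 (one clone) to log₂N (uniform);
- *Pielou evenness* `J = H / log₂ N` in [0, 1];
- *vertex Gini index* — inequality of clonotype read counts (clonal
  expansion);
- *cluster Gini index* — inequality of vertices per cluster (clonal
  diversification).

A downsampling control re-estimates both Gini indexes on 10 random draws of
500 reads per chain, excluding samples below that depth in any chain.

**Downstream stages.** V-gene usage matrices (percent of clones per germline
V gene, samples with ≥ 100 clones) with PCA, k-means cluster discovery,
elastic-net marker-gene selection (α grid 0.1–0.9, 5-fold CV) and
complete-linkage hierarchical ordering; association scans of features
against clinical covariates (Spearman for continuous, Wilcoxon rank-sum
with log₂ mean-ratio for categorical, Benjamini–Hochberg within tumor
type); and Cox proportional-hazards models per feature adjusted for age,
sex and stage (Efron ties, ≥ 40 events per tumor type, FDR < 0.1), with
Kaplan–Meier median-split summaries.

**Synthetic cohorts.** `repnet.synthetic` generates cohorts with known
truth — Dirichlet clone-abundance skew, star-shaped SHM lineages capped at
10% divergence, per-group V-gene usage shifts, proportional-hazards
survival with a chosen coefficient — so clone calling, marker selection and
hazard estimation can all be scored against ground truth.

## Worked example

```python
from repnet.synthetic import SyntheticConfig, simulate_cohort
from repnet.diversity import feature_table

cohort = simulate_cohort(SyntheticConfig(
    n_samples_per_group=3, n_adjacent_per_group=1, seed=42))
table = feature_table(cohort.records_by_sample, cohort.manifest)
print(table.head(6).round(4).to_string(index=False))
```

```
       sample_id tumor_type chain  n_reads  expression  n_clones  entropy_H  evenness_J  vertex_gini  cluster_gini
TCGA-S0-0001-01A       GRPA   IGH     2548      0.0012        90     5.4641      0.8417       0.6731        0.2569
TCGA-S0-0001-01A       GRPA   IGK     1138      0.0006       100     5.7041      0.8585       0.6422        0.2730
TCGA-S0-0001-01A       GRPA   IGL     2327      0.0011       124     6.0460      0.8694       0.6430        0.2789
TCGA-S0-0001-11A       GRPA   IGH     1286      0.0009       159     6.8131      0.9317       0.5301        0.2523
TCGA-S0-0001-11A       GRPA   IGK     2695      0.0019       184     6.9702      0.9264       0.5820        0.2625
TCGA-S0-0001-11A       GRPA   IGL     2242      0.0016       181     6.9812      0.9308       0.5594        0.2625
```

The `-01A` barcode is the participant's primary tumor, `-11A` the adjacent
non-tumor tissue. The tumor sample is generated with a more skewed clone
abundance law, and the features show it: lower entropy and evenness, higher
vertex Gini (more clonal expansion) than the adjacent sample.

The same pipeline runs from the shell:

```bash
repnet simulate --seed 42 --n-per-group 3 --n-adjacent 1 --out synth/
repnet ingest --clones synth/clones --manifest synth/manifest.tsv \
              --clinical synth/clinical.tsv --out store/
repnet features --store store/ --out features.tsv
repnet survival --features features.tsv --clinical synth/clinical.tsv \
                --min-events 40 --fdr 0.1 --out surv.tsv
```

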