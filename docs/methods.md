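# Methods

This note records the model, the parameter choices and the numerical
conventions behind `repnet`, and what its synthetic benchmarks do and do
not establish about real data.

## Clone definition and similarity networks

A clonotype is the triple (V gene, J gene, CDR3 nucleotide sequence); reads
with identical triples are aggregated into one vertex sized by read count.
Two vertices are connected when they share V gene, J gene and CDR3 length
and their CDR3s agree at ≥ 90% of positions. Clones are the connected
components of this graph — single-linkage clustering — so the clone
partition used by the diversity statistics and the cluster structure used
by the network statistics are the same objects by construction.

Conventions worth stating:

- Identity is evaluated exactly over the integers (`matches·10 ≥ 9·L`),
  never through floating point, and only within equal-length bins; the
  public `cdr3_identity` returns an exact `Fraction`.
- Identity is computed over the CDR3 only. Bulk RNA-seq extraction yields
  the CDR3 reliably but not the full variable region, and the clone rule
  keys on CDR3 length, so the CDR3 is the natural clonotype identity.
- The vertex key includes V and J gene: identical CDR3s on different genes
  are distinct vertices and can never be joined.
- Pairwise comparison is confined to (V, J, length) bins, keeping the
  worst-case quadratic cost local to a bin.

## Diversity and inequality statistics

Clone proportions `p_i` are read-weighted (clones are groups of reads, and
`p_i` is the proportion of the chain's reads in clone i). Shannon entropy
uses base 2 throughout; Pielou evenness `J = H/log₂N` is reported as
missing for single-clone repertoires (0/0 is not defined, and such samples
are excluded from downstream summaries rather than zero-filled).

The Gini index uses the population (uncorrected) estimator
`G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄)`, computed via the sorted O(n log n) identity. It
is bounded in [0, 1) and returns exactly 0 for a single value or equal
values; the sample-corrected variant was rejected because it can exceed 1,
breaking the interpretation of the index as a [0, 1] inequality scale.
Empty networks yield missing values, not errors: a chain with no reads is
an observation, not a fault.

## Downsampling control

Gini indexes respond to sequencing depth, so each sample is re-analysed on
10 random subsamples of 500 reads per chain, drawn *without replacement*
from the read-level expansion, and the per-chain means are reported.
Without-replacement sampling is chosen because with-replacement draws
distort vertex-size distributions exactly in the shallow samples the
control exists to protect. A sample qualifies only when all three chains
hold ≥ 500 reads — exclusion is per sample, not per chain, so the retained
set is identical across chains. Randomness comes from one master seed with
per-sample, per-repetition substreams (seed, CRC32 of the sample id,
repetition index), so a sample's downsampled values do not depend on which
other samples are in the cohort.

## V-gene usage stage

Usage is the percent of a sample's *clones* (not reads) using each V gene,
so clonal expansion cannot inflate a gene; samples with fewer than 100
clones are excluded as too noisy for stable percentages. PCA centers
columns but does not scale to unit variance — columns already share the
percent scale and scaling would inflate rare genes; component signs are
fixed by making each loading's largest-magnitude entry positive. k-means
(k = 2 by default, 10 restarts) runs on the PC1–PC2 scores, the space in
which sample clusters are identified; labels are canonicalised by
decreasing cluster size with size ties broken by centroid coordinates, so
the labelling depends only on the fitted partition. Marker selection is an
elastic-net logistic regression over a mixing-parameter grid 0.1–0.9; the
mixing parameter and regularization strength are chosen jointly by minimum
mean cross-validated deviance over 5 stratified folds, with predictors
standardized internally and selection reported on original gene names.
Heatmap ordering uses complete-linkage Euclidean hierarchical clustering on
rows and columns (the common default of the plotting stacks this output
feeds).

## Association and survival statistics

Continuous covariates use Spearman correlation with average ranks; for
n ≤ 8 complete pairs the two-sided p is the exact permutation tail over all
n! pairings (matching R's exact small-sample behaviour), otherwise the
asymptotic approximation. Categorical covariates use the two-sided Wilcoxon
rank-sum test (tie-corrected; exact for small untied samples) plus
`log₂(mean A / mean B)` oriented as declared in the covariate spec (tumor
over adjacent for the tissue contrast). Benjamini–Hochberg adjustment is
applied within one tumor type across all chain × feature tests of one
covariate — the narrowest family consistent with per-tumor-type reporting.
Tumor types with fewer than 10 adjacent samples are flagged insufficient in
the tissue contrast (the minimum applies to the adjacent group only);
flagged rows are retained with missing statistics rather than dropped.

Survival models enter each feature as a continuous term in a Cox
proportional-hazards fit adjusted for age (continuous), sex (binary,
dropped automatically in single-sex subsets) and stage (binary early I–II /
late III–IV, consistent with the association stage), with Efron tie
handling and complete-case exclusion. Tumor types need ≥ 40 events (≈ 10
per predictor). The Kaplan–Meier median split (ties to the low group) is
presentation only; its annotated p-values are the BH-adjusted Cox p-values,
not log-rank tests. Non-convergent or degenerate fits return flagged
missing results with a diagnostic message.

## Synthetic cohort generator

The generator emulates the data structure the pipeline assumes, with
defaults chosen as plausible for moderately infiltrated solid-tumor
RNA-seq repertoires:

| parameter | default | meaning |
|---|---|---|
| clones per sample | 120–200 (uniform) | richness before depth thinning |
| clonality α | 0.3 tumor / 1.0 adjacent | symmetric-Dirichlet abundance concentration; smaller = more clonal |
| depth per chain | 1000–3000 reads | BCR-aligned reads per chain |
| SHM rate | 0.02 per base | substitutions per variant, capped at ⌊0.1·L⌋ |
| lineage size | 1 + Poisson(1) | clonotype variants per clone |
| CDR3 length | 15–45 nt, codon multiples | uniform bases, no junctional realism |
| total-reads multiplier | 200–500× | manifest sequencing depth (expression ≈ 0.2–0.5%) |
| censoring fraction | 0.3 | administrative censoring quantile |

Lineages are star-shaped around a founder that always retains at least one
read, and every variant stays within ⌊0.1·L⌋ substitutions of the founder;
this guarantees the 90% single-linkage rule reconnects each lineage through
its founder, making exact lineage recovery a clean correctness test rather
than a statistical one. V/J names come from a bundled list of real human
germline genes; per-group usage bias adds a configured number of
percentage points to each biased gene and removes the mass proportionally
from the rest. Survival times are exponential with log-hazard linear in a
chosen true feature (computed from the generator's own clone table), with
administrative censoring at the empirical quantile that realises the target
censoring fraction.

A second, feature-level generator (`simulate_feature_cohort`) draws the
feature table and clinical covariates directly from plausible
distributions, bypassing sequence generation. It exists for error-
calibration studies, where hundreds of independent cohorts are scanned and
only the statistics' behaviour under the null is at stake; sequence-level
realism would add cost without changing what those studies measure.

**What passing tests do not show.** CDR3s are uniform random nucleotides
with no V(D)J junctional structure, lineages are stars rather than trees,
chains are generated independently (no paired-chain structure, as in real
bulk data), and clinical covariates are independent of the repertoire
except through the planted hazard. Recovery and calibration results on
these cohorts validate the machinery, not biological claims; conclusions
about real tumors require real cohorts at full scale.

## Problem sizes in the test suite

The bundled benchmarks run at desk scale: brute-force clustering oracles up
to ~200 records × 100 repertoires, Gini oracles on 1000 random vectors,
Cox recovery over 100 cohorts of n = 300 (β = log 2, 30% censoring,
requiring ≤ 15% mean bias and 90–98% CI coverage), elastic-net marker
recovery over 20 seeded cohorts of 120 samples (5 genes shifted by 10
usage points; mean sensitivity ≥ 0.8), and 200-cohort null calibration of
both scans against their nominal FDR levels. These sizes were chosen so
the entire suite completes in a few minutes on one CPU while keeping every
statistical check adequately powered.

## Known limitations

- Single-linkage clone calling can chain distinct true lineages through
  intermediate sequences in very dense repertoires; the 10%-divergence
  generator avoids this by construction, real data need not.
- Stage enters all models as a binary early/late contrast; ordinal or
  categorical encodings are not offered.
- The elastic-net stage assumes a binary cluster contrast; multi-cluster
  marker selection is out of scope.
- No isotype/subclass information, no paired heavy–light chain analysis,
  and no SHM phylogeny reconstruction — none of these are recoverable from
  bulk short-read clonotype tables.
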