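"""Synthetic BCR-repertoire cohorts with known ground truth.

The generator emulates the structure the analysis stages assume: per-sample
heavy/kappa/lambda clonotype tables with a skewable clone-abundance law
(symmetric Dirichlet; small concentration = clonal, large = even),
somatic-hypermutation-style lineages of near-identical CDR3s around a
founder (star topology, capped at 10% divergence so single-linkage
clustering provably recovers the lineage), configurable per-group V-gene
usage biases, TCGA-style barcodes, and clinical covariates whose survival
times follow an exponential proportional-hazards law with a known
coefficient on a chosen true repertoire feature.

No biological V(D)J recombination realism is claimed: CDR3s are uniform
over {A,C,G,T} at codon-multiple lengths and lineages are star-shaped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._genes import J_POOLS, V_POOLS
from .errors import ConfigError
from .io import (
    IG_CHAINS,
    ClonotypeRecord,
    MIXCR_DIALECT,
    SampleManifestEntry,
    write_clonotype_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SurvivalSpec:
    """Proportional-hazards outcome generation tied to a true feature."""

    baseline_hazard: float = 1.0 / 1500.0   # events per day
    beta: float = 0.0                       # log-hazard per unit of feature
    feature: str = "entropy_H"              # computed from true clone counts
    chain: str = "IGH"
    censoring_fraction: float = 0.3


@dataclass(frozen=True)
class GroupSpec:
    """Per-group overrides of the cohort-wide generation parameters."""

    clonality: float | None = None
    v_gene_bias: tuple[tuple[str, ...], float] | None = None  # (genes, pp each)
    subtype: str | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples_per_group: int = 30
    groups: Mapping[str, GroupSpec] = field(
        default_factory=lambda: {"GRPA": GroupSpec(), "GRPB": GroupSpec()}
    )
    n_adjacent_per_group: int = 0
    clones_per_sample: tuple[int, int] = (120, 200)
    clonality: float = 0.3            # Dirichlet concentration; lower = clonal
    adjacent_clonality: float = 1.0   # adjacent tissue: less clonal
    shm_rate: float = 0.02            # per-base substitution probability
    lineage_mean: float = 2.0         # mean clonotype variants per clone
    cdr3_codons: tuple[int, int] = (5, 15)    # CDR3 length = 3 x codons
    depth_per_chain: tuple[int, int] = (1000, 3000)
    total_reads_multiplier: tuple[int, int] = (200, 500)
    survival: SurvivalSpec = SurvivalSpec()
    seed: int = 0

    def validate(self) -> None:
        if self.shm_rate == 0 and self.lineage_mean > 1:
            raise ConfigError(
                "distinct lineage variants require shm_rate > 0"
            )
        if not (0 <= self.shm_rate <= 1):
            raise ConfigError("shm_rate must be a probability")
        if self.cdr3_codons[0] * 3 < 6:
            raise ConfigError("CDR3 length must be at least 6 nt")
        if not (0 <= self.survival.censoring_fraction < 1):
            raise ConfigError("censoring_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every recovery test."""

    clonality: dict[str, float]                       # sample_id -> alpha used
    biased_genes: dict[str, tuple[str, ...]]          # group -> gene set
    beta: float
    survival_feature: str
    survival_chain: str
    lineages: pd.DataFrame    # sample_id, chain, clone_id, v_gene, j_gene, cdr3_nt, reads
    clones: pd.DataFrame      # sample_id, chain, clone_id, v_gene, j_gene, reads
    features: pd.DataFrame    # sample_id, chain, entropy_H, evenness_J, vertex_gini, cluster_gini


@dataclass
class SyntheticCohort:
    records_by_sample: dict[str, list[ClonotypeRecord]]
    manifest: list[SampleManifestEntry]
    clinical: pd.DataFrame
    truth: SyntheticTruth


def _base_usage_weights(pool_size: int) -> np.ndarray:
    # fixed, smoothly decreasing usage profile: a few common genes, a long
    # tail of rare ones
    w = np.exp(-np.arange(pool_size) / 8.0) + 0.02
    return w / w.sum()


def _biased_weights(
    genes: Sequence[str], bias: tuple[tuple[str, ...], float] | None
) -> np.ndarray:
    p = _base_usage_weights(len(genes))
    if bias is None:
        return p
    bias_genes, shift_pp = bias
    idx = [genes.index(g) for g in bias_genes if g in genes]
    if not idx:
        return p
    add = shift_pp / 100.0
    p = p.copy()
    others = np.setdiff1d(np.arange(len(genes)), idx)
    total_added = add * len(idx)
    if p[others].sum() <= total_added:
        raise ConfigError("v_gene_bias shift exceeds available usage mass")
    p[others] *= (p[others].sum() - total_added) / p[others].sum()
    p[idx] += add
    return p / p.sum()


def _mutate(founder: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k substitutions at distinct positions, each to a different base."""
    seq = founder.copy()
    pos = rng.choice(seq.size, size=k, replace=False)
    for p in pos:
        choices = _BASES[_BASES != seq[p]]
        seq[p] = rng.choice(choices)
    return seq


def simulate_repertoire(
    cfg: SyntheticConfig,
    sample_id: str,
    chain: str,
    rng: np.random.Generator,
    clonality: float | None = None,
    v_gene_bias: tuple[tuple[str, ...], float] | None = None,
) -> tuple[list[ClonotypeRecord], list[dict]]:
    """One sample x chain repertoire plus its lineage truth rows.

    Clone abundances are symmetric-Dirichlet; each clone has one founder
    CDR3 and star-shaped variant lineage whose members stay within
    floor(0.1 L) substitutions of the founder, so the 90%-identity
    single-linkage rule reconnects the lineage exactly (the founder always
    receives at least one read).
    """
    cfg.validate()
    alpha = cfg.clonality if clonality is None else clonality
    genes = list(V_POOLS[chain])
    j_pool = list(J_POOLS[chain])
    v_probs = _biased_weights(genes, v_gene_bias)

    n_clones = int(rng.integers(cfg.clones_per_sample[0], cfg.clones_per_sample[1] + 1))
    abundances = rng.dirichlet(np.full(n_clones, alpha))
    depth = int(rng.integers(cfg.depth_per_chain[0], cfg.depth_per_chain[1] + 1))
    clone_reads = rng.multinomial(depth, abundances)

    records: list[ClonotypeRecord] = []
    truth_rows: list[dict] = []
    for clone_id, reads in enumerate(clone_reads):
        if reads == 0:
            continue
        codons = int(rng.integers(cfg.cdr3_codons[0], cfg.cdr3_codons[1] + 1))
        L = 3 * codons
        cap = max(1, L // 10)
        founder = rng.choice(_BASES, size=L)
        v_gene = genes[rng.choice(len(genes), p=v_probs)]
        j_gene = j_pool[int(rng.integers(len(j_pool)))]

        n_variants = 1
        if cfg.lineage_mean > 1:
            n_variants = 1 + int(rng.poisson(cfg.lineage_mean - 1))
        n_variants = min(n_variants, int(reads))
        variant_seqs = [founder]
        seen = {founder.tobytes()}
        for _ in range(n_variants - 1):
            for _attempt in range(20):
                k = int(rng.binomial(L, cfg.shm_rate))
                k = min(max(k, 1), cap)
                var = _mutate(founder, k, rng)
                if var.tobytes() not in seen:
                    seen.add(var.tobytes())
                    variant_seqs.append(var)
                    break
        n_variants = len(variant_seqs)
        # every variant (founder included) gets at least one read
        extra = rng.multinomial(
            int(reads) - n_variants,
            rng.dirichlet(np.concatenate([[2.0], np.ones(n_variants - 1)])),
        ) if reads > n_variants else np.zeros(n_variants, dtype=int)
        variant_reads = extra + 1
        for seq, vr in zip(variant_seqs, variant_reads):
            cdr3 = seq.tobytes().decode("ascii")
            records.append(
                ClonotypeRecord(
                    sample_id=sample_id,
                    chain=chain,
                    v_gene=v_gene,
                    j_gene=j_gene,
                    cdr3_nt=cdr3,
                    read_count=int(vr),
                )
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "chain": chain,
                    "clone_id": clone_id,
                    "v_gene": v_gene,
                    "j_gene": j_gene,
                    "cdr3_nt": cdr3,
                    "reads": int(vr),
                }
            )
    return records, truth_rows


def _true_chain_features(truth_rows: list[dict]) -> dict[str, float]:
    """Diversity/network features from the generator's own clone table."""
    from .diversity import pielou_evenness, shannon_entropy
    from .network import gini

    df = pd.DataFrame(truth_rows)
    clone_counts = df.groupby("clone_id")["reads"].sum().to_numpy()
    vertex_sizes = df["reads"].to_numpy()
    cluster_sizes = df.groupby("clone_id").size().to_numpy()
    return {
        "entropy_H": shannon_entropy(clone_counts),
        "evenness_J": pielou_evenness(clone_counts),
        "vertex_gini": gini(vertex_sizes),
        "cluster_gini": gini(cluster_sizes),
    }


def simulate_survival_outcomes(
    feature_values: np.ndarray,
    beta: float,
    baseline_hazard: float,
    censoring_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards times with administrative censoring.

    Hazard for subject i is h0 * exp(beta * (f_i - mean f)); the censoring
    time is the empirical (1 - censoring_fraction) quantile of the drawn
    event times, so the realised censoring fraction matches the target.
    Returns (observed time, event indicator).
    """
    f = np.asarray(feature_values, dtype=float)
    rate = baseline_hazard * np.exp(beta * (f - f.mean()))
    t_event = rng.exponential(1.0 / rate)
    if censoring_fraction <= 0:
        return t_event, np.ones(f.size, dtype=int)
    c = np.quantile(t_event, 1.0 - censoring_fraction)
    observed = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    return observed, event


def simulate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Full cohort: clonotype tables, manifest, clinical table and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)

    records_by_sample: dict[str, list[ClonotypeRecord]] = {}
    manifest: list[SampleManifestEntry] = []
    truth_rows: list[dict] = []
    feature_rows: list[dict] = []
    clonality_used: dict[str, float] = {}
    biased_genes: dict[str, tuple[str, ...]] = {}
    sample_meta: list[dict] = []

    participant = 0
    for gi, (group, gspec) in enumerate(cfg.groups.items()):
        alpha = gspec.clonality if gspec.clonality is not None else cfg.clonality
        bias = gspec.v_gene_bias
        if bias is not None:
            biased_genes[group] = tuple(bias[0])
        for si in range(cfg.n_samples_per_group):
            participant += 1
            pid = f"TCGA-S{gi}-{participant:04d}"
            samples = [(f"{pid}-01A", alpha, bias, "tumor")]
            if si < cfg.n_adjacent_per_group:
                samples.append(
                    (f"{pid}-11A", cfg.adjacent_clonality, None, "adjacent")
                )
            for sample_id, s_alpha, s_bias, role in samples:
                recs: list[ClonotypeRecord] = []
                clonality_used[sample_id] = s_alpha
                for chain in IG_CHAINS:
                    chain_recs, chain_truth = simulate_repertoire(
                        cfg, sample_id, chain, rng,
                        clonality=s_alpha,
                        v_gene_bias=s_bias if chain == "IGH" else None,
                    )
                    recs.extend(chain_recs)
                    truth_rows.extend(chain_truth)
                    feats = _true_chain_features(chain_truth)
                    feature_rows.append(
                        {"sample_id": sample_id, "chain": chain, **feats}
                    )
                records_by_sample[sample_id] = recs
                chain_total = sum(r.read_count for r in recs)
                mult = int(
                    rng.integers(
                        cfg.total_reads_multiplier[0],
                        cfg.total_reads_multiplier[1] + 1,
                    )
                )
                manifest.append(
                    SampleManifestEntry(sample_id, group, chain_total * mult)
                )
                sample_meta.append(
                    {
                        "sample_id": sample_id,
                        "participant_id": pid,
                        "group": group,
                        "role": role,
                        "subtype": gspec.subtype,
                    }
                )

    features = pd.DataFrame(feature_rows)
    meta = pd.DataFrame(sample_meta)

    # clinical covariates per participant; survival tied to the tumor
    # sample's true feature under the configured hazard model
    tumor_meta = meta[meta["role"] == "tumor"].reset_index(drop=True)
    sv = cfg.survival
    fvals = (
        features.set_index(["sample_id", "chain"])[sv.feature]
        .loc[[(s, sv.chain) for s in tumor_meta["sample_id"]]]
        .to_numpy()
    )
    os_time, os_event = simulate_survival_outcomes(
        fvals, sv.beta, sv.baseline_hazard, sv.censoring_fraction, rng
    )
    n_pat = len(tumor_meta)
    clinical = pd.DataFrame(
        {
            "participant_id": tumor_meta["participant_id"],
            "age_at_diagnosis": np.clip(rng.normal(62, 11, n_pat), 25, 90).round(1),
            "sex": rng.choice(["female", "male"], size=n_pat),
            "stage_group": rng.choice(["early", "late"], size=n_pat),
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
            "subtype": tumor_meta["subtype"],
            "mutation_load": np.round(rng.lognormal(0.5, 1.0, n_pat), 3),
        }
    )

    truth = SyntheticTruth(
        clonality=clonality_used,
        biased_genes=biased_genes,
        beta=sv.beta,
        survival_feature=sv.feature,
        survival_chain=sv.chain,
        lineages=pd.DataFrame(truth_rows),
        clones=pd.DataFrame(truth_rows)
        .groupby(["sample_id", "chain", "clone_id", "v_gene", "j_gene"],
                 as_index=False)["reads"]
        .sum(),
        features=features,
    )
    return SyntheticCohort(records_by_sample, manifest, clinical, truth)


def simulate_feature_cohort(
    n_samples: int,
    rng: np.random.Generator,
    tumor_type: str = "SIM",
    effects: Mapping[tuple[str, str], float] | None = None,
    survival_beta: float = 0.0,
    censoring_fraction: float = 0.3,
) -> pd.DataFrame:
    """Feature-level cohort for statistical calibration studies.

    Draws the per-sample x chain feature table directly from plausible null
    distributions together with independent clinical covariates, bypassing
    sequence generation — scans over many such cohorts probe the error
    calibration of the association and survival statistics cheaply.
    ``effects`` maps (feature, covariate) to an additive shift applied where
    the covariate is "high" (late stage, male, above-median mutation load).
    ``survival_beta`` couples the hazard to IGH entropy_H.
    """
    effects = dict(effects or {})
    rows = []
    age = np.clip(rng.normal(62, 11, n_samples), 25, 90)
    sex = rng.choice(["female", "male"], size=n_samples)
    stage = rng.choice(["early", "late"], size=n_samples)
    mutation_load = rng.lognormal(0.5, 1.0, n_samples)
    sample_class = rng.choice(
        ["primary_tumor", "adjacent_non_tumor"], size=n_samples
    )
    for i in range(n_samples):
        for chain in IG_CHAINS:
            feats = {
                "expression": float(rng.lognormal(-6.0, 1.0)),
                "entropy_H": float(np.clip(rng.normal(5.0, 1.5), 0.1, None)),
                "evenness_J": float(np.clip(rng.beta(8, 3), 0.01, 0.999)),
                "vertex_gini": float(np.clip(rng.beta(4, 4), 0.01, 0.999)),
                "cluster_gini": float(np.clip(rng.beta(3, 6), 0.01, 0.999)),
            }
            for (feat, cov), delta in effects.items():
                high = {
                    "stage_group": stage[i] == "late",
                    "sex": sex[i] == "male",
                    "mutation_load": mutation_load[i] > np.median(mutation_load),
                    "age_at_diagnosis": age[i] > np.median(age),
                    "sample_class": sample_class[i] == "primary_tumor",
                }[cov]
                if high:
                    feats[feat] += delta
            rows.append(
                {
                    "sample_id": f"TCGA-Q0-{i:04d}-01A",
                    "tumor_type": tumor_type,
                    "chain": chain,
                    **feats,
                }
            )
    df = pd.DataFrame(rows)
    entropy_igh = (
        df[df["chain"] == "IGH"].set_index("sample_id")["entropy_H"]
    )
    os_time, os_event = simulate_survival_outcomes(
        entropy_igh.to_numpy(),
        survival_beta,
        1.0 / 1500.0,
        censoring_fraction,
        rng,
    )
    clin = pd.DataFrame(
        {
            "sample_id": entropy_igh.index,
            "age_at_diagnosis": age,
            "sex": sex,
            "stage_group": stage,
            "mutation_load": mutation_load,
            "sample_class": sample_class,
            "os_time": os_time,
            "os_event": os_event,
        }
    )
    return df.merge(clin, on="sample_id")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a simulated cohort in the ingestion dialects plus truth tables."""
    outdir = Path(outdir)
    clones_dir = outdir / "clones"
    clones_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, recs in cohort.records_by_sample.items():
        write_clonotype_table(
            recs, clones_dir / f"{sample_id}.tsv", MIXCR_DIALECT
        )
    pd.DataFrame([vars(e) for e in cohort.manifest]).to_csv(
        outdir / "manifest.tsv", sep="\t", index=False
    )
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    cohort.truth.lineages.to_csv(
        truth_dir / "lineages.tsv", sep="\t", index=False
    )
    cohort.truth.features.to_csv(
        truth_dir / "features.tsv", sep="\t", index=False
    )


def vgene_bias_cohort_config(
    seed: int = 0,
    n_per_group: int = 60,
    n_biased_genes: int = 5,
    shift_pp: float = 10.0,
) -> SyntheticConfig:
    """Two-group cohort (n = 120 by default) with a planted IGH V-gene
    usage shift of ``shift_pp`` percentage points on each of
    ``n_biased_genes`` genes in the second group — the standard marker-
    recovery benchmark."""
    biased = tuple(V_POOLS["IGH"][:: len(V_POOLS["IGH"]) // n_biased_genes][:n_biased_genes])
    return SyntheticConfig(
        n_samples_per_group=n_per_group,
        groups={
            "GRPA": GroupSpec(),
            "GRPB": GroupSpec(v_gene_bias=(biased, shift_pp)),
        },
        seed=seed,
    )
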