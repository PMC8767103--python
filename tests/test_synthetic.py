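"""Ground-truth cohort generator: determinism, invariants, recovery hooks."""

import numpy as np
import pandas as pd
import pytest

from repnet.errors import ConfigError
from repnet.io import IG_CHAINS, parse_tcga_barcode
from repnet.network import build_network, cluster_gini, gini, vertex_gini
from repnet.synthetic import (
    GroupSpec,
    SurvivalSpec,
    SyntheticConfig,
    simulate_cohort,
    simulate_repertoire,
    simulate_survival_outcomes,
)


class TestSimulateRepertoire:
    def test_no_shm_and_unit_lineage_gives_singletons(self):
        cfg = SyntheticConfig(shm_rate=0.0, lineage_mean=1.0, seed=1)
        rng = np.random.default_rng(0)
        recs, truth = simulate_repertoire(cfg, "S", "IGH", rng)
        net = build_network(recs)
        assert all(len(c) == 1 for c in net.clusters)
        assert cluster_gini(net) == pytest.approx(0.0, abs=1e-12)

    def test_lineage_without_shm_is_config_error(self):
        cfg = SyntheticConfig(shm_rate=0.0, lineage_mean=2.0)
        with pytest.raises(ConfigError):
            simulate_repertoire(cfg, "S", "IGH", np.random.default_rng(0))

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=5)
        a, _ = simulate_repertoire(cfg, "S", "IGK", np.random.default_rng(42))
        b, _ = simulate_repertoire(cfg, "S", "IGK", np.random.default_rng(42))
        assert a == b

    def test_variants_stay_within_divergence_cap(self):
        cfg = SyntheticConfig(shm_rate=0.05, lineage_mean=3.0, seed=2)
        _, truth = simulate_repertoire(cfg, "S", "IGH", np.random.default_rng(3))
        df = pd.DataFrame(truth)
        for _, clone in df.groupby("clone_id"):
            seqs = clone["cdr3_nt"].tolist()
            founder = seqs[0]
            cap = len(founder) // 10
            for var in seqs[1:]:
                dist = sum(a != b for a, b in zip(founder, var))
                assert 1 <= dist <= cap

    def test_higher_clonality_skew_raises_vertex_gini(self):
        cfg = SyntheticConfig(seed=3)
        rng = np.random.default_rng(7)
        ginis = {}
        for alpha in (0.05, 1.0):
            vals = []
            for i in range(25):
                recs, _ = simulate_repertoire(
                    cfg, f"S{i}", "IGH", rng, clonality=alpha
                )
                vals.append(vertex_gini(build_network(recs)))
            ginis[alpha] = np.mean(vals)
        assert ginis[0.05] > ginis[1.0]


class TestSimulateCohort:
    def test_counts_and_barcode_validity(self, small_cohort):
        cohort = small_cohort
        # 2 groups x 4 tumor samples + 2 adjacent each
        assert len(cohort.manifest) == 2 * (4 + 2)
        for entry in cohort.manifest:
            info = parse_tcga_barcode(entry.sample_id)
            assert info.sample_class in ("primary_tumor", "adjacent_non_tumor")
            recs = cohort.records_by_sample[entry.sample_id]
            assert entry.total_reads >= sum(r.read_count for r in recs)
            for r in recs:
                assert r.read_count >= 1
                assert r.chain in IG_CHAINS
                assert r.v_gene.startswith(r.chain + "V")
                assert r.j_gene.startswith(r.chain + "J")
                assert set(r.cdr3_nt) <= set("ACGT")
                assert len(r.cdr3_nt) % 3 == 0

    def test_clinical_unique_participants_and_fields(self, small_cohort):
        clinical = small_cohort.clinical
        assert clinical["participant_id"].is_unique
        assert clinical["os_time"].ge(0).all()
        assert clinical["os_event"].isin([0, 1]).all()
        assert clinical["sex"].isin(["female", "male"]).all()

    def test_single_linkage_recovers_generator_lineages(self, small_cohort):
        """With SHM capped at 10% divergence, network clusters must equal
        the generator's lineages for every sample and chain."""
        lineages = small_cohort.truth.lineages
        for (sid, chain), block in lineages.groupby(["sample_id", "chain"]):
            recs = [
                r for r in small_cohort.records_by_sample[sid] if r.chain == chain
            ]
            net = build_network(recs)
            truth_partition = {
                frozenset(
                    (r.v_gene, r.j_gene, r.cdr3_nt) for r in clone.itertuples()
                )
                for _, clone in block.groupby("clone_id")
            }
            assert set(net.clusters) == truth_partition

    def test_truth_features_match_pipeline_features(self, small_cohort):
        """The generator's true per-sample features must agree with the
        values the analysis pipeline computes from its emitted records."""
        from repnet.diversity import feature_table

        table = feature_table(
            small_cohort.records_by_sample, small_cohort.manifest
        ).set_index(["sample_id", "chain"])
        truth = small_cohort.truth.features.set_index(["sample_id", "chain"])
        for key in truth.index:
            for col in ("entropy_H", "vertex_gini", "cluster_gini"):
                assert table.loc[key, col] == pytest.approx(
                    truth.loc[key, col], abs=1e-9
                )

    def test_clone_abundance_law_matches_configuration(self):
        """Dirichlet concentration controls the abundance skew: the fitted
        Gini of clone proportions should be far higher at alpha=0.05 than
        at alpha=5."""
        out = {}
        for alpha in (0.05, 5.0):
            cfg = SyntheticConfig(
                n_samples_per_group=6,
                groups={"G": GroupSpec(clonality=alpha)},
                seed=11,
            )
            cohort = simulate_cohort(cfg)
            clones = cohort.truth.clones
            gs = [
                gini(b["reads"].to_numpy())
                for _, b in clones.groupby(["sample_id", "chain"])
            ]
            out[alpha] = np.mean(gs)
        assert out[0.05] > out[5.0] + 0.2

    def test_vgene_bias_shifts_group_usage(self):
        cfg = SyntheticConfig(
            n_samples_per_group=10,
            groups={
                "PLAIN": GroupSpec(),
                "BIAS": GroupSpec(v_gene_bias=(("IGHV3-23", "IGHV1-2"), 10.0)),
            },
            seed=13,
        )
        cohort = simulate_cohort(cfg)
        clones = cohort.truth.clones
        clones = clones[clones["chain"] == "IGH"]
        tt = {e.sample_id: e.tumor_type for e in cohort.manifest}
        clones = clones.assign(group=clones["sample_id"].map(tt))
        usage = (
            clones.groupby("group")["v_gene"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        for gene in ("IGHV3-23", "IGHV1-2"):
            assert usage.loc["BIAS", gene] > usage.loc["PLAIN", gene] + 0.05


class TestSurvivalOutcomes:
    def test_censoring_fraction_is_hit(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1, 1000)
        _, e = simulate_survival_outcomes(f, 0.0, 1 / 1500, 0.3, rng)
        assert e.mean() == pytest.approx(0.7, abs=0.01)

    def test_zero_censoring_all_events(self):
        rng = np.random.default_rng(1)
        _, e = simulate_survival_outcomes(np.zeros(50), 0.0, 1 / 1500, 0.0, rng)
        assert e.sum() == 50

    def test_positive_beta_shortens_high_feature_survival(self):
        rng = np.random.default_rng(2)
        f = np.repeat([0.0, 2.0], 2000)
        t, e = simulate_survival_outcomes(f, np.log(2), 1 / 1500, 0.0, rng)
        assert t[f == 2.0].mean() < t[f == 0.0].mean()
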