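"""Interaction LRT, size factors, BH adjustment and splice-site usage."""

import numpy as np
import pandas as pd
import pytest

from splicem6a.diffmeth import (
    DesignError,
    bh_adjust,
    call_targets,
    estimate_size_factors,
    nb_lrt_interaction,
    nb_lrt_interaction_gene,
    relative_ss_usage,
    validate_samples,
    weight_multimapped,
)
from splicem6a.simulate import SyntheticConfig, simulate_ip_counts


def _samples(replicates=3):
    rows = []
    for assay in ("input", "ip"):
        for genotype in ("WT", "KO"):
            for rep in range(1, replicates + 1):
                rows.append({"sample": f"{assay}_{genotype}_{rep}", "assay": assay,
                             "genotype": genotype, "replicate": rep})
    return pd.DataFrame(rows)


class TestWeightMultimapped:
    T2G = {"tx1": "gA", "tx2": "gA", "tx3": "gB"}

    def test_two_transcripts_one_gene(self):
        counts = weight_multimapped([["tx1", "tx2"]], self.T2G)
        assert counts["gA"] == pytest.approx(1.0)

    def test_two_genes_split(self):
        counts = weight_multimapped([["tx1", "tx3"]], self.T2G)
        assert counts["gA"] == pytest.approx(0.5)
        assert counts["gB"] == pytest.approx(0.5)

    def test_unique_read(self):
        assert weight_multimapped([["tx3"]], self.T2G)["gB"] == 1.0

    def test_zero_targets_is_error(self):
        with pytest.raises(ValueError):
            weight_multimapped([[]], self.T2G)


class TestSizeFactors:
    def test_identical_samples_all_one(self):
        counts = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)),
                              columns=list("abcd"))
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_sample_gets_factor_two(self):
        base = np.array([[10, 10, 10, 20], [40, 40, 40, 80], [7, 7, 7, 14]])
        counts = pd.DataFrame(base, columns=list("abcd"))
        factors = estimate_size_factors(counts)
        assert np.allclose(factors[["a", "b", "c"]], 1.0)
        assert factors["d"] == pytest.approx(2.0)

    def test_recovers_simulated_depths(self):
        cfg = SyntheticConfig(seed=5, n_genes=2000, n_methylated=0)
        sim = simulate_ip_counts(cfg)
        est = estimate_size_factors(sim.counts)
        true = sim.true_size_factors
        ratio = (est / est.iloc[0]) / (true / true.iloc[0])
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_all_zero_gene_fallback(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        factors = estimate_size_factors(counts)
        assert (factors > 0).all()


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_value(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_order_preserved_and_dominates_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        # adjusting a permutation permutes the result identically
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_nan_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.02, 0.04])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2, 3]], [0.03, 0.03, 0.04])


class TestInteractionLrt:
    def test_equal_counts_give_null_lr(self):
        samples = _samples()
        y = np.full(12, 50.0)
        res = nb_lrt_interaction_gene("g", y, samples, np.ones(12))
        assert res.lr_statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_lr_invariant_to_common_size_factor_scale(self):
        samples = _samples()
        rng = np.random.default_rng(0)
        y = rng.negative_binomial(20, 0.1, size=12).astype(float)
        sf = rng.uniform(0.8, 1.2, 12)
        a = nb_lrt_interaction_gene("g", y, samples, sf)
        b = nb_lrt_interaction_gene("g", y, samples, sf * 3.7)
        assert a.lr_statistic == pytest.approx(b.lr_statistic, abs=1e-5)

    def test_planted_loss_detected_with_correct_sign(self):
        cfg = SyntheticConfig(seed=21, n_genes=60, n_methylated=5,
                              nb_mean_range=(500.0, 500.0), nb_dispersion=0.05,
                              ip_enrichment=4.0)
        sim = simulate_ip_counts(cfg)
        res = nb_lrt_interaction(sim.counts, sim.samples)
        planted = set(sim.counts.index[:5])
        called = set(call_targets(res, threshold=0.1, direction="decrease"))
        # desk-scale check: most planted genes recovered, no sign errors
        assert len(planted & called) >= 4
        assert not planted & set(call_targets(res, threshold=0.1, direction="increase"))
        effects = res.set_index("gene").loc[sorted(planted), "log2_interaction"]
        assert np.all(np.abs(effects - (-2.0)) < 1.0)

    def test_low_count_genes_flagged_and_excluded(self):
        cfg = SyntheticConfig(seed=8, n_genes=10, n_methylated=0)
        sim = simulate_ip_counts(cfg)
        counts = sim.counts.copy()
        counts.iloc[0] = 0
        res = nb_lrt_interaction(counts, sim.samples)
        assert res.loc[0, "flag"] == "low_count"
        assert np.isnan(res.loc[0, "padj"])

    def test_call_targets_monotone_in_threshold(self):
        cfg = SyntheticConfig(seed=22, n_genes=40, n_methylated=4,
                              nb_mean_range=(300.0, 600.0))
        sim = simulate_ip_counts(cfg)
        res = nb_lrt_interaction(sim.counts, sim.samples)
        small = set(call_targets(res, threshold=0.01))
        large = set(call_targets(res, threshold=0.2))
        assert small <= large
        assert call_targets(res, threshold=0.0) == []

    def test_design_validation(self):
        samples = _samples().iloc[:-1]  # one cell loses a replicate -> still >=2
        validate_samples(samples)
        with pytest.raises(DesignError):
            validate_samples(_samples(replicates=1))
        bad = _samples()
        bad.loc[0, "assay"] = "IP"  # wrong case
        with pytest.raises(DesignError):
            validate_samples(bad)


class TestRelativeUsage:
    def _inputs(self, ko_factor=2.0):
        samples = pd.DataFrame({
            "sample": ["wt1", "wt2", "ko1", "ko2"],
            "genotype": ["WT", "WT", "KO", "KO"],
        })
        libs = {s: 10**6 for s in samples["sample"]}
        gene_counts = pd.DataFrame(
            {"wt1": [100, 100], "wt2": [100, 100], "ko1": [100, 100], "ko2": [100, 100]},
            index=["gA", "gB"],
        )
        junctions = pd.DataFrame(
            {
                "wt1": [10, 10], "wt2": [10, 10],
                "ko1": [10 * ko_factor, 10], "ko2": [10 * ko_factor, 10],
            },
            index=["siteA", "siteB"],
        )
        mapping = {"siteA": "gA", "siteB": "gB"}
        return junctions, gene_counts, mapping, samples, libs

    def test_usage_ratio(self):
        junctions, genes, mapping, samples, libs = self._inputs(ko_factor=1.0)
        table = relative_ss_usage(junctions, genes, mapping, samples, libs)
        assert np.allclose(table["mean_usage_wt"], 0.1)
        assert np.allclose(table["delta"], 0.0)

    def test_planted_increase_tops_ranking(self):
        junctions, genes, mapping, samples, libs = self._inputs(ko_factor=2.0)
        table = relative_ss_usage(junctions, genes, mapping, samples, libs)
        assert table.iloc[0]["site"] == "siteA"
        assert table.iloc[0]["direction"] == "increase"
        assert table.iloc[0]["delta"] == pytest.approx(0.1)

    def test_zero_gene_expression_flagged(self):
        junctions, genes, mapping, samples, libs = self._inputs()
        genes.loc["gB"] = 0
        table = relative_ss_usage(junctions, genes, mapping, samples, libs)
        row = table[table["site"] == "siteB"].iloc[0]
        assert not row["defined"]
        assert np.isnan(row["delta"])
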