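import numpy as np
import pytest
from scipy import stats

from txgc.hic import overlap_pairs
from txgc.simulate import (
    SimConfig,
    StudyConfig,
    simulate_genotypes,
    simulate_study,
    simulate_transcript_pair,
)


class TestGenotypes:
    def test_symmetric_maf_gives_mean_allele_count_one(self):
        cfg = SimConfig(n_individuals=2000, n_snps=50, n_causal=10, maf_range=(0.5, 0.5), seed=1)
        G = simulate_genotypes(cfg)
        se = np.sqrt(2 * 0.5 * 0.5 / cfg.n_individuals)
        assert np.all(np.abs(G.counts.mean(axis=0) - 1.0) < 3 * se)

    def test_identical_seed_reproduces_identical_matrix(self):
        cfg = SimConfig(n_individuals=50, n_snps=100, seed=9)
        G1 = simulate_genotypes(cfg)
        G2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(G1.counts, G2.counts)
        np.testing.assert_array_equal(G1.snp_positions, G2.snp_positions)

    def test_hardy_weinberg_proportions(self):
        cfg = SimConfig(n_individuals=1000, n_snps=2000, maf_range=(0.05, 0.5), seed=2)
        G = simulate_genotypes(cfg)
        n = cfg.n_individuals
        p = G.counts.mean(axis=0) / 2.0
        obs = np.stack([(G.counts == g).sum(axis=0) for g in (0, 1, 2)])
        exp = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
        chi2 = ((obs - exp) ** 2 / exp).sum(axis=0)
        # genotype counts have 1 free dimension given the estimated frequency
        pvals = stats.chi2.sf(chi2, df=1)
        assert np.mean(pvals > 0.001) >= 0.99

    def test_counts_in_range_no_missing(self):
        G = simulate_genotypes(SimConfig(n_individuals=30, n_snps=40, n_causal=10, seed=0))
        assert np.isin(G.counts, (0.0, 1.0, 2.0)).all()

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(SimConfig(maf_range=(0.001, 0.5)))
        with pytest.raises(ValueError):
            simulate_genotypes(SimConfig(maf_range=(0.4, 0.2)))


class TestTranscriptPair:
    def test_perfect_genetic_correlation_gives_proportional_genetic_values(self):
        cfg = SimConfig(n_individuals=100, n_snps=200, n_causal=50, h2_i=0.4, h2_j=0.4, r_G=1.0, seed=5)
        G = simulate_genotypes(cfg)
        _, _, truth = simulate_transcript_pair(G, cfg)
        corr = np.corrcoef(truth.g_i, truth.g_j)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_zero_genetic_correlation_monte_carlo(self):
        cfg = SimConfig(n_individuals=150, n_snps=200, n_causal=100, h2_i=0.5, h2_j=0.5, r_G=0.0, r_E=0.0, seed=6)
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(6)
        reps = 500
        corrs = []
        for _ in range(reps):
            _, _, truth = simulate_transcript_pair(G, cfg, rng)
            corrs.append(np.corrcoef(truth.g_i, truth.g_j)[0, 1])
        corrs = np.asarray(corrs)
        assert abs(corrs.mean()) < 3 * corrs.std() / np.sqrt(reps)

    def test_genetic_and_residual_correlations_recovered(self):
        cfg = SimConfig(n_individuals=200, n_snps=300, n_causal=150, h2_i=0.5, h2_j=0.5, r_G=0.5, r_E=0.2, seed=8)
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(8)
        reps = 200
        cg, ce = [], []
        for _ in range(reps):
            _, _, t = simulate_transcript_pair(G, cfg, rng)
            cg.append(np.corrcoef(t.g_i, t.g_j)[0, 1])
            ce.append(np.corrcoef(t.e_i, t.e_j)[0, 1])
        for vals, target in [(np.asarray(cg), 0.5), (np.asarray(ce), 0.2)]:
            assert abs(vals.mean() - target) < 3 * vals.std() / np.sqrt(reps)

    def test_phenotypes_standardized(self):
        cfg = SimConfig(n_individuals=80, n_snps=100, n_causal=20, seed=4)
        G = simulate_genotypes(cfg)
        y_i, y_j, _ = simulate_transcript_pair(G, cfg)
        for y in (y_i, y_j):
            assert y.mean() == pytest.approx(0.0, abs=1e-12)
            assert y.std() == pytest.approx(1.0, abs=1e-12)

    def test_impossible_correlation_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(r_G=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(r_E=1.0).validate()
        with pytest.raises(ValueError):
            SimConfig(n_causal=500, n_snps=100).validate()


class TestStudy:
    def test_planted_shared_esnps_hit_two_probes(self, study_bundle):
        cfg, bundle = study_bundle
        counts = bundle.eqtl.groupby("snp_id")["probe_id"].nunique()
        strong = bundle.eqtl[bundle.eqtl["p_value"] < 1e-6]
        shared_snps = strong.groupby("snp_id")["probe_id"].nunique()
        assert (shared_snps >= 2).sum() >= cfg.n_shared_esnp_pairs
        assert counts.max() >= 2

    def test_every_probe_annotated_and_has_top_esnp(self, study_bundle):
        _, bundle = study_bundle
        probes = set(bundle.expression.index)
        assert probes == set(bundle.annotation["probe_id"])
        strong = bundle.eqtl[bundle.eqtl["p_value"] < 1e-6]
        assert probes <= set(strong["probe_id"])

    def test_planted_contact_detected_at_500kb(self, study_bundle):
        cfg, bundle = study_bundle
        ann = bundle.annotation.set_index("probe_id")
        rows = []
        for _, pr in bundle.truth.pairs[bundle.truth.pairs["contact_planted"]].iterrows():
            rows.append(
                {
                    "probe_i": pr["probe_i"],
                    "probe_j": pr["probe_j"],
                    "chrom_i": ann.loc[pr["probe_i"], "chromosome"],
                    "pos_i": ann.loc[pr["probe_i"], "position"],
                    "chrom_j": ann.loc[pr["probe_j"], "chromosome"],
                    "pos_j": ann.loc[pr["probe_j"], "position"],
                }
            )
        import pandas as pd

        res = overlap_pairs(pd.DataFrame(rows), bundle.contacts, window=500_000)
        assert res.n_overlapping >= 1

    def test_study_deterministic_under_seed(self, study_bundle):
        cfg, bundle = study_bundle
        again = simulate_study(cfg)
        np.testing.assert_array_equal(bundle.genotypes.counts, again.genotypes.counts)
        assert bundle.expression.equals(again.expression)
        assert bundle.eqtl.equals(again.eqtl)
        assert bundle.contacts.equals(again.contacts)
        assert bundle.tf_genes == again.tf_genes

    def test_bundle_roundtrip_through_writers(self, study_bundle, tmp_path):
        _, bundle = study_bundle
        from txgc import io

        io.write_expression(bundle.expression, tmp_path / "expr.tsv")
        io.write_annotation(bundle.annotation, tmp_path / "ann.tsv")
        io.write_eqtl(bundle.eqtl, tmp_path / "eqtl.tsv")
        io.write_bedpe(bundle.contacts, tmp_path / "contacts.bedpe")
        io.write_gene_list(bundle.tf_genes, tmp_path / "tf.txt")
        expr = io.read_expression(tmp_path / "expr.tsv")
        assert np.allclose(expr.to_numpy(), bundle.expression.to_numpy())
        assert io.read_annotation(tmp_path / "ann.tsv").equals(bundle.annotation)
        eqtl = io.read_eqtl(tmp_path / "eqtl.tsv")
        assert np.allclose(eqtl["beta"], bundle.eqtl["beta"])
        contacts = io.read_bedpe(tmp_path / "contacts.bedpe")
        assert contacts.equals(bundle.contacts.astype(contacts.dtypes.to_dict()))
        assert io.read_gene_list(tmp_path / "tf.txt") == bundle.tf_genes
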