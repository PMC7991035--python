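"""Generator behaviour: determinism, planted structure, statistical limits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hntgwas.config import PipelineConfig
from hntgwas.errors import ConfigurationError
from hntgwas.simulate import (DESpec, QTLSpec, SimConfig,
                              generate_annotation, generate_expression,
                              generate_genotypes, generate_network,
                              generate_phenotypes, generate_ranks, gene_ids)


def _cfg(**kw) -> SimConfig:
    base = dict(n_samples=100, n_markers=200, n_chromosomes=2, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        a, b = (generate_genotypes(_cfg(seed=9)) for _ in range(2))
        assert np.array_equal(a.dosages, b.dosages)
        assert a.markers.equals(b.markers)
        ca, cb = (generate_expression(_cfg(seed=9)) for _ in range(2))
        assert ca.counts.equals(cb.counts)
        na, nb = (generate_network(_cfg(seed=9)) for _ in range(2))
        assert na.equals(nb)

    def test_different_seed_differs(self):
        a = generate_genotypes(_cfg(seed=1))
        b = generate_genotypes(_cfg(seed=2))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_stage_streams_independent(self):
        """Adding a DE spec must not perturb the genotype stream."""
        a = generate_genotypes(_cfg(seed=3))
        b = generate_genotypes(_cfg(seed=3, de_spec=(
            DESpec("gene_c1_0000", "T1", 2.0),)))
        assert np.array_equal(a.dosages, b.dosages)


class TestGenotypes:
    def test_dosages_are_diploid_minor_counts(self):
        g = generate_genotypes(_cfg())
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        assert (g.maf() <= 0.5 + 1e-12).all()

    def test_marker_map_sorted_and_qtl_present(self):
        g = generate_genotypes(_cfg(qtl_spec=(QTLSpec(2, 777_777, "YPP"),)))
        key = g.markers[["chrom", "pos"]].apply(tuple, axis=1)
        assert key.is_monotonic_increasing
        assert "Chr2pos777777.1" in set(g.markers["snp_id"])

    def test_too_many_markers_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_genotypes(_cfg(n_markers=50, chrom_length_bp=10))

    def test_maf_conservation(self):
        """Mean simulated MAF matches the folded expectation of the
        uniform(0.1, 0.9) generating frequencies (= 0.3) within
        sampling error; the copula must preserve marginals."""
        cfg = _cfg(n_samples=500, n_markers=800, n_subpops=1,
                   fst_like_divergence=0.0, ld_block_span_bp=0, seed=21)
        g = generate_genotypes(cfg)
        assert g.maf().mean() == pytest.approx(0.3, abs=0.03)

    def test_no_structure_limit(self):
        """F = 0: leading PC explains no more variance than after
        permuting sample labels."""
        from hntgwas.gwas import compute_kinship
        cfg = _cfg(n_samples=150, fst_like_divergence=0.0, seed=13)
        g = generate_genotypes(cfg)
        w = np.linalg.eigvalsh(compute_kinship(g).values)
        top_share = w[-1] / w.sum()
        rng = np.random.default_rng(0)
        perm_shares = []
        for _ in range(5):
            d = g.dosages.copy()
            for j in range(d.shape[1]):
                rng.shuffle(d[:, j])
            gp = dataclasses.replace(g, dosages=d)
            wp = np.linalg.eigvalsh(compute_kinship(gp).values)
            perm_shares.append(wp[-1] / wp.sum())
        assert top_share < 1.5 * max(perm_shares)

    def test_structure_recovered_by_top_pc(self):
        """2 subpops at divergence 0.3: top-PC clustering recovers the
        labels for > 90% of samples (best of both label assignments)."""
        from hntgwas.gwas import compute_pcs
        cfg = _cfg(n_samples=200, n_markers=400, n_subpops=2,
                   fst_like_divergence=0.3, seed=17)
        g = generate_genotypes(cfg)
        pc1 = compute_pcs(g, 1)[:, 0]
        truth = np.arange(cfg.n_samples) % 2
        call = (pc1 > np.median(pc1)).astype(int)
        agree = max(np.mean(call == truth), np.mean(call != truth))
        assert agree > 0.9

    def test_ld_blocks_raise_adjacent_correlation(self):
        cfg_ld = _cfg(n_samples=300, n_markers=300, n_chromosomes=1,
                      ld_block_span_bp=50_000, n_subpops=1,
                      fst_like_divergence=0.0, seed=23)
        cfg_free = dataclasses.replace(cfg_ld, ld_block_span_bp=0)

        def adjacent_r2(g):
            d = g.dosages
            r = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
                 for j in range(d.shape[1] - 1)
                 if d[:, j].std() > 0 and d[:, j + 1].std() > 0]
            return np.mean(r)

        r2_ld = adjacent_r2(generate_genotypes(cfg_ld))
        r2_free = adjacent_r2(generate_genotypes(cfg_free))
        assert r2_ld > 3 * r2_free  # independence limit is the baseline
        assert r2_free < 0.05


class TestPhenotypes:
    def test_qtl_effect_shifts_carriers(self):
        cfg = _cfg(n_samples=300, h2_polygenic=0.0,
                   qtl_spec=(QTLSpec(1, 400_000, "YPP", "both", 1.0),))
        g = generate_genotypes(cfg)
        ph = generate_phenotypes(cfg, g)
        j = g.marker_index("Chr1pos400000.1")
        y = ph[(ph.treatment == "HNT") & (ph.trait == "YPP")]["value"].to_numpy()
        d = g.dosages[:, j]
        slope = np.polyfit(d, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.3)

    def test_treatment_scope_restricts_effect(self):
        cfg = _cfg(n_samples=400, h2_polygenic=0.0,
                   qtl_spec=(QTLSpec(1, 400_000, "YPP", "HNT_only", 1.0),))
        g = generate_genotypes(cfg)
        ph = generate_phenotypes(cfg, g)
        j = g.marker_index("Chr1pos400000.1")
        d = g.dosages[:, j]
        y_h = ph[(ph.treatment == "HNT") & (ph.trait == "YPP")]["value"].to_numpy()
        y_c = ph[(ph.treatment == "CNT") & (ph.trait == "YPP")]["value"].to_numpy()
        assert np.polyfit(d, y_h, 1)[0] == pytest.approx(1.0, abs=0.3)
        assert np.polyfit(d, y_c, 1)[0] == pytest.approx(0.0, abs=0.3)

    def test_monomorphic_qtl_rejected(self):
        cfg = _cfg(qtl_spec=(QTLSpec(1, 123_456, "YPP"),))
        g = generate_genotypes(cfg)
        j = g.marker_index("Chr1pos123456.1")
        g.dosages[:, j] = 0.0
        with pytest.raises(ConfigurationError, match="monomorphic"):
            generate_phenotypes(cfg, g)

    def test_global_null_phenotypes_uncorrelated_with_markers(self):
        cfg = _cfg(n_samples=200, h2_polygenic=0.0, qtl_spec=(), seed=31)
        g = generate_genotypes(cfg)
        ph = generate_phenotypes(cfg, g)
        y = ph[(ph.treatment == "CNT") & (ph.trait == "YPP")]["value"].to_numpy()
        # marginal regression p-values approximately uniform
        ps = []
        for j in range(g.n_markers):
            d = g.dosages[:, j]
            if d.std() == 0:
                continue
            ps.append(stats.pearsonr(d, y).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestExpression:
    def test_null_counts_flag_few_genes(self):
        from hntgwas import prioritize as pri
        cfg = _cfg(n_genes=200, de_spec=(), seed=41)
        cm = generate_expression(cfg)
        res = pri.de_test(cm, PipelineConfig())
        n_sup = sum(r.de_flag == pri.SUPPORTED for r in res)
        assert n_sup <= 0.05 * cfg.n_genes + 3

    def test_library_sizes_span_twofold(self):
        cm = generate_expression(_cfg())
        libs = cm.counts.sum(axis=0).to_numpy()
        assert libs.max() / libs.min() >= 2.0

    def test_unknown_de_gene_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_expression(_cfg(de_spec=(DESpec("nope", "T1", 2.0),)))


class TestAnnotationNetworkRanks:
    def test_annotation_valid_and_sorted(self):
        a = generate_annotation(_cfg(n_genes=100))
        assert (a["start"] <= a["end"]).all()
        assert (a["start"] >= 1).all()
        assert a["gene_id"].is_unique
        for _, sub in a.groupby("chrom"):
            # non-overlapping by construction
            assert (sub["start"].to_numpy()[1:]
                    > sub["end"].to_numpy()[:-1]).all()

    def test_network_scores_in_scale(self):
        net = generate_network(_cfg(network_density=0.05))
        assert len(net) > 0
        assert net["score"].between(0, 871).all()

    def test_zero_density_network_empty(self):
        assert generate_network(_cfg(network_density=0.0)).empty

    def test_uniform_scores_survival_fraction(self):
        """Uniform integer scores on [0, 871]: P(score >= 200) = 672/872,
        verified by enumeration of the integer support."""
        support = np.arange(0, 872)
        expected = (support >= 200).sum() / len(support)
        assert expected == pytest.approx(672 / 872)
        net = generate_network(_cfg(n_genes=500, network_density=0.2,
                                    seed=43))
        frac = (net["score"] >= 200).mean()
        se = np.sqrt(expected * (1 - expected) / len(net))
        assert abs(frac - expected) < 5 * se

    def test_ranks_are_permutations(self):
        genes = {"L1": [f"g{i}" for i in range(5)], "L2": ["a", "b"]}
        rk = generate_ranks(genes, seed=1)
        for locus, sub in rk.groupby("locus_id"):
            assert sorted(sub["rank"]) == list(range(1, len(sub) + 1))

    def test_ranks_missing_fraction_and_unranked(self):
        genes = {"L1": [f"g{i}" for i in range(10)], "L2": ["a", "b"]}
        rk = generate_ranks(genes, missing_frac=0.3, unranked_loci=("L2",),
                            seed=2)
        assert (rk["locus_id"] == "L2").sum() == 0
        assert (rk["locus_id"] == "L1").sum() == 7
        assert sorted(rk["rank"]) == list(range(1, 8))

    def test_gene_ids_shared_across_generators(self):
        cfg = _cfg(n_genes=50)
        assert set(generate_annotation(cfg)["gene_id"]) == set(gene_ids(cfg))
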