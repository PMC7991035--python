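"""Evidence channels and the untestability-aware voting rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from hntgwas import prioritize as pri
from hntgwas.config import PipelineConfig
from hntgwas.prioritize import (FAILED, SUPPORTED, UNTESTABLE, de_test,
                                integrate, network_evidence, nb_exact_test,
                                rank_evidence, tmm_factors, vote)
from hntgwas.simulate import CountMatrix, DESpec, SimConfig, generate_expression


def _count_matrix(mat, n_t=1, n_rep=3):
    genes = [f"g{i}" for i in range(mat.shape[0])]
    sheet = []
    for cond in ("control", "HNT"):
        for t in range(1, n_t + 1):
            for r in range(1, n_rep + 1):
                sheet.append((f"{cond}_T{t}_R{r}", cond, f"T{t}", r))
    samples = pd.DataFrame(sheet, columns=["sample_id", "condition", "time",
                                           "replicate"])
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                          columns=samples["sample_id"].tolist())
    return CountMatrix(counts=counts, samples=samples)


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        col = np.random.default_rng(0).integers(10, 1000, size=200)
        mat = np.tile(col[:, None], (1, 6))
        f = tmm_factors(_count_matrix(mat).counts)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_exact_doubling_recovered(self):
        """One library scaled exactly x2: sequencing depth absorbs the
        doubling, so its *effective* size is ~2x the others while the
        TMM factors stay ~1 with geometric mean 1."""
        rng = np.random.default_rng(1)
        col = rng.integers(50, 2000, size=300).astype(float)
        mat = np.tile(col[:, None], (1, 6))
        mat[:, 0] *= 2.0
        counts = _count_matrix(mat).counts
        f = tmm_factors(counts).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(f, 1.0, rtol=0.05)
        eff = counts.sum(axis=0).to_numpy() * f
        assert eff[0] / eff[1] == pytest.approx(2.0, rel=0.05)

    def test_composition_shift_compensated(self):
        """Doubling a 25% subset of genes in one library shifts its
        composition; unchanged genes are diluted per unit of library
        size, so TMM pulls that library's factor below 1 to keep their
        normalized rates comparable."""
        rng = np.random.default_rng(7)
        col = rng.integers(50, 2000, size=400).astype(float)
        mat = np.tile(col[:, None], (1, 6))
        mat[:100, 0] *= 8.0
        f = tmm_factors(_count_matrix(mat).counts).to_numpy()
        assert f[0] < 0.9 * f[1]

    def test_matches_edger_reference(self, tmp_path):
        """Factors agree with edgeR's calcNormFactors (independent
        reference implementation) within 2% on a composition-shifted
        matrix."""
        import subprocess
        rng = np.random.default_rng(42)
        mat = rng.negative_binomial(10, 10 / (10 + 200), size=(200, 6)
                                    ).astype(float)
        mat[:40, 1] *= 5
        counts_path = tmp_path / "counts.tsv"
        pd.DataFrame(mat.astype(int)).to_csv(counts_path, sep="\t",
                                             header=False, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'm <- as.matrix(read.table("{counts_path}"))\n'
            'f <- calcNormFactors(DGEList(counts=m),'
            ' method="TMM")$samples$norm.factors\n'
            'cat(f, sep="\\n")\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(x) for x in out.stdout.split()])
        mine = tmm_factors(
            pd.DataFrame(mat, columns=[f"s{i}" for i in range(6)])).to_numpy()
        assert np.allclose(mine, ref, rtol=0.02)


class TestExactTest:
    def test_symmetry(self):
        assert nb_exact_test(30, 3, 90, 3, 0.1) == pytest.approx(
            nb_exact_test(90, 3, 30, 3, 0.1))

    def test_equal_split_p_one(self):
        assert nb_exact_test(50, 3, 50, 3, 0.1) == pytest.approx(1.0)

    def test_zero_total_p_one(self):
        assert nb_exact_test(0, 3, 0, 3, 0.1) == 1.0

    def test_extreme_split_small_p(self):
        assert nb_exact_test(300, 3, 10, 3, 0.05) < 1e-4

    def test_more_dispersion_less_significant(self):
        p_lo = nb_exact_test(200, 3, 80, 3, 0.01)
        p_hi = nb_exact_test(200, 3, 80, 3, 0.5)
        assert p_lo < p_hi


class TestDETest:
    def test_null_supports_nothing_obvious(self, cfg):
        rng = np.random.default_rng(2)
        mat = rng.negative_binomial(10, 10 / (10 + 100.0), size=(150, 6))
        res = de_test(_count_matrix(mat), cfg)
        n_sup = sum(r.de_flag == SUPPORTED for r in res)
        assert n_sup <= 0.05 * 150 + 3

    def test_planted_gene_supported(self, cfg):
        cm = generate_expression(SimConfig(
            n_samples=10, n_markers=10, n_genes=80, n_timepoints=2,
            de_spec=(DESpec("gene_c1_0000", "T1", 2.0),), seed=6))
        res = {r.gene_id: r for r in de_test(cm, cfg)}
        assert res["gene_c1_0000"].de_flag == SUPPORTED
        # supported at T1 specifically
        assert res["gene_c1_0000"].per_time["T1"][2] < cfg.de_fdr_max

    def test_undetectable_gene_untestable(self, cfg):
        rng = np.random.default_rng(3)
        mat = rng.integers(50, 200, size=(20, 6))
        mat[5, :] = 0
        res = de_test(_count_matrix(mat), cfg)
        assert res[5].de_flag == UNTESTABLE

    def test_bh_matches_brute_force(self):
        """BH step agrees with a hand-rolled step-up computation."""
        rng = np.random.default_rng(4)
        p = rng.uniform(size=57)

        def brute_bh(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, pvals[i] * m / rank)
                adj[i] = running
            return adj

        assert np.allclose(multipletests(p, method="fdr_bh")[1], brute_bh(p))


class TestNetworkEvidence:
    def _net(self, rows):
        return pd.DataFrame(rows, columns=["tf_id", "target_id", "score"])

    def test_inclusive_threshold(self, cfg):
        net = self._net([("tf1", "gA", 200), ("tf1", "gB", 199)])
        out = {e.gene_id: e for e in network_evidence(["gA", "gB"], net, cfg)}
        assert out["gA"].net_flag == SUPPORTED
        assert out["gB"].net_flag == FAILED

    def test_absent_gene_untestable(self, cfg):
        net = self._net([("tf1", "gA", 500)])
        (e,) = network_evidence(["gZ"], net, cfg)
        assert e.net_flag == UNTESTABLE

    def test_tf_with_outgoing_edges_only_not_supported(self, cfg):
        """Being a TF (source) does not count as evidence; the node is
        testable but fails."""
        net = self._net([("gA", "gB", 800)])
        out = {e.gene_id: e for e in network_evidence(["gA", "gB"], net, cfg)}
        assert out["gA"].net_flag == FAILED
        assert out["gB"].net_flag == SUPPORTED

    def test_score_bounds_enforced(self, cfg):
        ok = self._net([("tf1", "gA", 871)])
        network_evidence(["gA"], ok, cfg)  # accepted
        bad = self._net([("tf1", "gA", 872)])
        with pytest.raises(ValueError):
            network_evidence(["gA"], bad, cfg)

    @pytest.mark.parametrize("seed", range(3))
    def test_retained_counts_match_brute_force(self, cfg, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        rows = [(genes[rng.integers(30)], genes[rng.integers(30)],
                 int(rng.integers(0, 872))) for _ in range(200)]
        net = self._net(rows)
        out = {e.gene_id: e for e in network_evidence(genes, net, cfg)}
        for g in genes:
            expected = [r for r in rows
                        if r[1] == g and r[2] >= cfg.network_score_min]
            assert out[g].n_interactions == len(expected)
            if expected:
                assert out[g].max_score == max(r[2] for r in expected)


class TestRankEvidence:
    def _ranks(self, rows):
        return pd.DataFrame(rows, columns=["locus_id", "gene_id", "rank"])

    def test_threshold_rule(self, cfg):
        rk = self._ranks([("L1", f"g{i}", i) for i in range(1, 6)])
        gl = {f"g{i}": ("L1",) for i in range(1, 6)}
        out = {e.gene_id: e for e in rank_evidence(gl, rk, cfg)}
        assert out["g2"].rank_flag == SUPPORTED
        assert out["g3"].rank_flag == FAILED

    def test_unranked_locus_untestable(self, cfg):
        rk = self._ranks([("L1", "gA", 1)])
        gl = {"gB": ("L2",)}
        (e,) = rank_evidence(gl, rk, cfg)
        assert e.rank_flag == UNTESTABLE

    def test_any_locus_support(self, cfg):
        """Gene ranked 1 in one locus and 5 in another is supported."""
        rk = self._ranks([("L1", "gA", 1), ("L2", "gA", 5),
                          ("L2", "gB", 1)])
        gl = {"gA": ("L1", "L2")}
        (e,) = rank_evidence(gl, rk, cfg)
        assert e.rank_flag == SUPPORTED
        assert e.best_rank == 1

    def test_duplicate_rank_rejected(self, cfg):
        rk = self._ranks([("L1", "gA", 1), ("L1", "gB", 1)])
        with pytest.raises(ValueError, match="duplicate rank"):
            rank_evidence({"gA": ("L1",)}, rk, cfg)


class TestVoting:
    def test_full_truth_table(self):
        """All 27 tri-state combinations follow the rule: high iff
        two supports, or one support with no testable failure."""
        states = (SUPPORTED, FAILED, UNTESTABLE)
        for flags in itertools.product(states, repeat=3):
            n_sup = flags.count(SUPPORTED)
            n_fail = flags.count(FAILED)
            expected = "high" if (n_sup >= 2
                                  or (n_sup >= 1 and n_fail == 0)) else "low"
            assert vote(*flags) == expected, flags

    @pytest.mark.parametrize("flags,expected", [
        ((SUPPORTED, SUPPORTED, FAILED), "high"),
        ((SUPPORTED, UNTESTABLE, UNTESTABLE), "high"),
        ((SUPPORTED, FAILED, UNTESTABLE), "low"),
        ((UNTESTABLE, UNTESTABLE, UNTESTABLE), "low"),
    ])
    def test_documented_cases(self, flags, expected):
        assert vote(*flags) == expected


class TestIntegrate:
    def _inputs(self):
        gl = {"gA": ("L1",), "gB": ("L1",), "gC": ("L2",)}
        de = [pri.DEResult("gA", SUPPORTED, {}),
              pri.DEResult("gB", FAILED, {}),
              pri.DEResult("gC", UNTESTABLE, {})]
        net = [pri.NetworkEvidence("gA", SUPPORTED, 2, 500),
               pri.NetworkEvidence("gB", UNTESTABLE, 0, -1),
               pri.NetworkEvidence("gC", SUPPORTED, 1, 300)]
        rk = [pri.RankEvidence("gA", FAILED, 4, "L1"),
              pri.RankEvidence("gB", SUPPORTED, 1, "L1"),
              pri.RankEvidence("gC", UNTESTABLE, 0, "")]
        return gl, de, net, rk

    def test_counts_partition(self):
        gl, de, net, rk = self._inputs()
        for p in integrate(gl, de, net, rk):
            assert p.n_supported + p.n_failed + p.n_untestable == 3

    def test_sorted_and_order_independent(self):
        gl, de, net, rk = self._inputs()
        base = integrate(gl, de, net, rk)
        shuffled = integrate(dict(reversed(list(gl.items()))),
                             list(reversed(de)), list(reversed(net)),
                             list(reversed(rk)))
        assert base == shuffled
        keys = [(-p.n_supported, p.n_failed, p.gene_id) for p in base]
        assert keys == sorted(keys)

    def test_idempotent(self):
        gl, de, net, rk = self._inputs()
        assert integrate(gl, de, net, rk) == integrate(gl, de, net, rk)

    def test_missing_channel_defaults_untestable(self):
        profiles = integrate({"gX": ("L1",)}, [], [], [])
        assert profiles[0].n_untestable == 3
        assert profiles[0].priority == "low"
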