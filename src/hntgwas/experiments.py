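"""Replicated simulation experiments that characterize the pipeline.

Each function runs the full relevant slice of the pipeline on freshly
generated synthetic data and returns summary statistics: null
calibration of the mixed-model scan, recovery of a planted polygenic
heritability, power and allelic-effect sign recovery for a planted
HNT-specific QTL, detection of a planted differentially expressed
gene, and end-to-end recovery of a fully supported causal gene.

Problem sizes are chosen to characterize desk-scale behaviour:
calibration and recovery experiments use panels of 500 genotypes
(commensurate with the ~200-genotype panel the design emulates, but
large enough for stable empirical rates), with 50–100 replicates per
experiment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import gwas, io, loci as loci_mod, genes as genes_mod
from . import prioritize as pri
from .config import PipelineConfig
from .simulate import (DESpec, QTLSpec, SimConfig, generate_annotation,
                       generate_expression, generate_genotypes,
                       generate_phenotypes, generate_network)


def _child_seed(seed: int, stream: int, rep: int) -> int:
    """Deterministic sub-seed below 2**31 for one replicate."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream, rep))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def table2_accounting() -> dict[str, float]:
    """Locus accounting over the packaged printed cMTA table.

    Computes per-treatment locus counts, the across-trait HNT total,
    the number of distinct peak-SNP names, the number of SNPs shared
    between absolute and relative scans, and the combined CNT + HNT
    (cross-treatment) locus count.
    """
    cfg = PipelineConfig()
    table = io.load_table2()
    all_loci = loci_mod.loci_from_table(table, cfg)
    counts = loci_mod.treatment_counts(all_loci)
    hnt_by_trait = loci_mod.trait_counts(all_loci, "HNT")
    return {
        "cmta_count_cnt": counts.get("CNT", 0),
        "cmta_count_hnt": counts.get("HNT", 0),
        "cmta_count_relative": counts.get("Relative", 0),
        "hnt_trait_breakdown_total": sum(hnt_by_trait.values()),
        "unique_peak_snps": loci_mod.unique_peak_snps(all_loci),
        "absolute_relative_shared_snps":
            len(loci_mod.absolute_relative_shared_snps(all_loci)),
        "cross_treatment_loci": counts.get("CNT", 0) + counts.get("HNT", 0),
    }


def null_calibration(seed: int, n_reps: int = 50, n_samples: int = 500,
                     n_markers: int = 1000, alpha: float = 0.01
                     ) -> dict[str, float]:
    """Type-I error and genomic-control lambda under the global null.

    Structured genotypes (2 subpopulations, LD blocks), phenotypes pure
    noise; the scan uses kinship and 3 PCs.  Returns the pooled
    empirical type-I error at ``alpha`` and the mean median-based
    lambda across replicates.
    """
    pc = PipelineConfig()
    hits = total = 0
    lambdas = []
    for rep in range(n_reps):
        cfg = SimConfig(n_samples=n_samples, n_markers=n_markers,
                        n_chromosomes=5, n_subpops=2,
                        fst_like_divergence=0.1, h2_polygenic=0.0,
                        qtl_spec=(), seed=_child_seed(seed, 11, rep))
        g = generate_genotypes(cfg)
        ph = generate_phenotypes(cfg, g)
        y = ph[(ph.treatment == "HNT") & (ph.trait == "YPP")]["value"].to_numpy()
        K = gwas.compute_kinship(g)
        pcs = gwas.compute_pcs(g, pc.n_pcs)
        assoc = gwas.mlm_scan(g, y, K, pcs, pc)
        hits += int((assoc["p"] < alpha).sum())
        total += len(assoc)
        lambdas.append(gwas.genomic_control_lambda(assoc["p"]))
    return {"type1_error": hits / total,
            "lambda_gc": float(np.mean(lambdas))}


def h2_recovery(seed: int, n_reps: int = 50, n_samples: int = 500,
                n_markers: int = 400, h2: float = 0.4) -> dict[str, float]:
    """Mean REML heritability estimate for a planted polygenic h2."""
    ests = []
    for rep in range(n_reps):
        cfg = SimConfig(n_samples=n_samples, n_markers=n_markers,
                        n_chromosomes=2, n_subpops=2,
                        fst_like_divergence=0.05, h2_polygenic=h2,
                        qtl_spec=(), seed=_child_seed(seed, 13, rep))
        g = generate_genotypes(cfg)
        ph = generate_phenotypes(cfg, g)
        y = ph[(ph.treatment == "HNT") & (ph.trait == "YPP")]["value"].to_numpy()
        K = gwas.compute_kinship(g)
        ests.append(gwas.estimate_heritability(y, K).h2)
    return {"h2_mean": float(np.mean(ests)), "h2_planted": h2}


def qtl_power_and_sign(seed: int, n_reps: int = 100, n_samples: int = 500,
                       n_markers: int = 200, effect: float = 1.0
                       ) -> dict[str, float]:
    """Detection and allelic-effect sign recovery for an HNT-only QTL.

    One QTL of ``effect`` SD per minor-allele copy is planted with
    HNT-only scope; each replicate scans both arms at the standard
    -log10(p) = 3.5 threshold and estimates the allelic effect at the
    planted marker in the HNT arm.  Detection counts a significant
    marker within the clumping window of the planted position.
    """
    pc = PipelineConfig()
    qtl_pos = 500_000
    det_hnt = det_cnt = sign_ok = 0
    for rep in range(n_reps):
        cfg = SimConfig(n_samples=n_samples, n_markers=n_markers,
                        n_chromosomes=2, n_subpops=2,
                        fst_like_divergence=0.05, h2_polygenic=0.2,
                        qtl_spec=(QTLSpec(1, qtl_pos, "YPP", "HNT_only",
                                          effect),),
                        seed=_child_seed(seed, 17, rep))
        g = generate_genotypes(cfg)
        ph = generate_phenotypes(cfg, g)
        K = gwas.compute_kinship(g)
        pcs = gwas.compute_pcs(g, pc.n_pcs)
        for arm in ("HNT", "CNT"):
            y = ph[(ph.treatment == arm) & (ph.trait == "YPP")]["value"].to_numpy()
            assoc = gwas.mlm_scan(g, y, K, pcs, pc)
            near = assoc[(assoc["chrom"] == 1)
                         & ((assoc["pos"] - qtl_pos).abs()
                            <= pc.clump_window_bp)]
            hit = bool((near["neg_log10_p"] >= pc.neg_log_p_threshold).any())
            if arm == "HNT":
                det_hnt += hit
                eff, _ = loci_mod.allelic_effect(
                    g, y, f"Chr1pos{qtl_pos}.1", +1)
                sign_ok += (np.sign(eff) == np.sign(effect))
            else:
                det_cnt += hit
    return {"power_hnt": det_hnt / n_reps, "power_cnt": det_cnt / n_reps,
            "sign_recovery": float(sign_ok) / n_reps}


def de_detection(seed: int, n_reps: int = 100, n_genes: int = 60,
                 log2fc: float = 2.0) -> dict[str, float]:
    """Detection rate of a planted log2FC gene at FDR < 0.05.

    One gene with baseline mean 100 is shifted by ``log2fc`` in the
    HNT arm at one time point (3 replicates per condition per time
    point); the rate counts replicates where the DE channel flags it
    supported.
    """
    pc = PipelineConfig()
    flagged = 0
    for rep in range(n_reps):
        cfg = SimConfig(n_samples=10, n_markers=10, n_genes=n_genes,
                        n_timepoints=2,
                        de_spec=(DESpec("gene_c1_0000", "T1", log2fc),),
                        seed=_child_seed(seed, 19, rep))
        cm = generate_expression(cfg)
        res = {r.gene_id: r for r in pri.de_test(cm, pc)}
        flagged += (res["gene_c1_0000"].de_flag == pri.SUPPORTED)
    return {"de_detection_rate": flagged / n_reps}


def causal_recovery(seed: int, n_reps: int = 20, n_samples: int = 400
                    ) -> dict[str, float]:
    """End-to-end recovery of a fully supported planted causal gene.

    Each replicate plants one HNT-only QTL; the gene nearest the QTL is
    made differentially expressed, targeted by a strong network edge,
    and ranked first in its locus.  Success means the HNT scan yields a
    locus covering the QTL and the planted gene is the unique
    high-priority call among that locus's candidates.
    """
    pc = PipelineConfig()
    qtl_pos = 500_000
    success = 0
    for rep in range(n_reps):
        base = SimConfig(n_samples=n_samples, n_markers=300,
                         n_chromosomes=2, n_subpops=2,
                         fst_like_divergence=0.05, h2_polygenic=0.2,
                         n_genes=160, network_density=0.0,
                         qtl_spec=(QTLSpec(1, qtl_pos, "YPP", "HNT_only",
                                           1.0),),
                         seed=_child_seed(seed, 23, rep))
        annot = generate_annotation(base)
        on_chrom = annot[annot["chrom"] == 1]
        mid = (on_chrom["start"] + on_chrom["end"]) / 2.0
        causal = on_chrom.loc[(mid - qtl_pos).abs().idxmin(), "gene_id"]
        cfg = dataclasses.replace(base,
                                  de_spec=(DESpec(causal, "T1", 2.0),))

        g = generate_genotypes(cfg)
        ph = generate_phenotypes(cfg, g)
        y = ph[(ph.treatment == "HNT") & (ph.trait == "YPP")]["value"].to_numpy()
        K = gwas.compute_kinship(g)
        pcs = gwas.compute_pcs(g, pc.n_pcs)
        assoc = gwas.mlm_scan(g, y, K, pcs, pc)
        called = loci_mod.call_cmtas(assoc, pc, trait="YPP", treatment="HNT",
                                     experiment="E1")
        covering = [l for l in called
                    if l.chrom == 1 and l.window_start <= qtl_pos <= l.window_end]
        if not covering:
            continue
        locus = covering[0]
        gene_set = genes_mod.genes_in_window(locus, annot, pc)
        if causal not in gene_set.genes:
            continue

        cm = generate_expression(cfg)
        network = pd.DataFrame([{"tf_id": "gene_c2_0000",
                                 "target_id": causal, "score": 500}])
        others = [gg for gg in gene_set.genes if gg != causal]
        rng = np.random.default_rng(_child_seed(seed, 29, rep))
        order = [causal] + list(rng.permutation(others))
        ranks = pd.DataFrame({"locus_id": locus.locus_id,
                              "gene_id": order,
                              "rank": np.arange(1, len(order) + 1)})

        gene_loci = {gg: (locus.locus_id,) for gg in gene_set.genes}
        de = pri.de_test(cm, pc)
        net = pri.network_evidence(list(gene_loci), network, pc)
        rank = pri.rank_evidence(gene_loci, ranks, pc)
        profiles = pri.integrate(gene_loci, de, net, rank)
        high = [p.gene_id for p in profiles if p.priority == "high"]
        success += (high == [causal])
    return {"causal_recovery_rate": success / n_reps}
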