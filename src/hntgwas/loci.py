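"""Collapse significant markers into candidate marker-trait associations.

A locus (cMTA) is the lowest-p significant SNP with no other accepted
peak within the clumping window (100 kb by default) on the same
chromosome.  Each locus carries its trait/treatment/experiment context,
the allelic effect (minor-carrier mean minus major-carrier mean), the
favorable allele under the trait's direction of benefit, and a
peak-centred gene-search window.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import GenotypeMatrix


@dataclasses.dataclass(frozen=True)
class Locus:
    locus_id: str
    trait: str
    treatment: str  # CNT | HNT | Relative
    experiment: str
    snp_id: str
    chrom: int
    pos: int
    p_value: float
    major: str = ""
    minor: str = ""
    allelic_effect: float = float("nan")
    favorable_allele: str = ""
    window_start: int = 0
    window_end: int = 0

    @property
    def analysis(self) -> str:
        """'relative' for ratio-trait scans, 'absolute' otherwise."""
        return "relative" if self.treatment == "Relative" else "absolute"


@dataclasses.dataclass(frozen=True)
class LocusComparison:
    locus_a: str
    locus_b: str
    snp_a: str
    snp_b: str
    relation: str  # identical_snp | proximal
    distance_bp: int


def call_cmtas(assoc: pd.DataFrame, cfg: PipelineConfig,
               trait: str = "", treatment: str = "", experiment: str = "",
               locus_prefix: str = "Q") -> list[Locus]:
    """Greedy clumping of significant markers into peak-SNP loci.

    Significant markers (neg_log10_p >= threshold) are visited in
    ascending p order (ties broken by chromosome then position); a
    marker is accepted unless an already accepted peak on the same
    chromosome lies within ``clump_window_bp``.  Each accepted peak
    becomes a locus with a +/- ``gene_window_bp`` search window.
    """
    sig = assoc[assoc["neg_log10_p"] >= cfg.neg_log_p_threshold]
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")
    accepted: list[pd.Series] = []
    for _, row in sig.iterrows():
        clash = any(a["chrom"] == row["chrom"]
                    and abs(int(a["pos"]) - int(row["pos"])) <= cfg.clump_window_bp
                    for a in accepted)
        if not clash:
            accepted.append(row)
    loci = []
    for i, row in enumerate(accepted, start=1):
        pos = int(row["pos"])
        loci.append(Locus(
            locus_id=f"{locus_prefix}{i}",
            trait=trait, treatment=treatment, experiment=experiment,
            snp_id=str(row["snp_id"]), chrom=int(row["chrom"]), pos=pos,
            p_value=float(row["p"]),
            window_start=max(1, pos - cfg.gene_window_bp),
            window_end=pos + cfg.gene_window_bp,
        ))
    return loci


def allelic_effect(geno: GenotypeMatrix, pheno_vector: np.ndarray,
                   snp_id: str, trait_direction: int = +1
                   ) -> tuple[float, str]:
    """Allelic effect of a peak SNP and its favorable allele.

    Effect = mean phenotype of minor-allele carriers (dosage >= 1)
    minus mean phenotype of major-allele homozygotes.  The favorable
    allele is the one whose carrier group lies in the beneficial
    direction (``trait_direction`` +1 for higher-is-better traits,
    -1 for loss traits such as chalkiness); equal group means give an
    indeterminate call ('?').
    """
    j = geno.marker_index(snp_id)
    dose = geno.dosages[:, j]
    y = np.asarray(pheno_vector, dtype=float)
    valid = np.isfinite(dose) & np.isfinite(y)
    carrier = valid & (dose >= 1)
    non = valid & (dose == 0)
    if not carrier.any() or not non.any():
        raise ValueError(f"empty carrier class at {snp_id}")
    effect = float(y[carrier].mean() - y[non].mean())
    row = geno.markers.iloc[j]
    if effect == 0.0:
        return 0.0, "?"
    favors_minor = (effect > 0) == (trait_direction > 0)
    return effect, (row["minor"] if favors_minor else row["major"])


def annotate_effects(loci: Sequence[Locus], geno: GenotypeMatrix,
                     pheno_vector: np.ndarray, cfg: PipelineConfig
                     ) -> list[Locus]:
    """Fill allelic effect, allele pair and favorable allele per locus."""
    out = []
    for loc in loci:
        direction = cfg.trait_directions.get(loc.trait, +1)
        eff, fav = allelic_effect(geno, pheno_vector, loc.snp_id, direction)
        row = geno.markers.iloc[geno.marker_index(loc.snp_id)]
        out.append(dataclasses.replace(
            loc, major=str(row["major"]), minor=str(row["minor"]),
            allelic_effect=eff, favorable_allele=fav))
    return out


def compare_loci(loci: Sequence[Locus], cfg: PipelineConfig
                 ) -> list[LocusComparison]:
    """Classify all cross-context locus pairs as shared or proximal.

    Pairs from different (trait, treatment, experiment) contexts are
    compared: exact peak-SNP name identity, or same-chromosome
    proximity within ``colocalization_bp``.  Output is symmetric-free
    (each unordered pair once) and contains no self-pairs.
    """
    out = []
    for a, b in itertools.combinations(loci, 2):
        same_context = (a.trait, a.treatment, a.experiment) == \
                       (b.trait, b.treatment, b.experiment)
        if same_context:
            continue
        if a.snp_id == b.snp_id:
            out.append(LocusComparison(a.locus_id, b.locus_id,
                                       a.snp_id, b.snp_id,
                                       "identical_snp", 0))
        elif a.chrom == b.chrom and abs(a.pos - b.pos) <= cfg.colocalization_bp:
            out.append(LocusComparison(a.locus_id, b.locus_id,
                                       a.snp_id, b.snp_id,
                                       "proximal", abs(a.pos - b.pos)))
    return out


def unique_peak_snps(loci: Iterable[Locus]) -> int:
    """Number of distinct peak-SNP names across all loci."""
    return len({loc.snp_id for loc in loci})


def treatment_counts(loci: Iterable[Locus]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for loc in loci:
        counts[loc.treatment] = counts.get(loc.treatment, 0) + 1
    return counts


def trait_counts(loci: Iterable[Locus], treatment: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for loc in loci:
        if loc.treatment == treatment:
            counts[loc.trait] = counts.get(loc.trait, 0) + 1
    return counts


def absolute_relative_shared_snps(loci: Iterable[Locus]) -> set[str]:
    """Peak-SNP names appearing in both absolute and relative scans."""
    absolute = {loc.snp_id for loc in loci if loc.analysis == "absolute"}
    relative = {loc.snp_id for loc in loci if loc.analysis == "relative"}
    return absolute & relative


def loci_from_table(df: pd.DataFrame, cfg: PipelineConfig | None = None
                    ) -> list[Locus]:
    """Build Locus records from a cMTA table (e.g. the packaged fixture)."""
    W = cfg.gene_window_bp if cfg is not None else 50_000
    out = []
    for _, r in df.iterrows():
        major, minor = str(r["alleles"]).split(":")
        pos = int(r["pos"])
        out.append(Locus(
            locus_id=str(r["locus_id"]), trait=str(r["trait"]),
            treatment=str(r["treatment"]), experiment=str(r["experiment"]),
            snp_id=str(r["snp_name"]), chrom=int(r["chrom"]), pos=pos,
            p_value=float(r["p_value"]), major=major, minor=minor,
            allelic_effect=float(r["allelic_effect"]),
            favorable_allele=str(r["favorable_allele"]),
            window_start=max(1, pos - W), window_end=pos + W,
        ))
    return out


def loci_to_table(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = []
    for loc in loci:
        rows.append({
            "trait": loc.trait, "locus_id": loc.locus_id,
            "experiment": loc.experiment, "treatment": loc.treatment,
            "snp_name": loc.snp_id, "chrom": loc.chrom, "pos": loc.pos,
            "p_value": loc.p_value,
            "alleles": f"{loc.major}:{loc.minor}",
            "allelic_effect": loc.allelic_effect,
            "favorable_allele": loc.favorable_allele,
        })
    return pd.DataFrame(rows)
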