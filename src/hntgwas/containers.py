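"""In-memory containers shared across the pipeline.

The genotype matrix is a dense samples x markers array of minor-allele
dosages (0/1/2, NaN for missing) plus a marker map sorted by
(chromosome, position).  Phenotypes, annotation, network edges, ranks
and counts travel as validated pandas DataFrames; thin dataclasses wrap
them only where extra state (sample index, marker map) is needed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("CNT", "HNT")
EXPERIMENTS = ("E1", "E2")

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "major", "minor"]
PHENOTYPE_COLUMNS = ["genotype_id", "trait", "treatment", "experiment", "value"]
ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
NETWORK_COLUMNS = ["tf_id", "target_id", "score"]
RANK_COLUMNS = ["locus_id", "gene_id", "rank"]

#: Upper bound of the regulatory-network interaction-score scale.
MAX_INTERACTION_SCORE = 871


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix with a marker map.

    ``dosages[i, j]`` counts copies of the minor allele of marker ``j``
    in sample ``i`` (0, 1, 2, or NaN for missing).  ``markers`` has
    columns snp_id, chrom, pos, major, minor and is sorted by
    (chrom, pos); ``samples`` preserves input order.
    """

    samples: list[str]
    dosages: np.ndarray  # float64, shape (n_samples, n_markers)
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        if self.markers["snp_id"].duplicated().any():
            dup = self.markers.loc[self.markers["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicated marker IDs: {sorted(set(dup))[:5]}")
        order = self.markers[["chrom", "pos"]].apply(tuple, axis=1)
        if not order.is_monotonic_increasing:
            raise ValueError("marker map must be sorted by (chrom, pos)")
        valid = self.dosages[np.isfinite(self.dosages)]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2} (or NaN)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency, NaN-aware.

        Because dosages are minor-allele oriented the frequency is
        folded at 0.5.
        """
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            dosages=self.dosages[:, mask],
            markers=self.markers.loc[mask].reset_index(drop=True),
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing[:5]}")
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            samples=list(ids),
            dosages=self.dosages[rows],
            markers=self.markers.copy(),
        )

    def marker_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.markers["snp_id"] == snp_id).to_numpy())
        if hits.size != 1:
            raise KeyError(f"marker {snp_id!r} not found")
        return int(hits[0])


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a long phenotype table.

    Treatment labels are upper-cased and must be CNT, HNT or Relative;
    duplicate (genotype, trait, treatment, experiment) rows collapse to
    their first occurrence.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    out = df[PHENOTYPE_COLUMNS].copy()
    norm = out["treatment"].astype(str).str.upper()
    label = norm.map({"CNT": "CNT", "HNT": "HNT", "RELATIVE": "Relative"})
    bad = out.loc[label.isna(), "treatment"].unique()
    if len(bad):
        raise ValueError(f"unknown treatment labels: {list(bad)[:5]}")
    out["treatment"] = label
    out["value"] = pd.to_numeric(out["value"])
    out = out.drop_duplicates(
        subset=["genotype_id", "trait", "treatment", "experiment"], keep="first"
    ).reset_index(drop=True)
    return out


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    out = df[ANNOTATION_COLUMNS].copy()
    if out["gene_id"].duplicated().any():
        raise ValueError("duplicated gene_id in annotation")
    if (out["start"] > out["end"]).any():
        bad = out.loc[out["start"] > out["end"], "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has start > end")
    if (out["start"] < 1).any():
        raise ValueError("annotation coordinates are 1-based; start < 1 found")
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def validate_network(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"network missing columns: {missing}")
    out = df[NETWORK_COLUMNS].copy()
    scores = pd.to_numeric(out["score"])
    if not (scores == scores.round()).all():
        raise ValueError("interaction scores must be integers")
    out["score"] = scores.astype(int)
    if (out["score"] < 0).any() or (out["score"] > MAX_INTERACTION_SCORE).any():
        raise ValueError(
            f"interaction scores must lie in [0, {MAX_INTERACTION_SCORE}]"
        )
    return out.reset_index(drop=True)


def validate_ranks(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RANK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rank table missing columns: {missing}")
    out = df[RANK_COLUMNS].copy()
    out["rank"] = pd.to_numeric(out["rank"]).astype(int)
    if (out["rank"] < 1).any():
        raise ValueError("ranks are 1-based")
    dup = out.duplicated(subset=["locus_id", "rank"])
    if dup.any():
        locus = out.loc[dup, "locus_id"].iloc[0]
        raise ValueError(f"duplicate rank within locus {locus!r}")
    return out.reset_index(drop=True)
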