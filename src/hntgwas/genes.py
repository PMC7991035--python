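"""Candidate-gene extraction: annotated genes within +/-50 kb of a peak.

The gene window is the 1-based closed interval
[max(1, peak - W), peak + W]; any gene whose interval intersects it is
a candidate.  Per-gene provenance across loci distinguishes candidates
found only around absolute-trait peaks, only around relative-trait
peaks, or shared between the two analyses.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import validate_annotation
from .loci import Locus

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class LocusGeneSet:
    locus: Locus
    genes: tuple[str, ...]  # ordered by gene start

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclasses.dataclass
class CandidatePool:
    """Union of candidate genes with per-gene locus provenance."""

    table: pd.DataFrame  # gene_id, loci (list), analyses (set), shared

    @property
    def n_absolute_only(self) -> int:
        return int((self.table["provenance"] == "absolute").sum())

    @property
    def n_relative_only(self) -> int:
        return int((self.table["provenance"] == "relative").sum())

    @property
    def n_shared(self) -> int:
        return int((self.table["provenance"] == "shared").sum())

    def __len__(self) -> int:
        return len(self.table)


def genes_in_window(locus: Locus, annot: pd.DataFrame, cfg: PipelineConfig
                    ) -> LocusGeneSet:
    """Genes overlapping the closed window around the peak SNP.

    Uses a sorted-start binary search with a running maximum of gene
    ends per chromosome; any intersection with the window counts.
    """
    annot = validate_annotation(annot)
    W = cfg.gene_window_bp
    lo = max(1, locus.pos - W)
    hi = locus.pos + W
    sub = annot[annot["chrom"] == locus.chrom]
    if sub.empty:
        log.warning("locus %s: chromosome %s absent from annotation",
                    locus.locus_id, locus.chrom)
        return LocusGeneSet(locus=locus, genes=())
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    # genes sorted by start: candidates have start <= hi and end >= lo
    last = int(np.searchsorted(starts, hi, side="right"))
    hit = np.flatnonzero(ends[:last] >= lo)
    genes = tuple(sub["gene_id"].to_numpy()[:last][hit])
    return LocusGeneSet(locus=locus, genes=genes)


def pool_candidates(sets: Sequence[LocusGeneSet]) -> CandidatePool:
    """Union of locus gene sets with absolute/relative/shared provenance."""
    if not sets:
        raise ValueError("pool_candidates needs at least one locus gene set")
    rows: dict[str, dict] = {}
    for s in sets:
        for g in s.genes:
            rec = rows.setdefault(g, {"gene_id": g, "loci": [],
                                      "analyses": set()})
            rec["loci"].append(s.locus.locus_id)
            rec["analyses"].add(s.locus.analysis)
    out = []
    for g in sorted(rows):
        rec = rows[g]
        if rec["analyses"] == {"absolute", "relative"}:
            prov = "shared"
        else:
            prov = next(iter(rec["analyses"]))
        out.append({"gene_id": g, "loci": tuple(rec["loci"]),
                    "provenance": prov})
    return CandidatePool(table=pd.DataFrame(
        out, columns=["gene_id", "loci", "provenance"]))


def gene_sets_to_table(sets: Sequence[LocusGeneSet], annot: pd.DataFrame
                       ) -> pd.DataFrame:
    """Long gene table (one row per locus x gene) for the CLI writer."""
    annot = validate_annotation(annot).set_index("gene_id")
    pool = pool_candidates(sets) if sets else None
    shared = set(pool.table.loc[pool.table["provenance"] == "shared",
                                "gene_id"]) if pool else set()
    rows = []
    for s in sets:
        for g in s.genes:
            a = annot.loc[g]
            rows.append({
                "locus_id": s.locus.locus_id, "gene_id": g,
                "chrom": a["chrom"], "start": a["start"], "end": a["end"],
                "strand": a["strand"], "analysis": s.locus.analysis,
                "shared": g in shared,
            })
    return pd.DataFrame(rows, columns=["locus_id", "gene_id", "chrom",
                                       "start", "end", "strand",
                                       "analysis", "shared"])
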