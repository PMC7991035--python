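"""Pipeline configuration.

All tunable thresholds of the analysis live here: the MAF floor applied
before the association scan, the genome-wide significance threshold on
the -log10(p) scale, the clumping window that collapses significant
markers into one locus, the half-width of the candidate-gene window
around each peak SNP, and the cut-offs of the three prioritization
channels (differential expression FDR, regulatory-network interaction
score, per-locus ortholog rank).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

#: Direction of benefit per trait: +1 if a larger value is favorable
#: (yield, seed weight, harvest index), -1 if a smaller value is
#: favorable (chalkiness is a grain defect).
DEFAULT_TRAIT_DIRECTIONS: Mapping[str, int] = {
    "YPP": +1,
    "HWT": +1,
    "HI": +1,
    "CHALK": -1,
    "GW": +1,
    "GL": +1,
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and window sizes of the locus-to-gene pipeline.

    Defaults follow the analysis this package reproduces: MAF > 0.05,
    significance at -log10(p) = 3.5, 100 kb clumping, +/-50 kb gene
    windows, network interaction score >= 200, DE FDR < 0.05, and the
    top two ranked genes per locus.
    """

    maf_min: float = 0.05
    neg_log_p_threshold: float = 3.5
    clump_window_bp: int = 100_000
    gene_window_bp: int = 50_000
    network_score_min: int = 200
    de_fdr_max: float = 0.05
    rank_top_k: int = 2
    n_pcs: int = 3
    colocalization_bp: int = 100_000
    region_group_bp: int = 490_000
    seed: int = 0
    trait_directions: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAIT_DIRECTIONS)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError(f"maf_min must be in (0, 0.5), got {self.maf_min}")
        if self.neg_log_p_threshold <= 0:
            raise ValueError("neg_log_p_threshold must be positive")
        for name in ("clump_window_bp", "gene_window_bp", "colocalization_bp",
                     "region_group_bp", "network_score_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.de_fdr_max < 1.0:
            raise ValueError("de_fdr_max must be in (0, 1)")
        if self.rank_top_k < 1:
            raise ValueError("rank_top_k must be >= 1")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from a JSON file; keyword overrides win."""
        data = json.loads(Path(path).read_text())
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["trait_directions"] = dict(self.trait_directions)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
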