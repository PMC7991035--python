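"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate, at desk scale, the data the analysis consumes:

* structured diploid genotypes — subpopulation allele frequencies drawn
  around shared ancestral frequencies (Balding–Nichols style) and
  block-haplotype linkage disequilibrium, the two features a mixed
  model with kinship and principal components exists to correct;
* paired control / high-night-temperature phenotypes with planted
  additive QTLs (optionally treatment-scoped, i.e. a G x treatment
  component), a kinship-correlated polygenic background at a planted
  heritability, and iid noise;
* negative-binomial RNA-seq counts over a control/HNT x time-point x
  replicate design with planted fold changes and unequal library sizes;
* a GFF3-style gene annotation, a scored TF -> target edge list on the
  0–871 confidence scale, and per-locus candidate-gene rank tables.

One master seed deterministically derives an independent child stream
per stage, so each output is bit-reproducible and stages can be
regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MAX_INTERACTION_SCORE
from .errors import ConfigurationError

# Fixed per-stage stream identifiers: stage order never perturbs streams.
_STREAMS = {
    "genotypes": 1,
    "phenotypes": 2,
    "expression": 3,
    "annotation": 4,
    "network": 5,
    "ranks": 6,
}


@dataclasses.dataclass(frozen=True)
class QTLSpec:
    """One planted additive QTL.

    ``effect_size`` is the phenotype shift per minor-allele copy, in
    units of the background (polygenic + noise) standard deviation.
    ``treatment_scope`` restricts the effect to one treatment arm,
    which is how a genotype-by-treatment interaction is planted.
    """

    chrom: int
    pos: int
    trait: str
    treatment_scope: str = "both"  # both | HNT_only | CNT_only
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if self.treatment_scope not in ("both", "HNT_only", "CNT_only"):
            raise ConfigurationError(
                f"treatment_scope must be both/HNT_only/CNT_only, "
                f"got {self.treatment_scope!r}"
            )


@dataclasses.dataclass(frozen=True)
class DESpec:
    """One planted differentially expressed gene: gene, time point, log2FC."""

    gene: str
    time_point: str
    log2fc: float


@dataclasses.dataclass(frozen=True)
class SimConfig:
    n_samples: int = 200
    n_markers: int = 1000
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_subpops: int = 2
    fst_like_divergence: float = 0.1
    ld_block_span_bp: int = 20_000
    qtl_spec: tuple[QTLSpec, ...] = ()
    h2_polygenic: float = 0.3
    n_genes: int = 200
    de_spec: tuple[DESpec, ...] = ()
    network_density: float = 0.02
    seed: int = 0
    # secondary knobs
    traits: tuple[str, ...] = ("YPP",)
    experiments: tuple[str, ...] = ("E1",)
    trait_baseline: float = 10.0
    missing_rate: float = 0.0
    n_timepoints: int = 3
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    de_gene_mean: float = 100.0
    tf_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_markers", "n_chromosomes",
                     "chrom_length_bp", "n_subpops", "n_genes",
                     "n_timepoints", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("fst_like_divergence", "h2_polygenic"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.network_density <= 1.0:
            raise ConfigurationError("network_density must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.ld_block_span_bp < 0:
            raise ConfigurationError("ld_block_span_bp must be >= 0")
        object.__setattr__(self, "qtl_spec",
                           tuple(q if isinstance(q, QTLSpec) else QTLSpec(*q)
                                 for q in self.qtl_spec))
        object.__setattr__(self, "de_spec",
                           tuple(d if isinstance(d, DESpec) else DESpec(*d)
                                 for d in self.de_spec))
        for q in self.qtl_spec:
            if not 1 <= q.chrom <= self.n_chromosomes:
                raise ConfigurationError(
                    f"QTL chromosome {q.chrom} outside 1..{self.n_chromosomes}")
            if not 1 <= q.pos <= self.chrom_length_bp:
                raise ConfigurationError(
                    f"QTL position {q.pos} outside simulated chromosome")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic child generator for one pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(_STREAMS[stage],)))


def _marker_positions(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Sorted unique 1-based positions per chromosome, QTLs included."""
    base, extra = divmod(cfg.n_markers, cfg.n_chromosomes)
    per_chrom = [base + (1 if c < extra else 0) for c in range(cfg.n_chromosomes)]
    out = []
    for c, m in enumerate(per_chrom, start=1):
        if m > cfg.chrom_length_bp:
            raise ConfigurationError(
                f"cannot place {m} markers on a {cfg.chrom_length_bp} bp "
                f"chromosome")
        qtl_pos = sorted({q.pos for q in cfg.qtl_spec if q.chrom == c})
        if len(qtl_pos) > m:
            raise ConfigurationError(f"more QTLs than markers on chromosome {c}")
        pos: set[int] = set(qtl_pos)
        while len(pos) < m:
            pos.update(rng.integers(1, cfg.chrom_length_bp + 1,
                                    size=m - len(pos)).tolist())
        out.append(np.array(sorted(pos), dtype=int))
    return out


def generate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Structured diploid dosages with LD blocks and subpopulations.

    Each marker's ancestral frequency is uniform on (0.1, 0.9); each
    subpopulation draws its own frequency from a Beta distribution
    centred on the ancestral one with Balding–Nichols concentration
    (1 - F)/F, F = ``fst_like_divergence`` (F = 0 collapses to a single
    panmictic population).  Haplotypes within an LD block share a
    latent Gaussian factor whose per-marker loading decays with the
    marker's offset into the block, so adjacent-marker correlation
    decays with distance and vanishes across block boundaries.
    Dosages count copies of the *minor* allele.
    """
    rng = cfg.rng("genotypes")
    positions = _marker_positions(cfg, rng)
    subpop = np.arange(cfg.n_samples) % cfg.n_subpops
    letters = np.array(list("ACGT"))

    records = []
    dosage_cols = []
    F = cfg.fst_like_divergence
    for c, pos in enumerate(positions, start=1):
        m = len(pos)
        p_anc = rng.uniform(0.1, 0.9, size=m)
        if F > 0:
            conc = (1.0 - F) / F
            p_sub = rng.beta(p_anc * conc, (1.0 - p_anc) * conc,
                             size=(cfg.n_subpops, m))
            p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
        else:
            p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

        if cfg.ld_block_span_bp > 0:
            block = pos // cfg.ld_block_span_bp
            offset = pos - block * cfg.ld_block_span_bp
            loading = np.exp(-offset / cfg.ld_block_span_bp)
        else:
            block = np.arange(m)
            loading = np.ones(m)

        # latent factor per (haplotype, block); independent residual per marker
        uniq, block_idx = np.unique(block, return_inverse=True)
        z = rng.standard_normal((cfg.n_samples, 2, len(uniq)))
        eps = rng.standard_normal((cfg.n_samples, 2, m))
        latent = loading * z[:, :, block_idx] + np.sqrt(1 - loading ** 2) * eps
        thresh = stats.norm.ppf(p_sub)[subpop]  # (n_samples, m)
        alleles = latent < thresh[:, None, :]
        dose = alleles.sum(axis=1).astype(float)  # counts of allele "A1"

        pair = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
        dosage_cols.append(dose)
        records.append(pd.DataFrame({
            "snp_id": [f"Chr{c}pos{p}.1" for p in pos],
            "chrom": c,
            "pos": pos,
            "major": letters[pair[:, 0]],
            "minor": letters[pair[:, 1]],
        }))

    dosages = np.concatenate(dosage_cols, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan
    markers = pd.concat(records, ignore_index=True)

    # orient to the minor allele on the *observed* calls, so a reader
    # recomputing frequencies from emitted files agrees with the map
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    a1 = markers["major"].to_numpy().copy()
    a2 = markers["minor"].to_numpy().copy()
    markers["major"] = np.where(flip, a2, a1)
    markers["minor"] = np.where(flip, a1, a2)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(samples=samples, dosages=dosages, markers=markers)


def generate_phenotypes(cfg: SimConfig, geno: GenotypeMatrix) -> pd.DataFrame:
    """Paired CNT/HNT phenotypes with planted QTLs and polygenic background.

    For each trait and experiment, value = baseline + sum of planted
    QTL effects in scope + polygenic term + iid noise.  The polygenic
    term is Z alpha with VanRaden-centred dosages and alpha scaled so
    its covariance is h2 * K, and noise variance is 1 - h2, so the
    planted narrow-sense heritability equals ``h2_polygenic`` on the
    simulated (SD-unit) scale.  Both treatment arms share the genetic
    terms not scoped to a treatment; noise is independent per arm.
    """
    rng = cfg.rng("phenotypes")
    n, m = geno.dosages.shape
    dose = geno.dosages.copy()
    col_mean = np.nanmean(dose, axis=0)
    nan = np.isnan(dose)
    if nan.any():
        dose[nan] = np.broadcast_to(col_mean, dose.shape)[nan]

    traits = list(dict.fromkeys(list(cfg.traits) +
                                [q.trait for q in cfg.qtl_spec]))
    qtl_idx: dict[QTLSpec, int] = {}
    for q in cfg.qtl_spec:
        j = geno.marker_index(f"Chr{q.chrom}pos{q.pos}.1")
        if np.nanstd(geno.dosages[:, j]) == 0:
            raise ConfigurationError(
                f"QTL at Chr{q.chrom}:{q.pos} is monomorphic in the "
                f"simulated panel")
        qtl_idx[q] = j

    p_hat = col_mean / 2.0
    het = 2.0 * p_hat * (1.0 - p_hat)
    poly_scale = het.sum()
    Zc = dose - col_mean

    h2 = cfg.h2_polygenic
    rows = []
    for exp in cfg.experiments:
        for trait in traits:
            if h2 > 0 and poly_scale > 0:
                alpha = rng.standard_normal(m) * np.sqrt(h2 / poly_scale)
                g = Zc @ alpha
            else:
                g = np.zeros(n)
            for treatment in ("CNT", "HNT"):
                y = cfg.trait_baseline + g + rng.standard_normal(n) * np.sqrt(1 - h2)
                for q, j in qtl_idx.items():
                    if q.trait != trait:
                        continue
                    if q.treatment_scope == "HNT_only" and treatment != "HNT":
                        continue
                    if q.treatment_scope == "CNT_only" and treatment != "CNT":
                        continue
                    y = y + q.effect_size * dose[:, j]
                rows.append(pd.DataFrame({
                    "genotype_id": geno.samples,
                    "trait": trait,
                    "treatment": treatment,
                    "experiment": exp,
                    "value": y,
                }))
    return pd.concat(rows, ignore_index=True)


@dataclasses.dataclass
class CountMatrix:
    """RNA-seq counts (genes x samples) plus the sample design sheet."""

    counts: pd.DataFrame  # index gene_id, columns sample ids
    samples: pd.DataFrame  # sample_id, condition, time, replicate

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns must match the sample sheet order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


def gene_ids(cfg: SimConfig) -> list[str]:
    """Deterministic gene identifiers shared by all generators."""
    base, extra = divmod(cfg.n_genes, cfg.n_chromosomes)
    out = []
    for c in range(1, cfg.n_chromosomes + 1):
        k = base + (1 if c - 1 < extra else 0)
        out.extend(f"gene_c{c}_{i:04d}" for i in range(k))
    return out


def generate_expression(cfg: SimConfig) -> CountMatrix:
    """NB counts over a control/HNT x time x replicate flag-leaf design.

    Library sizes are geometrically spaced over a 2.5-fold range to
    exercise normalization; planted genes get their stated log2 fold
    change in the HNT arm at the stated time point.  Planted genes are
    assigned a fixed moderate baseline mean (``de_gene_mean``) so the
    planted shift is identifiable; the rest draw log-normal baselines.
    """
    rng = cfg.rng("expression")
    genes = gene_ids(cfg)
    planted = {(d.gene, d.time_point): d.log2fc for d in cfg.de_spec}
    universe = set(genes)
    for d in cfg.de_spec:
        if d.gene not in universe:
            raise ConfigurationError(f"de_spec gene {d.gene!r} not in universe")

    times = [f"T{t+1}" for t in range(cfg.n_timepoints)]
    sheet = []
    for cond in ("control", "HNT"):
        for t in times:
            for r in range(1, cfg.n_replicates + 1):
                sheet.append((f"{cond}_{t}_R{r}", cond, t, r))
    samples = pd.DataFrame(sheet, columns=["sample_id", "condition", "time",
                                           "replicate"])
    n_lib = len(samples)
    lib = np.geomspace(0.5, 1.25, num=n_lib)

    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=len(genes))
    for d in cfg.de_spec:
        base[genes.index(d.gene)] = cfg.de_gene_mean

    phi = cfg.nb_dispersion
    r_nb = 1.0 / phi
    mat = np.empty((len(genes), n_lib), dtype=int)
    for k, (sid, cond, t, _) in enumerate(samples.itertuples(index=False)):
        mu = base * lib[k]
        if cond == "HNT":
            fc = np.ones(len(genes))
            for (g, tp), l2 in planted.items():
                if tp == t:
                    fc[genes.index(g)] = 2.0 ** l2
            mu = mu * fc
        mat[:, k] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                          columns=samples["sample_id"].tolist())
    return CountMatrix(counts=counts, samples=samples)


def generate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals tiling the simulated chromosomes.

    Each chromosome is divided into equal slots, one gene per slot at a
    random offset, so every 100 kb locus window contains candidates.
    Intervals are 1-based closed, sorted by (chrom, start).
    """
    rng = cfg.rng("annotation")
    ids = gene_ids(cfg)
    rows = []
    i = 0
    base, extra = divmod(cfg.n_genes, cfg.n_chromosomes)
    for c in range(1, cfg.n_chromosomes + 1):
        k = base + (1 if c - 1 < extra else 0)
        slot = cfg.chrom_length_bp // max(k, 1)
        if slot < 10:
            raise ConfigurationError("too many genes for chromosome length")
        for s in range(k):
            lo = s * slot + 1
            length = int(rng.integers(max(2, slot // 10), max(3, slot // 2)))
            start = int(rng.integers(lo, lo + slot - length))
            rows.append({
                "gene_id": ids[i],
                "chrom": c,
                "start": start,
                "end": start + length - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
            })
            i += 1
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def generate_network(cfg: SimConfig) -> pd.DataFrame:
    """Sparse scored TF -> target edge list on the 0–871 scale.

    A ``tf_fraction`` subset of genes act as transcription factors;
    each (TF, target) pair is an edge with probability
    ``network_density``, scored uniformly on the full integer scale.
    """
    rng = cfg.rng("network")
    genes = gene_ids(cfg)
    n_tf = max(1, int(round(cfg.tf_fraction * len(genes))))
    tfs = [genes[i] for i in sorted(rng.choice(len(genes), size=n_tf,
                                               replace=False))]
    rows = []
    if cfg.network_density > 0:
        for tf in tfs:
            hit = rng.random(len(genes)) < cfg.network_density
            for j in np.flatnonzero(hit):
                if genes[j] == tf:
                    continue
                rows.append({
                    "tf_id": tf,
                    "target_id": genes[j],
                    "score": int(rng.integers(0, MAX_INTERACTION_SCORE + 1)),
                })
    return pd.DataFrame(rows, columns=["tf_id", "target_id", "score"])


def generate_ranks(locus_genes: Mapping[str, Sequence[str]],
                   missing_frac: float = 0.0,
                   unranked_loci: Sequence[str] = (),
                   seed: int = 0) -> pd.DataFrame:
    """Per-locus permutation ranks over window genes.

    ``missing_frac`` of each locus's genes are omitted (untestable in
    the rank channel); loci in ``unranked_loci`` are omitted entirely,
    emulating loci the ranking tool could not process.  Present genes
    receive a random permutation of 1..k.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus, genes in locus_genes.items():
        if locus in unranked_loci:
            continue
        genes = list(genes)
        n_keep = len(genes) - int(round(missing_frac * len(genes)))
        keep_idx = sorted(rng.choice(len(genes), size=max(n_keep, 0),
                                     replace=False)) if genes else []
        kept = [genes[i] for i in keep_idx]
        perm = rng.permutation(len(kept)) + 1
        for g, r in zip(kept, perm):
            rows.append({"locus_id": locus, "gene_id": g, "rank": int(r)})
    return pd.DataFrame(rows, columns=["locus_id", "gene_id", "rank"])
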