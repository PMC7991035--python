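"""Multi-evidence causal-gene prioritization with untestability-aware voting.

Each candidate gene is scored on three independent channels:

* **differential expression** — TMM-normalized negative-binomial exact
  tests between HNT and control at each time point, BH-corrected within
  time point; supported if FDR < 0.05 at any time point;
* **regulatory network** — supported if the gene is the target of at
  least one transcription-factor interaction with confidence score
  >= 200 on the 0–871 scale;
* **ortholog rank** — supported if a per-locus ranking tool placed the
  gene in the top two of any of its loci.

Every channel is tri-state: supported, failed, or *untestable* (the
gene could not be evaluated — absent from the expression data, the
network, or the rank table).  Untestability never counts against a
candidate: a gene is high priority if two channels support it, or if
one supports it and no testable channel failed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .containers import validate_network, validate_ranks
from .simulate import CountMatrix

log = logging.getLogger(__name__)

SUPPORTED, FAILED, UNTESTABLE = "supported", "failed", "untestable"

_MIN_DISPERSION = 1e-4
_EXACT_TOTAL_CAP = 50_000


@dataclasses.dataclass(frozen=True)
class DEResult:
    gene_id: str
    de_flag: str
    per_time: Mapping[str, tuple[float, float, float]]  # t -> (log2fc, p, fdr)


@dataclasses.dataclass(frozen=True)
class NetworkEvidence:
    gene_id: str
    net_flag: str
    n_interactions: int
    max_score: int  # -1 when no retained interaction


@dataclasses.dataclass(frozen=True)
class RankEvidence:
    gene_id: str
    rank_flag: str
    best_rank: int  # 0 when unranked
    locus_id: str


@dataclasses.dataclass(frozen=True)
class EvidenceProfile:
    gene_id: str
    loci: tuple[str, ...]
    de_flag: str
    net_flag: str
    rank_flag: str
    n_supported: int
    n_failed: int
    n_untestable: int
    priority: str  # high | low


# ---------------------------------------------------------------- TMM

def tmm_factors(counts: pd.DataFrame, log_ratio_trim: float = 0.3,
                abundance_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors per library.

    The reference is the library whose upper-quartile count rate is
    closest to the mean upper quartile.  Per library, gene-wise log2
    ratios against the reference are trimmed (30% tails by M, 5% by
    abundance A) and averaged with inverse asymptotic-variance weights.
    Factors are rescaled to geometric mean 1.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library with zero total count")
    rate = mat / lib
    uq = np.array([np.quantile(rate[:, k][mat[:, k] > 0], 0.75)
                   if (mat[:, k] > 0).any() else 0.0
                   for k in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    yr, Nr = mat[:, ref], lib[ref]
    for k in range(mat.shape[1]):
        if k == ref:
            continue
        yk, Nk = mat[:, k], lib[k]
        use = (yk > 0) & (yr > 0)
        if not use.any():
            continue
        M = np.log2((yk[use] / Nk) / (yr[use] / Nr))
        A = 0.5 * np.log2((yk[use] / Nk) * (yr[use] / Nr))
        w = (Nk - yk[use]) / (Nk * yk[use]) + (Nr - yr[use]) / (Nr * yr[use])
        mlo, mhi = np.quantile(M, [log_ratio_trim, 1 - log_ratio_trim])
        alo, ahi = np.quantile(A, [abundance_trim, 1 - abundance_trim])
        keep = (M >= mlo) & (M <= mhi) & (A >= alo) & (A <= ahi)
        if keep.any():
            factors[k] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------- NB exact testing

def _common_dispersion(pseudo: np.ndarray, groups: Sequence[np.ndarray]
                       ) -> float:
    """Method-of-moments common NB dispersion over replicate groups."""
    ests = []
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = pseudo[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        if ok.any():
            ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not ests:
        return _MIN_DISPERSION
    pooled = float(np.median(np.concatenate(ests)))
    return max(pooled, _MIN_DISPERSION)


def nb_exact_test(sum_a: int, n_a: int, sum_b: int, n_b: int,
                  dispersion: float) -> float:
    """Two-sided exact NB test of equal per-replicate means.

    Conditions on the total ``sum_a + sum_b``; replicate-group totals
    are NB with sizes n/dispersion, and the p-value sums conditional
    probabilities of splits no more likely than the observed one.
    """
    s = int(sum_a) + int(sum_b)
    if s == 0:
        return 1.0
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    if s <= _EXACT_TOTAL_CAP:
        y = np.arange(s + 1)
        mu = s / (n_a + n_b)
        p_nb = 1.0 / (1.0 + dispersion * mu)
        lp = (stats.nbinom.logpmf(y, r_a, p_nb)
              + stats.nbinom.logpmf(s - y, r_b, p_nb))
        lp = lp - logsumexp(lp)
        obs = lp[int(sum_a)]
        mask = lp <= obs + 1e-10
        return float(min(1.0, np.exp(logsumexp(lp[mask]))))
    # large totals: normal approximation on the conditional split
    mu_a = s * n_a / (n_a + n_b)
    var = s * n_a * n_b / (n_a + n_b) ** 2 * (1 + dispersion * s / (n_a + n_b))
    z = (sum_a - mu_a) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def de_test(cm: CountMatrix, cfg: PipelineConfig) -> list[DEResult]:
    """Per-time-point HNT vs control NB exact tests with BH correction.

    Counts are TMM-normalized and rescaled to a common effective
    library size before testing with a common method-of-moments
    dispersion.  A gene is *supported* if its BH FDR is below
    ``cfg.de_fdr_max`` at any time point, *untestable* if its total
    count across all libraries is below the number of libraries (no
    detectable expression), and *failed* otherwise.  Time points
    missing either condition are skipped with a warning.
    """
    counts, sheet = cm.counts, cm.samples
    factors = tmm_factors(counts)
    eff = counts.sum(axis=0).to_numpy() * factors.to_numpy()
    target = float(np.exp(np.mean(np.log(eff))))
    pseudo = counts.to_numpy(dtype=float) * (target / eff)

    genes = counts.index.to_list()
    n_lib = counts.shape[1]
    detectable = counts.sum(axis=1).to_numpy() >= n_lib

    cond = sheet["condition"].to_numpy()
    time = sheet["time"].to_numpy()
    groups = [np.flatnonzero((cond == c) & (time == t))
              for c in np.unique(cond) for t in np.unique(time)]
    phi = _common_dispersion(pseudo, groups)

    per_time: dict[str, pd.DataFrame] = {}
    for t in pd.unique(time):
        ctrl = np.flatnonzero((cond == "control") & (time == t))
        hnt = np.flatnonzero((cond == "HNT") & (time == t))
        if len(ctrl) == 0 or len(hnt) == 0:
            log.warning("time point %s lacks one condition; skipped", t)
            continue
        rounded = np.rint(pseudo).astype(np.int64)
        sum_c = rounded[:, ctrl].sum(axis=1)
        sum_h = rounded[:, hnt].sum(axis=1)
        pvals = np.ones(len(genes))
        for i in np.flatnonzero(detectable):
            pvals[i] = nb_exact_test(sum_h[i], len(hnt), sum_c[i], len(ctrl),
                                     phi)
        fdr = np.ones(len(genes))
        if detectable.any():
            fdr[detectable] = multipletests(pvals[detectable],
                                            method="fdr_bh")[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            l2fc = np.log2((sum_h / len(hnt) + 0.5) / (sum_c / len(ctrl) + 0.5))
        per_time[t] = pd.DataFrame({"log2fc": l2fc, "p": pvals, "fdr": fdr},
                                   index=genes)

    results = []
    for i, g in enumerate(genes):
        table = {t: (float(df["log2fc"].iloc[i]), float(df["p"].iloc[i]),
                     float(df["fdr"].iloc[i])) for t, df in per_time.items()}
        if not detectable[i]:
            flag = UNTESTABLE
        elif any(v[2] < cfg.de_fdr_max for v in table.values()):
            flag = SUPPORTED
        else:
            flag = FAILED
        results.append(DEResult(gene_id=g, de_flag=flag, per_time=table))
    return results


# ------------------------------------------------- network & rank channels

def network_evidence(gene_ids: Sequence[str], network: pd.DataFrame,
                     cfg: PipelineConfig) -> list[NetworkEvidence]:
    """TF->target interactions retained at the confidence-score cut-off.

    Only edges where the candidate is the *target* count; a gene absent
    from the full network (neither TF nor target of any edge) is
    untestable, a present gene with no retained incoming edge failed.
    """
    net = validate_network(network)
    nodes = set(net["tf_id"]) | set(net["target_id"])
    strong = net[net["score"] >= cfg.network_score_min]
    by_target = strong.groupby("target_id")
    out = []
    for g in gene_ids:
        if g not in nodes:
            out.append(NetworkEvidence(g, UNTESTABLE, 0, -1))
            continue
        try:
            edges = by_target.get_group(g)
        except KeyError:
            out.append(NetworkEvidence(g, FAILED, 0, -1))
            continue
        out.append(NetworkEvidence(g, SUPPORTED, len(edges),
                                   int(edges["score"].max())))
    return out


def rank_evidence(gene_loci: Mapping[str, Sequence[str]],
                  ranks: pd.DataFrame, cfg: PipelineConfig
                  ) -> list[RankEvidence]:
    """Per-locus ortholog-rank support: top-k in any containing locus.

    A gene with no rank row in any of its loci (the locus was never
    ranked, or the gene was dropped from the ranking) is untestable.
    """
    rk = validate_ranks(ranks)
    indexed = rk.set_index(["locus_id", "gene_id"])["rank"]
    out = []
    for g, loci in gene_loci.items():
        found: list[tuple[int, str]] = []
        for locus in loci:
            if (locus, g) in indexed.index:
                found.append((int(indexed.loc[(locus, g)]), locus))
        if not found:
            out.append(RankEvidence(g, UNTESTABLE, 0, ""))
            continue
        best, where = min(found)
        flag = SUPPORTED if best <= cfg.rank_top_k else FAILED
        out.append(RankEvidence(g, flag, best, where))
    return out


# ------------------------------------------------------------ integration

def vote(de_flag: str, net_flag: str, rank_flag: str) -> str:
    """Priority class from three tri-state flags.

    High priority requires either two supporting channels, or one
    supporting channel with every other channel untestable — a failure
    in any testable channel blocks single-channel promotion.
    """
    flags = (de_flag, net_flag, rank_flag)
    n_sup = flags.count(SUPPORTED)
    n_fail = flags.count(FAILED)
    if n_sup >= 2 or (n_sup >= 1 and n_fail == 0):
        return "high"
    return "low"


def integrate(gene_loci: Mapping[str, Sequence[str]],
              de: Sequence[DEResult],
              net: Sequence[NetworkEvidence],
              rank: Sequence[RankEvidence]) -> list[EvidenceProfile]:
    """Combine the three channels into sorted evidence profiles.

    Output order: supporting-channel count descending, failed count
    ascending, then gene id — independent of input order.
    """
    de_map = {r.gene_id: r.de_flag for r in de}
    net_map = {r.gene_id: r.net_flag for r in net}
    rank_map = {r.gene_id: r.rank_flag for r in rank}
    profiles = []
    for g, loci in gene_loci.items():
        flags = (de_map.get(g, UNTESTABLE), net_map.get(g, UNTESTABLE),
                 rank_map.get(g, UNTESTABLE))
        n_sup = flags.count(SUPPORTED)
        n_fail = flags.count(FAILED)
        profiles.append(EvidenceProfile(
            gene_id=g, loci=tuple(loci),
            de_flag=flags[0], net_flag=flags[1], rank_flag=flags[2],
            n_supported=n_sup, n_failed=n_fail,
            n_untestable=flags.count(UNTESTABLE),
            priority=vote(*flags)))
    profiles.sort(key=lambda p: (-p.n_supported, p.n_failed, p.gene_id))
    return profiles


def profiles_to_table(profiles: Sequence[EvidenceProfile]) -> pd.DataFrame:
    rows = [{
        "gene_id": p.gene_id, "loci": ",".join(p.loci),
        "de_flag": p.de_flag, "net_flag": p.net_flag,
        "rank_flag": p.rank_flag, "n_supported": p.n_supported,
        "priority": p.priority,
    } for p in profiles]
    return pd.DataFrame(rows, columns=["gene_id", "loci", "de_flag",
                                       "net_flag", "rank_flag",
                                       "n_supported", "priority"])
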