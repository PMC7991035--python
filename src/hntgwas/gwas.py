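"""Mixed-linear-model association scan with kinship and PC covariates.

The model for a phenotype vector y over n genotypes is

    y = mu + P beta + x_j b_j + u + e,   u ~ N(0, K sg2),  e ~ N(0, I se2)

with K the VanRaden genomic relationship matrix and P the leading
principal components of the same centred dosage matrix.  Variance
components are estimated once by REML on the null model (no marker) —
the P3D/EMMAX approximation — and every marker is then tested by
generalized least squares with a Wald t-test.  The same null fit
yields the marker-based heritability h2 = sg2 / (sg2 + se2).

All computations run in the eigenbasis of K, so the scan over markers
is a set of weighted least-squares fits that vectorize cleanly.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .config import PipelineConfig
from .containers import GenotypeMatrix, validate_phenotypes

log = logging.getLogger(__name__)

_PSD_TOL = 1e-8


@dataclasses.dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix with its sample index."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -_PSD_TOL * max(1.0, w.max()):
            raise ValueError("kinship is not positive semidefinite")


@dataclasses.dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    sigma2_g: float
    sigma2_e: float
    trait: str = ""
    treatment: str = ""
    experiment: str = ""


def compute_relative(pheno: pd.DataFrame) -> pd.DataFrame:
    """Append the stress-relative trait: HNT value / CNT value.

    For every (genotype, trait, experiment) present in both arms, a row
    with treatment ``Relative`` is added.  Genotypes missing either arm
    are skipped; genotypes with CNT = 0 are skipped with a warning (the
    ratio is undefined).
    """
    pheno = validate_phenotypes(pheno)
    wide = pheno.pivot_table(index=["genotype_id", "trait", "experiment"],
                             columns="treatment", values="value",
                             aggfunc="first")
    out_rows = []
    n_missing = n_zero = 0
    for (gid, trait, exp), row in wide.iterrows():
        cnt = row.get("CNT", np.nan)
        hnt = row.get("HNT", np.nan)
        if np.isnan(cnt) or np.isnan(hnt):
            n_missing += 1
            continue
        if cnt == 0:
            n_zero += 1
            continue
        out_rows.append((gid, trait, "Relative", exp, hnt / cnt))
    if n_missing:
        log.info("relative trait: %d genotype/trait/experiment cells missing "
                 "one treatment arm were excluded", n_missing)
    if n_zero:
        log.warning("relative trait: %d genotypes with CNT = 0 excluded "
                    "(undefined ratio)", n_zero)
    base = pheno[pheno["treatment"] != "Relative"]
    if not out_rows:
        return base.reset_index(drop=True)
    rel = pd.DataFrame(out_rows, columns=list(pheno.columns))
    return pd.concat([base, rel], ignore_index=True)


def _centered_imputed(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, column-centred dosages and per-marker allele freqs."""
    X = geno.dosages.copy()
    mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.broadcast_to(mean, X.shape)[nan]
    p = mean / 2.0
    poly = (X.std(axis=0) > 0)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    return (X - mean)[:, poly], p[poly]


def compute_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden relationship matrix: Zc Zc' / (2 * sum p(1-p)).

    Zc are mean-imputed dosages centred at 2p; the scaling makes the
    diagonal average roughly 1 + inbreeding in a panel at Hardy-
    Weinberg proportions.  Monomorphic markers are excluded.
    """
    if geno.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    Zc, p = _centered_imputed(geno)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    K = (Zc @ Zc.T) / denom
    return KinshipMatrix(samples=list(geno.samples), values=K)


def compute_pcs(geno: GenotypeMatrix, k: int) -> np.ndarray:
    """Leading principal components (n_samples x k) of centred dosages.

    Eigenvectors of the VanRaden relationship matrix ordered by
    decreasing eigenvalue, scaled to unit norm.
    """
    if k == 0:
        return np.empty((geno.n_samples, 0))
    K = compute_kinship(geno).values
    w, V = linalg.eigh(K)
    order = np.argsort(w)[::-1]
    return V[:, order[:k]]


def _reml_profile(log_delta: float, d: np.ndarray, yt: np.ndarray,
                  Xt: np.ndarray, xtx_logdet: float) -> float:
    """Negative restricted log-likelihood at variance ratio delta = se2/sg2."""
    delta = np.exp(log_delta)
    n, q = Xt.shape
    w = 1.0 / (d + delta)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    beta = np.linalg.solve(A, b)
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    sg2 = rss / (n - q)
    sign, logdet_A = np.linalg.slogdet(A)
    ll = -0.5 * ((n - q) * np.log(2 * np.pi * sg2) + np.sum(np.log(d + delta))
                 + logdet_A - xtx_logdet + (n - q))
    return -ll


def _fit_null(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """REML fit of the null mixed model; returns components and eigenbasis.

    Optimizes the profiled restricted likelihood in log(delta) on a
    coarse grid refined by bounded 1-D minimization.
    """
    n = len(y)
    d, U = linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    _, xtx_logdet = np.linalg.slogdet(X.T @ X)
    grid = np.linspace(-10.0, 10.0, 41)
    vals = [_reml_profile(g, d, yt, Xt, xtx_logdet) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(_reml_profile, bounds=(lo, hi),
                                   args=(d, yt, Xt, xtx_logdet),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    q = X.shape[1]
    w = 1.0 / (d + delta)
    Xw = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    sg2 = float(np.sum(w * r * r) / (n - q))
    se2 = sg2 * delta
    return sg2, se2, delta, d, U


def estimate_heritability(pheno_vector: np.ndarray, kinship: KinshipMatrix,
                          covariates: np.ndarray | None = None,
                          context: tuple[str, str, str] = ("", "", "")
                          ) -> HeritabilityEstimate:
    """Marker-based heritability from the null mixed model.

    h2 = sg2 / (sg2 + se2) with variance components from REML.
    """
    y = np.asarray(pheno_vector, dtype=float)
    n = len(y)
    if n != len(kinship.samples):
        raise ValueError("phenotype length does not match kinship")
    X = np.ones((n, 1))
    if covariates is not None and covariates.size:
        X = np.column_stack([X, covariates])
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    sg2, se2, _, _, _ = _fit_null(y, X, kinship.values)
    tot = sg2 + se2
    if not np.isfinite(tot) or tot <= 0:
        raise RuntimeError(
            f"heritability fit did not converge for trait {context[0]!r}")
    return HeritabilityEstimate(h2=sg2 / tot, sigma2_g=sg2, sigma2_e=se2,
                                trait=context[0], treatment=context[1],
                                experiment=context[2])


def mlm_scan(geno: GenotypeMatrix, pheno_vector: np.ndarray,
             kinship: KinshipMatrix, pcs: np.ndarray | None,
             cfg: PipelineConfig,
             fixed_components: tuple[float, float] | None = None
             ) -> pd.DataFrame:
    """P3D mixed-model scan; one GLS Wald test per marker.

    Markers with MAF < ``cfg.maf_min`` or zero variance after mean
    imputation are excluded.  ``fixed_components`` = (sg2, se2) skips
    the REML step and tests under those components (sg2 = 0 reduces the
    scan to ordinary least squares exactly).

    Returns a DataFrame with snp_id, chrom, pos, maf, beta, p,
    neg_log10_p, and r2_model (squared correlation of fixed-effect
    fitted values with the phenotype).
    """
    y = np.asarray(pheno_vector, dtype=float)
    n = geno.n_samples
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype samples")
    keep = np.isfinite(y)
    if not keep.all():
        log.info("dropping %d samples with missing phenotype", (~keep).sum())
        geno = GenotypeMatrix(
            samples=[s for s, k in zip(geno.samples, keep) if k],
            dosages=geno.dosages[keep], markers=geno.markers.copy())
        idx = np.flatnonzero(keep)
        kinship = KinshipMatrix(samples=[kinship.samples[i] for i in idx],
                                values=kinship.values[np.ix_(idx, idx)])
        if pcs is not None and pcs.size:
            pcs = pcs[keep]
        y = y[keep]
        n = len(y)

    maf = geno.maf()
    ok = maf >= cfg.maf_min
    X = geno.dosages[:, ok].copy()
    mean = np.nanmean(X, axis=0)
    nanmask = np.isnan(X)
    if nanmask.any():
        X[nanmask] = np.broadcast_to(mean, X.shape)[nanmask]
    sd = X.std(axis=0)
    nonzero = sd > 0
    if (~nonzero).any():
        log.info("dropping %d zero-variance markers after imputation",
                 int((~nonzero).sum()))
    X = X[:, nonzero]
    markers = geno.markers.loc[ok].loc[nonzero].reset_index(drop=True)
    maf = maf[ok][nonzero]

    C = np.ones((n, 1))
    if pcs is not None and pcs.size:
        C = np.column_stack([C, pcs])
    q = C.shape[1]
    if n <= q + 1:
        raise ValueError("fewer samples than model covariates")

    if fixed_components is None:
        sg2, se2, delta, d, U = _fit_null(y, C, kinship.values)
    else:
        sg2, se2 = fixed_components
        if sg2 > 0:
            d, U = linalg.eigh(kinship.values)
            d = np.clip(d, 0.0, None)
            delta = se2 / sg2
        else:
            d, U, delta = None, None, None

    if sg2 > 0:
        w = 1.0 / (d + delta)
        sw = np.sqrt(w)
        ys = sw * (U.T @ y)
        Cs = sw[:, None] * (U.T @ C)
        Xs = sw[:, None] * (U.T @ X)
    else:  # pure fixed-effect limit: ordinary least squares
        ys, Cs, Xs = y, C, X

    Q, _ = np.linalg.qr(Cs)
    ey = ys - Q @ (Q.T @ ys)
    EX = Xs - Q @ (Q.T @ Xs)
    xx = np.einsum("ij,ij->j", EX, EX)
    xy = EX.T @ ey
    beta = xy / xx
    df = n - q - 1
    rss = np.maximum(np.sum(ey * ey) - beta * xy, 0.0)
    se = np.sqrt(rss / df / xx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    # R2 of the model with the SNP: corr(fitted fixed effects, y)^2,
    # with the GLS coefficient estimates on the original scale.
    r2 = np.empty(len(beta))
    # fitted = C gamma_j + x_j beta_j ; gamma_j via GLS of (ys - xs beta) on Cs
    G = np.linalg.solve(Cs.T @ Cs, Cs.T @ (ys[:, None] - Xs * beta))
    fitted = C @ G + X * beta
    yc = y - y.mean()
    ysd = float(np.sqrt(np.sum(yc * yc)))
    for j in range(fitted.shape[1]):
        f = fitted[:, j] - fitted[:, j].mean()
        fn = float(np.sqrt(np.sum(f * f)))
        r2[j] = (float(f @ yc) / (fn * ysd)) ** 2 if fn > 0 and ysd > 0 else 0.0

    out = markers[["snp_id", "chrom", "pos"]].copy()
    out["maf"] = maf
    out["beta"] = beta
    out["p"] = p
    out["neg_log10_p"] = -np.log10(p)
    out["r2_model"] = r2
    return out


def genomic_control_lambda(p: Sequence[float]) -> float:
    """Median-based genomic-control inflation factor of a p-value set."""
    chi2 = stats.chi2.isf(np.asarray(p, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
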