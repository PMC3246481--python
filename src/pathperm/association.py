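"""Per-SNP additive-model logistic regression with cluster adjustment.

Each SNP is tested with a maximum-likelihood logistic fit of case status on
its minor-allele count plus K-1 cluster indicator covariates (reference =
first cluster in sorted label order) and any user-supplied numeric
covariates (e.g. ancestry principal components computed upstream).  The
reported statistic is the Wald z = beta / se(beta) for the per-allele
effect; |z| feeds the gene scores downstream.

A permutation run refits every SNP for every permuted phenotype vector, so
the scan is implemented as a Newton/IRLS iteration batched across SNPs: the
covariate block of the design is shared, only the genotype column differs,
and the per-SNP (p x p) Hessians are solved as one stacked system.
Samples with a missing genotype are dropped for that SNP only, implemented
as zero IRLS weights.

Non-converged fits (quasi-separation, constant genotype, iteration cap) are
flagged ``converged = False`` with NaN statistics; downstream gene scoring
drops them rather than imputing z = 0, which would deflate set statistics
unpredictably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .formats_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

GRADIENT_TOL = 1e-8
MAX_ITER = 100
#: |beta| beyond this is treated as divergence toward separation.
BETA_DIVERGED = 30.0

RESULT_COLUMNS = ["snp_id", "beta", "se", "z", "p", "n_used", "converged"]


@dataclass(frozen=True)
class SnpAssociation:
    """Result of one per-SNP logistic fit."""

    snp_id: str
    beta: float
    se: float
    z: float
    p: float
    n_used: int
    converged: bool

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def odds_ratio_ci(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.norm.ppf(0.5 + level / 2) * self.se
        return float(np.exp(self.beta - half)), float(np.exp(self.beta + half))


def cluster_design(
    clusters: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> np.ndarray:
    """Design matrix: intercept, K-1 cluster indicators, numeric covariates.

    The reference cluster is the first label in sorted order.  Constant
    covariate columns are dropped (they are absorbed by the intercept), so
    adding one never changes the genotype coefficient.
    """
    clusters = np.asarray(clusters)
    labels = sorted(set(clusters.tolist()))
    n = clusters.size
    cols = [np.ones(n)]
    for lab in labels[1:]:
        cols.append((clusters == lab).astype(float))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            col = cov[:, j]
            if np.ptp(col) == 0.0:
                logger.warning("dropping constant covariate column %d", j)
                continue
            cols.append(col)
    return np.column_stack(cols)


def _batched_logistic(
    y: np.ndarray,
    G: np.ndarray,
    C: np.ndarray,
    tol: float = GRADIENT_TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``m`` logistic models sharing covariates ``C``, one genotype each.

    Parameters
    ----------
    y : (n,) 0/1 phenotype
    G : (m, n) genotype counts, NaN = missing
    C : (n, q) shared covariates including the intercept

    Returns
    -------
    beta_g : (m,) per-allele log odds ratio
    se_g : (m,) Wald standard error
    converged : (m,) bool
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    C = np.asarray(C, dtype=float)
    m, n = G.shape
    q = C.shape[1]
    p = q + 1

    mask = np.isfinite(G)
    Gz = np.where(mask, G, 0.0)
    n_used = mask.sum(axis=1)

    # SNPs that cannot be fit at all: constant genotype or one-class outcome
    g_min = np.where(mask, G, np.inf).min(axis=1)
    g_max = np.where(mask, G, -np.inf).max(axis=1)
    y_mean = (y * mask).sum(axis=1) / np.maximum(n_used, 1)
    fittable = (n_used >= p) & (g_max > g_min) & (y_mean > 0) & (y_mean < 1)

    # outer products of covariate columns, shared by every SNP
    CC = (C[:, :, None] * C[:, None, :]).reshape(n, q * q)

    B = np.zeros((m, p))
    with np.errstate(divide="ignore"):
        B[:, 0] = np.where(fittable, np.log(y_mean / (1.0 - y_mean)), 0.0)

    converged = np.zeros(m, dtype=bool)
    H = np.zeros((m, p, p))
    for _ in range(max_iter):
        eta = B[:, :q] @ C.T + B[:, q][:, None] * Gz
        np.clip(eta, -35.0, 35.0, out=eta)
        mu = expit(eta)
        w = mu * (1.0 - mu) * mask
        resid = (y - mu) * mask

        grad = np.empty((m, p))
        grad[:, :q] = resid @ C
        grad[:, q] = (resid * Gz).sum(axis=1)

        H[:, :q, :q] = (w @ CC).reshape(m, q, q)
        Hcg = (w * Gz) @ C
        H[:, :q, q] = Hcg
        H[:, q, :q] = Hcg
        H[:, q, q] = (w * Gz * Gz).sum(axis=1)

        live = fittable & ~converged
        newly = live & (np.abs(grad).max(axis=1) < tol)
        converged |= newly
        live &= ~newly
        if not live.any():
            break

        idx = np.flatnonzero(live)
        try:
            step = np.linalg.solve(H[idx], grad[idx][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.empty((idx.size, p))
            for k, j in enumerate(idx):
                try:
                    step[k] = np.linalg.solve(H[j], grad[j])
                except np.linalg.LinAlgError:
                    step[k] = 0.0
                    fittable[j] = False  # singular information: give up
        B[idx] += step
        # runaway estimates signal (quasi-)separation
        diverged = np.abs(B[:, q]) > BETA_DIVERGED
        fittable &= ~diverged | converged

    beta_g = B[:, q].copy()
    se_g = np.full(m, np.nan)
    ok = fittable & converged
    if ok.any():
        idx = np.flatnonzero(ok)
        try:
            cov = np.linalg.inv(H[idx])
            var = cov[:, q, q]
        except np.linalg.LinAlgError:
            var = np.full(idx.size, np.nan)
            for k, j in enumerate(idx):
                try:
                    var[k] = np.linalg.inv(H[j])[q, q]
                except np.linalg.LinAlgError:
                    pass
        bad_var = ~(var > 0) | ~np.isfinite(var)
        var = np.where(bad_var, np.nan, var)
        se_g[idx] = np.sqrt(var)
        ok_idx = idx[bad_var]
        ok[ok_idx] = False

    ok &= np.isfinite(se_g) & (np.abs(beta_g) <= BETA_DIVERGED)
    beta_g[~ok] = np.nan
    se_g[~ok] = np.nan
    return beta_g, se_g, ok


class LogisticScan:
    """Prepared design for repeated scans of one panel.

    Building the genotype matrix and covariate block once lets a
    permutation run call :meth:`scan` thousands of times with only the
    phenotype vector changing.
    """

    def __init__(self, panel: GenotypePanel, covariates: np.ndarray | None = None):
        self.panel = panel
        G = panel.genotypes.T.astype(float)
        G[G == MISSING] = np.nan
        self.G = G
        cov = covariates
        if cov is None and panel.covariates is not None:
            cov = panel.covariates.to_numpy(dtype=float)
        self.C = cluster_design(panel.clusters, cov)
        self.n_used = np.isfinite(G).sum(axis=1).astype(int)
        self.snp_ids = panel.snps["snp_id"].to_numpy()
        self.y_observed = panel.case_mask.astype(float)

    def scan(self, y: np.ndarray | None = None) -> pd.DataFrame:
        """One full per-SNP scan for phenotype ``y`` (default: observed)."""
        yv = self.y_observed if y is None else np.asarray(y, dtype=float)
        beta, se, ok = _batched_logistic(yv, self.G, self.C)
        with np.errstate(invalid="ignore"):
            z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta": beta,
                "se": se,
                "z": z,
                "p": p,
                "n_used": self.n_used,
                "converged": ok,
            }
        )

    def scan_z(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fast path for permutations: (|z| with NaN where dropped, p)."""
        beta, se, ok = _batched_logistic(np.asarray(y, dtype=float), self.G, self.C)
        with np.errstate(invalid="ignore"):
            z = np.abs(beta) / se
        p = 2.0 * stats.norm.sf(z)
        z[~ok] = np.nan
        p[~ok] = np.nan
        return z, p


def fit_snp_logistic(
    phenotypes: np.ndarray,
    genotypes: np.ndarray,
    clusters: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    snp_id: str = "snp",
) -> SnpAssociation:
    """Fit a single SNP.

    ``phenotypes`` is 0/1 (1 = case); ``genotypes`` holds minor-allele
    counts with :data:`~pathperm.formats_io.MISSING` or NaN for no-calls.
    """
    y = np.asarray(phenotypes, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    if clusters is None:
        clusters = np.zeros(y.size, dtype=int)
    if len(set(np.unique(y)) - {0.0, 1.0}) > 0:
        raise ValueError("phenotypes must be coded 0/1")
    C = cluster_design(np.asarray(clusters), covariates)
    beta, se, ok = _batched_logistic(y, g[None, :], C)
    b, s = float(beta[0]), float(se[0])
    z = b / s if ok[0] else float("nan")
    p = float(2.0 * stats.norm.sf(abs(z))) if ok[0] else float("nan")
    return SnpAssociation(
        snp_id=snp_id,
        beta=b,
        se=s,
        z=z,
        p=p,
        n_used=int(np.isfinite(g).sum()),
        converged=bool(ok[0]),
    )


def association_scan(panel: GenotypePanel, covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Scan every SNP of a panel against the observed phenotypes.

    Returns one row per SNP in panel order with columns
    ``snp_id, beta, se, z, p, n_used, converged``; the identical code path
    serves permuted phenotype vectors via :class:`LogisticScan`.
    """
    scan = LogisticScan(panel, covariates)
    df = scan.scan()
    n_bad = int((~df["converged"]).sum())
    if n_bad:
        logger.warning("%d of %d SNP fits did not converge and will be dropped "
                       "from gene scoring", n_bad, len(df))
    return df
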