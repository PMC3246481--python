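"""Per-SNP quality control.

Exclusion rules, applied in a fixed precedence so every SNP receives exactly
one verdict:

1. ``excluded_callrate`` — genotype call rate strictly below ``callrate_min``
   (a SNP at exactly the threshold passes);
2. ``excluded_maf`` — pooled minor-allele frequency strictly below
   ``maf_min`` (set ``maf_min = 0`` to disable);
3. ``excluded_hwe`` — exact Hardy-Weinberg p below ``hwe_alpha`` *and* no
   cross-cluster allele-frequency heterogeneity (Pearson chi-square p above
   ``heterogeneity_alpha``).  An HWE-deviant SNP whose allele frequencies
   differ between clusters is retained, because the pooled-sample deviation
   is then attributable to stratification (the Wahlund effect) rather than
   genotyping error.

The HWE test is the conditional exact test: given the observed allele
counts, the probability of every possible heterozygote count is evaluated
and the two-sided p-value is the total probability of all outcomes no more
likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import MISSING, GenotypePanel

VERDICTS = ("pass", "excluded_callrate", "excluded_maf", "excluded_hwe")


@dataclass(frozen=True)
class QcThresholds:
    """Thresholds for :func:`apply_qc`.

    ``hwe_scope`` selects the sample used for the HWE test: ``"pooled"``
    (cases plus controls) or ``"controls_only"``.
    """

    callrate_min: float = 0.97
    hwe_alpha: float = 1e-5
    heterogeneity_alpha: float = 1e-3
    maf_min: float = 0.01
    hwe_scope: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.callrate_min <= 1.0:
            raise ValueError("callrate_min must lie in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if self.hwe_scope not in ("pooled", "controls_only"):
            raise ValueError("hwe_scope must be 'pooled' or 'controls_only'")


@dataclass
class QcReport:
    """Per-SNP QC metrics and verdicts (one row per input SNP)."""

    table: pd.DataFrame  # snp_id, call_rate, maf, hwe_p, heterogeneity_p, verdict

    @property
    def verdict_counts(self) -> dict[str, int]:
        counts = self.table["verdict"].value_counts().to_dict()
        return {v: int(counts.get(v, 0)) for v in VERDICTS}

    @property
    def n_pass(self) -> int:
        return self.verdict_counts["pass"]


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def call_rate(genotypes: np.ndarray) -> float:
    """Fraction of non-missing genotypes for one SNP."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("call_rate needs at least one sample")
    return float((g != MISSING).mean())


def minor_allele_frequency(genotypes: np.ndarray) -> float:
    """Pooled frequency of the counted allele, folded onto [0, 0.5]."""
    g = np.asarray(genotypes)
    g = g[g != MISSING]
    if g.size == 0:
        return 0.0
    f = float(g.sum()) / (2 * g.size)
    return min(f, 1.0 - f)


@lru_cache(maxsize=4096)
def _hwe_het_probabilities(n_minor: int, n_geno: int) -> tuple[np.ndarray, int]:
    """Conditional distribution of the heterozygote count.

    Given ``n_minor`` copies of the rarer allele among ``n_geno`` diploid
    genotypes, returns ``(probs, h0)`` where ``probs[i]`` is the probability
    of observing ``h0 + 2 i`` heterozygotes (the count is fixed modulo 2 by
    the allele total).  Uses the stable multiplicative recurrence; the
    result is normalised.
    """
    h0 = n_minor % 2
    hs = np.arange(h0, n_minor + 1, 2)
    probs = np.empty(hs.size)
    probs[0] = 1.0
    for i in range(hs.size - 1):
        h = hs[i]
        hom_r = (n_minor - h) // 2
        hom_c = n_geno - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        if probs[i + 1] > 1e250:  # rescale to dodge overflow at large n
            probs[: i + 2] /= probs[i + 1]
    probs /= probs.sum()
    return probs, h0


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    The p-value is the summed probability of every heterozygote count (at
    the observed allele totals) whose conditional probability does not
    exceed that of the observed count.  Symmetric in the two homozygote
    classes; a monomorphic SNP returns 1.
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_geno = n_hom_minor + n_het + n_hom_major
    if n_geno < 1:
        raise ValueError("need at least one genotype")
    n_minor = min(2 * n_hom_minor + n_het, 2 * n_hom_major + n_het)
    if n_minor == 0:
        return 1.0
    probs, h0 = _hwe_het_probabilities(n_minor, n_geno)
    p_obs = probs[(n_het - h0) // 2]
    # 1+1e-12 slack keeps ties (equal-probability outcomes) included despite
    # floating-point noise in the recurrence.
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def heterogeneity_test(minor_counts: np.ndarray, major_counts: np.ndarray) -> float:
    """Pearson chi-square for allele-frequency differences across clusters.

    ``minor_counts[k]``/``major_counts[k]`` are the allele counts in cluster
    ``k``.  Clusters with zero alleles are dropped; the degrees of freedom
    are (number of remaining clusters) - 1, so six strata give the 5-d.f.
    test.  Returns p = 1 when fewer than two informative clusters remain or
    when an allele is absent overall.
    """
    minor = np.asarray(minor_counts, dtype=float)
    major = np.asarray(major_counts, dtype=float)
    if minor.shape != major.shape:
        raise ValueError("count vectors must have equal length")
    totals = minor + major
    keep = totals > 0
    minor, major, totals = minor[keep], major[keep], totals[keep]
    k = minor.size
    if k < 2:
        return 1.0
    grand = totals.sum()
    p_minor = minor.sum() / grand
    if p_minor in (0.0, 1.0):
        return 1.0
    exp_minor = totals * p_minor
    exp_major = totals * (1.0 - p_minor)
    chi2 = float(((minor - exp_minor) ** 2 / exp_minor).sum()
                 + ((major - exp_major) ** 2 / exp_major).sum())
    return float(stats.chi2.sf(chi2, df=k - 1))


# ---------------------------------------------------------------------------
# Panel-level QC
# ---------------------------------------------------------------------------

def snp_qc_table(panel: GenotypePanel, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Compute per-SNP QC metrics and verdicts without filtering."""
    th = thresholds or QcThresholds()
    g_all = panel.genotypes
    if th.hwe_scope == "controls_only":
        g_hwe = g_all[~panel.case_mask]
    else:
        g_hwe = g_all

    clusters = panel.clusters
    cluster_labels = sorted(set(clusters))
    cluster_rows = [np.flatnonzero(clusters == c) for c in cluster_labels]

    rows = []
    for j in range(panel.n_snps):
        col = g_all[:, j]
        rate = call_rate(col)
        maf = minor_allele_frequency(col)

        hcol = g_hwe[:, j]
        hcol = hcol[hcol != MISSING]
        if hcol.size == 0:
            hwe_p = 1.0
        else:
            n2 = int((hcol == 2).sum())
            n1 = int((hcol == 1).sum())
            n0 = int((hcol == 0).sum())
            hwe_p = hwe_exact_test(n2, n1, n0)

        minor_c = np.empty(len(cluster_rows))
        major_c = np.empty(len(cluster_rows))
        for k, idx in enumerate(cluster_rows):
            sub = col[idx]
            sub = sub[sub != MISSING]
            minor_c[k] = sub.sum()
            major_c[k] = 2 * sub.size - sub.sum()
        het_p = heterogeneity_test(minor_c, major_c) if len(cluster_rows) >= 2 else 1.0

        if rate < th.callrate_min:
            verdict = "excluded_callrate"
        elif maf < th.maf_min:
            verdict = "excluded_maf"
        elif hwe_p < th.hwe_alpha and het_p > th.heterogeneity_alpha:
            verdict = "excluded_hwe"
        else:
            verdict = "pass"
        rows.append((panel.snps.at[j, "snp_id"], rate, maf, hwe_p, het_p, verdict))

    return pd.DataFrame(
        rows, columns=["snp_id", "call_rate", "maf", "hwe_p", "heterogeneity_p", "verdict"]
    )


def apply_qc(
    panel: GenotypePanel, thresholds: QcThresholds | None = None
) -> tuple[GenotypePanel, QcReport]:
    """Filter a panel down to the SNPs passing every rule.

    Returns the surviving panel (SNP order preserved) and the full report.
    Idempotent: the survivors all pass a second application.
    """
    table = snp_qc_table(panel, thresholds)
    report = QcReport(table=table)
    keep = np.flatnonzero((table["verdict"] == "pass").to_numpy())
    return panel.subset_snps(keep), report
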