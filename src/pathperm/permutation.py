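"""Within-cluster label permutation tests and calibration utilities.

The main entry point :func:`run_pathway_test` evaluates SUMSTAT and SUMSQ
for one or more gene sets and attaches empirical p-values from case-control
label permutations constrained to the geographic clusters: within every
cluster the multiset of labels is preserved exactly, so the stratified
structure of the study survives permutation.  Each permuted dataset is
analysed by the identical scan -> score -> set-statistic pipeline as the
observed data, and all sets and both statistics share the same permutation
stream (datasets are permuted, not per-set draws).

The empirical p-value follows the strict-exceedance form

    p_emp = #{permuted statistic > observed} / N,

so ties with the observed value do not count and p_emp = 0 is possible; an
opt-in flag switches to the unbiased (r+1)/(N+1) estimator.

Also here: random-gene-set type-I calibration, the exact (Clopper-Pearson)
binomial confidence interval, the analytic probability that a random gene
set contains a truly associated gene, composite genotypic LD r-squared, and
the mean-p set test (threshold-selected, LD-pruned SNPs summarised by their
mean association p-value, with smaller-is-more-extreme orientation — the
natural direction for a mean of p-values, adopted here as a documented
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import LogisticScan
from .formats_io import GenotypePanel
from .geneset import DEFAULT_FLANK_BP, GeneRegion, build_regions, map_snps_to_regions
from .synthetic_data import GeneSpec

logger = logging.getLogger(__name__)

STATISTICS = ("SUMSTAT", "SUMSQ")


@dataclass
class PermutationResult:
    """Observed statistic, its permutation distribution, and empirical p."""

    set_label: str
    statistic: str  # SUMSTAT | SUMSQ | MEANP
    observed: float
    permuted: np.ndarray
    n_perm: int
    p_emp: float

    def __post_init__(self) -> None:
        self.permuted = np.asarray(self.permuted, dtype=float)
        if self.permuted.size != self.n_perm:
            raise ValueError("permuted length must equal n_perm")


@dataclass(frozen=True)
class CalibrationResult:
    """Type-I error of the set test over random gene sets."""

    n_sets: int
    n_significant: int
    rate: float
    ci_low: float
    ci_high: float
    alpha: float
    statistic: str


# ---------------------------------------------------------------------------
# Core permutation primitives
# ---------------------------------------------------------------------------

def permute_labels_within_clusters(
    phenotypes: np.ndarray, clusters: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle labels independently inside each cluster.

    Per-cluster case counts are conserved exactly; a single-sample cluster
    keeps its label.
    """
    y = np.asarray(phenotypes)
    clusters = np.asarray(clusters)
    if y.size != clusters.size or y.size == 0:
        raise ValueError("phenotypes and clusters must be equal-length, non-empty")
    out = y.copy()
    for lab in np.unique(clusters):
        idx = np.flatnonzero(clusters == lab)
        out[idx] = y[idx][rng.permutation(idx.size)]
    return out


def empirical_pvalue(
    observed: float,
    permuted: np.ndarray,
    tail: str = "greater",
    unbiased: bool = False,
) -> float:
    """Permutation p-value by strict exceedance counting.

    ``tail="greater"`` counts permuted values strictly above the observed
    (larger statistic = more extreme, the SUMSTAT/SUMSQ orientation);
    ``"less"`` counts strictly below (the mean-p orientation).  NaN permuted
    values (degenerate permutations) never count as exceedances.
    ``unbiased=True`` selects the (r+1)/(N+1) estimator, which cannot
    return zero.
    """
    permuted = np.asarray(permuted, dtype=float)
    n = permuted.size
    if n < 1:
        raise ValueError("need at least one permuted value")
    if tail == "greater":
        r = int(np.nansum(permuted > observed))
    elif tail == "less":
        r = int(np.nansum(permuted < observed))
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    if unbiased:
        return (r + 1) / (n + 1)
    return r / n


class _RegionScorer:
    """Vectorised per-permutation region scoring over a fixed SNP mapping."""

    def __init__(self, mapping: dict[str, np.ndarray], mode: str = "max"):
        if not mapping:
            raise ValueError("no region contains any SNP")
        if mode not in ("max", "second_best"):
            raise ValueError("mode must be 'max' or 'second_best'")
        self.region_ids = list(mapping)
        self.mode = mode
        self._idx = [np.asarray(mapping[r]) for r in self.region_ids]
        self._flat = np.concatenate(self._idx)
        self._offsets = np.cumsum([0] + [a.size for a in self._idx])[:-1]
        self._single = np.array([a.size == 1 for a in self._idx])

    def scores(self, absz: np.ndarray) -> np.ndarray:
        """Region scores from an |z| vector (NaN = dropped SNP fit).

        Regions whose SNPs are all dropped score NaN and leave k for that
        permutation.
        """
        vals = np.where(np.isfinite(absz), absz, -np.inf)[self._flat]
        if self.mode == "max":
            out = np.maximum.reduceat(vals, self._offsets)
        else:
            out = np.empty(len(self._idx))
            start = 0
            for i, a in enumerate(self._idx):
                seg = np.sort(vals[start:start + a.size])
                finite = seg[np.isfinite(seg)]
                if finite.size == 0:
                    out[i] = -np.inf
                elif finite.size == 1:
                    out[i] = finite[-1]
                else:
                    out[i] = finite[-2]
                start += a.size
        out[~np.isfinite(out)] = np.nan
        return out


def _set_masks(region_ids: list[str], sets: dict[str, list[str]]) -> dict[str, np.ndarray]:
    order = {r: i for i, r in enumerate(region_ids)}
    masks = {}
    for label, members in sets.items():
        mask = np.zeros(len(region_ids), dtype=bool)
        for r in members:
            if r in order:
                mask[order[r]] = True
        if mask.any():
            masks[label] = mask
        else:
            logger.warning("set %r has no scored regions; skipped", label)
    return masks


def run_pathway_test(
    panel: GenotypePanel,
    regions: list[GeneRegion],
    sets: dict[str, list[str]] | None = None,
    n_perm: int = 5000,
    seed: int | None = None,
    mode: str = "max",
    covariates: np.ndarray | None = None,
    unbiased: bool = False,
) -> list[PermutationResult]:
    """SUMSTAT/SUMSQ set tests with within-cluster permutation p-values.

    ``sets`` maps set labels to region-id lists (default: one set holding
    every region).  The observed scan and all ``n_perm`` permuted scans run
    through the identical code path; covariates and genotypes are never
    permuted, only case-control labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scan = LogisticScan(panel, covariates)
    mapping = map_snps_to_regions(panel.snps, regions)
    scorer = _RegionScorer(mapping, mode=mode)
    if sets is None:
        sets = {"All genes": scorer.region_ids}
    masks = _set_masks(scorer.region_ids, sets)
    if not masks:
        raise ValueError("no set has any scored region")

    def set_stats(absz: np.ndarray) -> dict[str, tuple[float, float]]:
        sc = scorer.scores(absz)
        out = {}
        for label, mask in masks.items():
            s = sc[mask]
            s = s[np.isfinite(s)]
            out[label] = (float(s.sum()), float((s**2).sum()))
        return out

    absz_obs, _ = scan.scan_z(scan.y_observed)
    observed = set_stats(absz_obs)

    rng = np.random.default_rng(seed)
    y = scan.y_observed
    clusters = panel.clusters
    cluster_idx = [np.flatnonzero(clusters == lab) for lab in np.unique(clusters)]

    perm = {label: np.empty((2, n_perm)) for label in masks}
    for i in range(n_perm):
        y_perm = y.copy()
        for idx in cluster_idx:
            y_perm[idx] = y[idx][rng.permutation(idx.size)]
        absz, _ = scan.scan_z(y_perm)
        for label, (s1, s2) in set_stats(absz).items():
            perm[label][0, i] = s1
            perm[label][1, i] = s2

    results = []
    for label in masks:
        for row, stat_name in enumerate(STATISTICS):
            dist = perm[label][row]
            obs = observed[label][row]
            results.append(
                PermutationResult(
                    set_label=label,
                    statistic=stat_name,
                    observed=obs,
                    permuted=dist,
                    n_perm=n_perm,
                    p_emp=empirical_pvalue(obs, dist, "greater", unbiased),
                )
            )
    return results


# ---------------------------------------------------------------------------
# Calibration and analytic side-calculations
# ---------------------------------------------------------------------------

def binomial_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def prob_random_set_contains_associated(
    n_genome: int = 20_000,
    n_associated: int = 24,
    set_size: int = 43,
    exact: bool = False,
) -> float:
    """Probability a random gene set contains >= 1 truly associated gene.

    Default is the independent-draw approximation
    ``1 - (1 - n_associated/n_genome) ** set_size``; ``exact=True`` uses the
    hypergeometric (sampling without replacement).
    """
    if not 0 <= n_associated <= n_genome:
        raise ValueError("need 0 <= n_associated <= n_genome")
    if set_size < 0:
        raise ValueError("set_size must be >= 0")
    if set_size == 0 or n_associated == 0:
        return 0.0
    if exact:
        return float(stats.hypergeom.sf(0, n_genome, n_associated, set_size))
    return float(1.0 - (1.0 - n_associated / n_genome) ** set_size)


def random_set_calibration(
    panel: GenotypePanel,
    gene_universe: list[GeneSpec],
    n_sets: int = 100,
    genes_per_set: int = 43,
    alpha: float = 0.05,
    seed: int | None = None,
    n_perm: int = 200,
    statistic: str = "SUMSTAT",
    flank_bp: int = DEFAULT_FLANK_BP,
) -> CalibrationResult:
    """Type-I calibration: the set test applied to random gene sets.

    Each set samples ``genes_per_set`` genes without replacement from the
    universe (independently across sets), builds flanked/merged regions, and
    runs the permutation test; genes carrying no genotyped SNPs shrink k
    exactly as in the main analysis.  Returns the fraction of sets with
    ``p_emp < alpha`` and its exact binomial CI.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if genes_per_set > len(gene_universe):
        raise ValueError("universe smaller than genes_per_set")
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    rng = np.random.default_rng(seed)
    n_sig = 0
    for s in range(n_sets):
        pick = rng.choice(len(gene_universe), size=genes_per_set, replace=False)
        records = [gene_universe[i].as_record() for i in pick]
        regions = build_regions(records, flank_bp)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            results = run_pathway_test(
                panel, regions, sets=None, n_perm=n_perm, seed=sub_seed)
        except ValueError:
            logger.warning("random set %d maps to no SNPs; counted non-significant", s)
            continue
        res = next(r for r in results if r.statistic == statistic)
        if res.p_emp < alpha:
            n_sig += 1
    lo, hi = binomial_ci(n_sig, n_sets)
    return CalibrationResult(
        n_sets=n_sets, n_significant=n_sig, rate=n_sig / n_sets,
        ci_low=lo, ci_high=hi, alpha=alpha, statistic=statistic,
    )


# ---------------------------------------------------------------------------
# Mean-p set test with LD pruning
# ---------------------------------------------------------------------------

def ld_r2(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> float:
    """Composite genotypic LD: squared Pearson correlation of allele counts
    over jointly non-missing samples (missing = NaN or the panel sentinel).
    """
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    a = np.where(a < 0, np.nan, a)
    b = np.where(b < 0, np.nan, b)
    joint = np.isfinite(a) & np.isfinite(b)
    if joint.sum() < 2:
        raise ValueError("need >= 2 jointly non-missing samples")
    a, b = a[joint], b[joint]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant genotype on the jointly observed subset")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _prune_and_mean(
    pvals: np.ndarray, cand: np.ndarray, r2: np.ndarray, p_threshold: float, r2_threshold: float
) -> float:
    """Greedy LD prune by ascending p, then mean p of retained SNPs.

    ``pvals`` is the full scan p vector; ``cand`` the candidate SNP indices;
    ``r2[i, j]`` the precomputed r-squared between candidates i and j (NaN
    where undefined, treated as not in LD).  NaN statistic when nothing is
    selected.
    """
    p = pvals[cand]
    sel = np.isfinite(p) & (p <= p_threshold)
    if not sel.any():
        return float("nan")
    local = np.flatnonzero(sel)
    order = local[np.argsort(p[local], kind="stable")]
    kept: list[int] = []
    for i in order:
        if all(not (r2[i, j] > r2_threshold) for j in kept):
            kept.append(i)
    return float(np.mean(p[kept]))


def mean_p_set_test(
    panel: GenotypePanel,
    regions: list[GeneRegion],
    set_region_ids: list[str] | None = None,
    p_threshold: float = 0.05,
    r2_threshold: float = 0.5,
    n_perm: int = 1000,
    seed: int | None = None,
    covariates: np.ndarray | None = None,
    set_label: str = "All genes",
    unbiased: bool = False,
) -> PermutationResult:
    """Mean-p set test: threshold-selected, LD-pruned SNP p-values.

    SNPs in the set's regions with association p <= ``p_threshold`` are
    selected; iterating by ascending p, any later SNP with r-squared above
    ``r2_threshold`` against a retained SNP is discarded; the statistic is
    the mean p of the retained SNPs.  The permutation null repeats selection
    and pruning on every permuted scan, and significance uses the
    smaller-is-more-extreme orientation.  If no SNP is selected on the
    observed data the statistic is NaN and the result is reported
    non-significant (p_emp = 1) with a warning.
    """
    scan = LogisticScan(panel, covariates)
    mapping = map_snps_to_regions(panel.snps, regions)
    if set_region_ids is None:
        set_region_ids = list(mapping)
    cand = np.unique(np.concatenate(
        [mapping[r] for r in set_region_ids if r in mapping] or [np.empty(0, int)]
    )).astype(int)
    if cand.size == 0:
        raise ValueError("the set maps to no SNPs")

    G = panel.genotypes[:, cand].astype(float)
    G[G < 0] = np.nan
    nc = cand.size
    r2 = np.full((nc, nc), np.nan)
    for i in range(nc):
        r2[i, i] = 1.0
        for j in range(i + 1, nc):
            try:
                r2[i, j] = r2[j, i] = ld_r2(G[:, i], G[:, j])
            except ValueError:
                pass  # undefined r2: treated as not in LD

    _, p_obs = scan.scan_z(scan.y_observed)
    observed = _prune_and_mean(p_obs, cand, r2, p_threshold, r2_threshold)
    if np.isnan(observed):
        logger.warning("mean-p test: no SNP passes p <= %g on observed data; "
                       "reported non-significant", p_threshold)

    rng = np.random.default_rng(seed)
    y = scan.y_observed
    clusters = panel.clusters
    cluster_idx = [np.flatnonzero(clusters == lab) for lab in np.unique(clusters)]
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = y.copy()
        for idx in cluster_idx:
            y_perm[idx] = y[idx][rng.permutation(idx.size)]
        _, p_i = scan.scan_z(y_perm)
        permuted[i] = _prune_and_mean(p_i, cand, r2, p_threshold, r2_threshold)

    if np.isnan(observed):
        p_emp = 1.0
    else:
        p_emp = empirical_pvalue(observed, permuted, tail="less", unbiased=unbiased)
    return PermutationResult(
        set_label=set_label, statistic="MEANP", observed=observed,
        permuted=permuted, n_perm=n_perm, p_emp=p_emp,
    )
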