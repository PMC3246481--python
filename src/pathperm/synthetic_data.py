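"""Synthetic stratified case-control genotype panels.

The generator emulates the structure the downstream analysis assumes: a
multi-centre case-control study whose samples fall into geographic clusters
with differing allele frequencies, SNPs grouped into gene regions, optional
causal SNPs acting through an additive logistic model, per-SNP missingness,
and Hardy-Weinberg-violating SNPs.

Genotypes are drawn per cluster as binomial(2, f) counts of the minor
allele, optionally distorted by an inbreeding-style coefficient F that
rescales the heterozygote probability by (1 - F) — a single monotone knob
for HWE violation.  Phenotypes are assigned by rejection sampling against

    logit P(case) = baseline + sum_j beta_j * g_j

until each cluster's exact case and control quotas are filled, matching a
quota-based case-control design.  Minor-allele orientation is fixed at
generation time: allele 'A' is minor, 'G' major by convention, so
allele-recoding behaviour stays explicit in tests.

SNPs are independent by default; ``tag_of`` lets a SNP copy another with a
target correlation, provided only so LD pruning is exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import MISSING, GenotypePanel, RegionRecord
from . import qc as _qc

#: Draws attempted per cluster before generation is declared infeasible.
MAX_DRAWS_PER_CLUSTER = 1_000_000


class GenerationError(RuntimeError):
    """Raised when a quota or fixture constraint cannot be satisfied."""


@dataclass(frozen=True)
class ClusterSpec:
    label: str
    n_cases: int
    n_controls: int
    baseline_log_odds: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError(f"cluster {self.label}: negative quota")


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP.

    ``maf`` is a single frequency or a per-cluster mapping; frequencies must
    be strictly inside (0, 1).  ``effect_log_odds_ratio`` is the per-allele
    log odds ratio beta; ``hwe_inbreeding`` is F in [-1, 1]; ``tag_of``
    names another SNP this one tags with squared correlation ~``tag_r2``.
    """

    snp_id: str
    gene_symbol: str | None = None
    maf: float | Mapping[str, float] = 0.3
    effect_log_odds_ratio: float = 0.0
    missing_rate: float = 0.0
    hwe_inbreeding: float = 0.0
    chrom: str | None = None
    pos: int | None = None
    tag_of: str | None = None
    tag_r2: float = 1.0

    def maf_in(self, cluster: str) -> float:
        f = self.maf[cluster] if isinstance(self.maf, Mapping) else self.maf
        if not 0.0 < f < 1.0:
            raise ValueError(f"{self.snp_id}: frequency {f} outside (0,1)")
        return float(f)


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    chrom: str
    start: int
    end: int
    subgroups: tuple[str, ...] = ()

    def as_record(self) -> RegionRecord:
        return RegionRecord(self.symbol, self.chrom, self.start, self.end, self.subgroups)


@dataclass
class SimulationConfig:
    clusters: Sequence[ClusterSpec]
    snp_specs: Sequence[SnpSpec]
    gene_specs: Sequence[GeneSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not self.clusters:
            raise ValueError("need at least one cluster")
        if not self.snp_specs:
            raise ValueError("need at least one SNP")
        labels = [c.label for c in self.clusters]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate cluster labels")
        ids = [s.snp_id for s in self.snp_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        genes = {g.symbol for g in self.gene_specs}
        for s in self.snp_specs:
            if s.gene_symbol is not None and s.gene_symbol not in genes:
                raise ValueError(f"{s.snp_id}: gene {s.gene_symbol} not in gene_specs")
            if s.gene_symbol is None and (s.chrom is None or s.pos is None):
                raise ValueError(f"{s.snp_id}: intergenic SNPs need explicit chrom/pos")
            if not 0.0 <= s.missing_rate < 1.0:
                raise ValueError(f"{s.snp_id}: missing_rate outside [0,1)")
            if not -1.0 <= s.hwe_inbreeding <= 1.0:
                raise ValueError(f"{s.snp_id}: inbreeding coefficient outside [-1,1]")
            for c in self.clusters:
                s.maf_in(c.label)
            if s.tag_of is not None and s.tag_of not in ids:
                raise ValueError(f"{s.snp_id}: tag_of target {s.tag_of} unknown")

    def region_records(self) -> list[RegionRecord]:
        return [g.as_record() for g in self.gene_specs]


def _genotype_probs(f: float, F: float) -> np.ndarray:
    """Genotype distribution (P0, P1, P2) under inbreeding coefficient F."""
    het = 2.0 * f * (1.0 - f) * (1.0 - F)
    # F > 0 moves mass from heterozygotes to homozygotes in HW proportion
    dev = f * (1.0 - f) * F
    p2 = f * f + dev
    p0 = (1.0 - f) ** 2 + dev
    probs = np.array([p0, het, p2])
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def _snp_positions(config: SimulationConfig) -> list[tuple[str, int]]:
    """Assign (chrom, pos) to each SNP, spacing gene SNPs across their span."""
    by_gene: dict[str, list[int]] = {}
    for i, s in enumerate(config.snp_specs):
        if s.gene_symbol is not None and s.pos is None:
            by_gene.setdefault(s.gene_symbol, []).append(i)
    genes = {g.symbol: g for g in config.gene_specs}
    placed: dict[int, tuple[str, int]] = {}
    for sym, idxs in by_gene.items():
        g = genes[sym]
        span = max(g.end - g.start, 1)
        for k, i in enumerate(idxs):
            pos = g.start + (k + 1) * span // (len(idxs) + 1)
            placed[i] = (g.chrom, pos)
    out = []
    for i, s in enumerate(config.snp_specs):
        if s.pos is not None:
            out.append((s.chrom or genes[s.gene_symbol].chrom, int(s.pos)))
        else:
            out.append(placed[i])
    return out


def generate_panel(config: SimulationConfig) -> GenotypePanel:
    """Draw a complete panel; bitwise-reproducible from ``config.seed``.

    Raises :class:`GenerationError` if a cluster's case or control quota
    cannot be filled within :data:`MAX_DRAWS_PER_CLUSTER` draws (e.g. a
    baseline log-odds so extreme that one class never appears).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = list(config.snp_specs)
    m = len(specs)
    betas = np.array([s.effect_log_odds_ratio for s in specs])
    tag_idx = {s.snp_id: i for i, s in enumerate(specs)}

    geno_blocks: list[np.ndarray] = []
    pheno_blocks: list[np.ndarray] = []
    sample_rows: list[tuple[str, str, str]] = []

    for cl in config.clusters:
        need_cases, need_controls = cl.n_cases, cl.n_controls
        if need_cases + need_controls < 2:
            raise ValueError(f"cluster {cl.label}: need at least 2 samples")
        cum = np.empty((m, 2))
        for j, s in enumerate(specs):
            probs = _genotype_probs(s.maf_in(cl.label), s.hwe_inbreeding)
            cum[j] = (probs[0], probs[0] + probs[1])

        cases: list[np.ndarray] = []
        controls: list[np.ndarray] = []
        drawn = 0
        while (len(cases) < need_cases or len(controls) < need_controls):
            if drawn >= MAX_DRAWS_PER_CLUSTER:
                raise GenerationError(
                    f"cluster {cl.label}: quotas unfilled after {drawn} draws "
                    f"({len(cases)}/{need_cases} cases, {len(controls)}/{need_controls} controls)"
                )
            batch = int(min(
                max(256, 4 * (need_cases + need_controls)),
                MAX_DRAWS_PER_CLUSTER - drawn,
            ))
            drawn += batch
            u = rng.random((batch, m))
            g = (u >= cum[:, 0]).astype(np.int8) + (u >= cum[:, 1]).astype(np.int8)
            for j, s in enumerate(specs):  # tagged SNPs copy their target
                if s.tag_of is not None:
                    src = g[:, tag_idx[s.tag_of]]
                    copy = rng.random(batch) < np.sqrt(max(0.0, min(1.0, s.tag_r2)))
                    g[:, j] = np.where(copy, src, g[:, j])
            eta = cl.baseline_log_odds + g @ betas
            p_case = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            is_case = rng.random(batch) < p_case
            for row, case in zip(g, is_case):
                if case and len(cases) < need_cases:
                    cases.append(row)
                elif not case and len(controls) < need_controls:
                    controls.append(row)
        block = np.vstack(cases + controls) if (cases or controls) else np.empty((0, m), np.int8)
        geno_blocks.append(block)
        pheno_blocks.append(np.array(["case"] * need_cases + ["control"] * need_controls))
        sample_rows += [
            (f"{cl.label}_{i:05d}", p, cl.label)
            for i, p in enumerate(pheno_blocks[-1])
        ]

    genotypes = np.vstack(geno_blocks).astype(np.int8)
    n = genotypes.shape[0]
    for j, s in enumerate(specs):
        if s.missing_rate > 0.0:
            mask = rng.random(n) < s.missing_rate
            genotypes[mask, j] = MISSING

    positions = _snp_positions(config)
    snps = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in specs],
            "chrom": [c for c, _ in positions],
            "pos": [p for _, p in positions],
            "minor_allele": "A",
            "major_allele": "G",
        }
    )
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "phenotype", "cluster"])
    return GenotypePanel(genotypes=genotypes, snps=snps, samples=samples)


# ---------------------------------------------------------------------------
# Ready-made study configurations
# ---------------------------------------------------------------------------

def study_config(
    n_clusters: int = 2,
    cases_per_cluster: int = 100,
    controls_per_cluster: int = 100,
    n_genes: int = 6,
    snps_per_gene: int = 2,
    causal_beta: float = 0.0,
    n_causal: int = 1,
    maf_low: float = 0.15,
    maf_high: float = 0.45,
    cluster_maf_spread: float = 0.05,
    seed: int = 0,
) -> SimulationConfig:
    """A compact stratified study: genes on distinct chromosomes, SNPs evenly
    spaced, per-cluster MAFs jittered by ``cluster_maf_spread`` to mimic
    geographic differentiation.  The first ``n_causal`` SNPs of gene 1 get
    ``causal_beta``; everything else is null.
    """
    rng = np.random.default_rng(seed)
    labels = [f"C{i + 1}" for i in range(n_clusters)]
    clusters = [ClusterSpec(lab, cases_per_cluster, controls_per_cluster) for lab in labels]
    genes = [
        GeneSpec(f"G{g + 1:03d}", chrom=str(g % 22 + 1), start=1_000_000 * (g + 1),
                 end=1_000_000 * (g + 1) + 50_000)
        for g in range(n_genes)
    ]
    snps = []
    k = 0
    for g in range(n_genes):
        for _ in range(snps_per_gene):
            base = rng.uniform(maf_low, maf_high)
            mafs = {
                lab: float(np.clip(base + rng.uniform(-cluster_maf_spread, cluster_maf_spread),
                                   0.02, 0.98))
                for lab in labels
            }
            beta = causal_beta if (g == 0 and k < n_causal) else 0.0
            snps.append(SnpSpec(f"rs{k + 1:05d}", gene_symbol=genes[g].symbol,
                                maf=mafs, effect_log_odds_ratio=beta))
            k += 1
    return SimulationConfig(clusters=clusters, snp_specs=snps, gene_specs=genes, seed=seed)


def make_qc_fixture(
    n_total_snps: int,
    n_low_callrate: int,
    n_hwe_violating: int,
    seed: int,
    n_clusters: int = 6,
    samples_per_cluster: int = 100,
) -> GenotypePanel:
    """A panel with exact QC bookkeeping, for testing the exclusion rules.

    Exactly ``n_low_callrate`` SNPs have call rate strictly below 0.97,
    exactly ``n_hwe_violating`` SNPs have exact-HWE p < 1e-5 with
    cross-cluster homogeneous allele frequencies (heterogeneity p > 0.001),
    and every other SNP passes all filters.  HWE violation is an extreme
    heterozygote deficit (F = 0.95) applied identically in all clusters;
    constructed SNPs are verified against the QC statistics and redrawn a
    bounded number of times, so the guarantees are exact, not probabilistic.
    """
    if n_low_callrate + n_hwe_violating > n_total_snps:
        raise ValueError("violating SNP counts exceed the SNP total")
    rng = np.random.default_rng(seed)
    n = n_clusters * samples_per_cluster
    half = samples_per_cluster // 2
    clusters = np.repeat([f"C{i + 1}" for i in range(n_clusters)], samples_per_cluster)
    # phenotype is irrelevant to QC; split each cluster half and half
    phen = np.tile(
        ["case"] * half + ["control"] * (samples_per_cluster - half), n_clusters
    )

    kinds = (["callrate"] * n_low_callrate + ["hwe"] * n_hwe_violating
             + ["pass"] * (n_total_snps - n_low_callrate - n_hwe_violating))
    rng.shuffle(kinds)

    cluster_slices = [
        slice(i * samples_per_cluster, (i + 1) * samples_per_cluster)
        for i in range(n_clusters)
    ]
    genotypes = np.empty((n, n_total_snps), dtype=np.int8)
    max_tries = 200
    for j, kind in enumerate(kinds):
        for _ in range(max_tries):
            f = rng.uniform(0.15, 0.40)
            F = 0.95 if kind == "hwe" else 0.0
            probs = _genotype_probs(f, F)
            cum0, cum1 = probs[0], probs[0] + probs[1]
            u = rng.random(n)
            col = ((u >= cum0).astype(np.int8) + (u >= cum1).astype(np.int8))
            if kind == "callrate":
                # strictly below 0.97: at least floor(0.03 n) + 1 no-calls
                lo = int(np.floor(0.03 * n)) + 1
                n_miss = int(rng.integers(lo, min(n, 2 * lo) + 1))
            else:
                n_miss = int(rng.integers(0, int(0.03 * n) + 1))  # rate >= 0.97
            if n_miss:
                miss_idx = rng.choice(n, size=n_miss, replace=False)
                col[miss_idx] = MISSING

            if _fixture_column_ok(col, kind, cluster_slices, n):
                genotypes[:, j] = col
                break
        else:
            raise GenerationError(
                f"could not construct a '{kind}' SNP in {max_tries} attempts"
            )

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:05d}" for j in range(n_total_snps)],
            "chrom": "1",
            "pos": np.arange(1, n_total_snps + 1) * 10_000,
            "minor_allele": "A",
            "major_allele": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1:05d}" for i in range(n)],
            "phenotype": phen,
            "cluster": clusters,
        }
    )
    return GenotypePanel(genotypes=genotypes, snps=snps, samples=samples)


def _fixture_column_ok(col, kind, cluster_slices, n) -> bool:
    """Check a candidate fixture SNP against its target QC verdict.

    Margins (e.g. HWE p below 1e-6 rather than 1e-5) keep the fixture's
    guarantees away from the decision boundaries.
    """
    obs = col[col != MISSING]
    rate = obs.size / n
    maf = _qc.minor_allele_frequency(col)
    if maf < 0.05:
        return False
    hwe_p = _qc.hwe_exact_test(int((obs == 2).sum()), int((obs == 1).sum()),
                               int((obs == 0).sum()))
    minor_c = np.array([
        col[sl][col[sl] != MISSING].sum() for sl in cluster_slices
    ], dtype=float)
    tot_c = np.array([
        2 * (col[sl] != MISSING).sum() for sl in cluster_slices
    ], dtype=float)
    het_p = _qc.heterogeneity_test(minor_c, tot_c - minor_c)

    if kind == "callrate":
        return rate < 0.97
    if kind == "hwe":
        return rate >= 0.97 and hwe_p < 1e-6 and het_p > 0.01
    return rate >= 0.97 and hwe_p > 1e-3
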