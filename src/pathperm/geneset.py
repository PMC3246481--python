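"""Gene regions, SNP-to-region mapping, gene scores and set statistics.

Each candidate gene interval is extended by a flank (default 100 kb) on
both sides, floored at position 1; flanked intervals on the same chromosome
that overlap or abut are merged transitively, the merged region spanning
the union and carrying the union of the members' subgroup labels.  A SNP
maps to a region iff ``start <= pos <= end`` on the same chromosome
(1-based inclusive); merged regions are disjoint, so every SNP maps to at
most one region.

Per-region ("gene") scores take the maximally associated SNP: score =
max |z| over the region's converged SNP fits, with a ``second_best`` mode
using the second-largest |z| (a single-SNP region falls back to its only
|z|).  Set statistics over the k scored regions of a set are
SUMSTAT = sum |z_i| and SUMSQ = sum z_i^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .formats_io import RegionRecord, read_region_file

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 100_000


@dataclass(frozen=True)
class GeneRegion:
    """A flanked, merged genomic interval (1-based inclusive)."""

    region_id: str
    genes: tuple[str, ...]
    chrom: str
    start: int
    end: int
    subgroups: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.region_id}: start > end")
        if not self.genes:
            raise ValueError("a region must contain at least one gene")


@dataclass(frozen=True)
class SetStatistics:
    """SUMSTAT and SUMSQ over the k scored regions of one set."""

    label: str
    k: int
    sumstat: float
    sumsq: float

    def __post_init__(self) -> None:
        # Cauchy-Schwarz sanity: both fail only through a scoring bug
        if self.sumstat < 0 or self.sumsq < 0:
            raise ValueError("set statistics must be non-negative")
        tol = 1e-9 * max(1.0, self.sumstat**2)
        if self.sumsq > self.sumstat**2 + tol:
            raise ValueError("SUMSQ exceeds SUMSTAT^2")
        if self.sumstat**2 > self.k * self.sumsq + tol:
            raise ValueError("SUMSTAT^2 exceeds k * SUMSQ")


def build_regions(
    records: list[RegionRecord], flank_bp: int = DEFAULT_FLANK_BP
) -> list[GeneRegion]:
    """Flank each gene by ``flank_bp`` and merge overlapping-or-abutting spans.

    Merging is transitive within a chromosome and independent of the input
    order; output is sorted by chromosome label then start.  Region ids join
    the member gene symbols with ``/`` in genomic order.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    by_chrom: dict[str, list[RegionRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    regions: list[GeneRegion] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene))
        cur: list[RegionRecord] = []
        cur_start = cur_end = 0
        for rec in recs:
            s = max(1, rec.start - flank_bp)
            e = rec.end + flank_bp
            if cur and s <= cur_end + 1:  # overlap or abut
                cur.append(rec)
                cur_end = max(cur_end, e)
            else:
                if cur:
                    regions.append(_close_region(cur, chrom, cur_start, cur_end))
                cur = [rec]
                cur_start, cur_end = s, e
        if cur:
            regions.append(_close_region(cur, chrom, cur_start, cur_end))
    return regions


def _close_region(members: list[RegionRecord], chrom: str, start: int, end: int) -> GeneRegion:
    genes = tuple(r.gene for r in members)
    subgroups = frozenset(s for r in members for s in r.subgroups)
    return GeneRegion(
        region_id="/".join(genes), genes=genes, chrom=chrom,
        start=start, end=end, subgroups=subgroups,
    )


def load_bundled_gene_table() -> list[RegionRecord]:
    """The packaged table of 43 tumour-immunosuppression candidate genes.

    Coordinates are approximate build-36 spans (see the file header); with
    the default 100 kb flank they merge into 39 regions.
    """
    path = resources.files("pathperm.data") / "immunosuppression_genes.tsv"
    with resources.as_file(path) as p:
        return read_region_file(p)


def map_snps_to_regions(
    snps: pd.DataFrame, regions: list[GeneRegion]
) -> dict[str, np.ndarray]:
    """Map panel SNPs onto regions.

    Returns ``{region_id: array of SNP row indices}`` in region order,
    containing only regions with at least one SNP; empty regions are
    dropped from scoring with a logged notice (this is what shrinks k for
    random gene sets whose genes carry no genotyped SNPs).
    """
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    mapping: dict[str, np.ndarray] = {}
    n_empty = 0
    for region in regions:
        hit = np.flatnonzero((chrom == region.chrom) & (pos >= region.start) & (pos <= region.end))
        if hit.size:
            mapping[region.region_id] = hit
        else:
            n_empty += 1
    if n_empty:
        logger.info("%d of %d regions contain no SNPs and are dropped from scoring",
                    n_empty, len(regions))
    return mapping


def score_genes(
    associations: pd.DataFrame,
    mapping: dict[str, np.ndarray],
    mode: str = "max",
) -> pd.DataFrame:
    """Per-region scores from a SNP association scan.

    ``mode="max"`` scores each region by its largest |z|; ``"second_best"``
    by the second largest (single-SNP regions fall back to their only |z|).
    Non-converged SNPs are dropped; a region with no usable SNP is dropped
    from the output with a warning.  Ties on |z| break toward the earlier
    SNP in panel order, affecting only ``best_snp_id``.

    Output columns: region_id, best_snp_id, score, n_snps, n_snps_p05, min_p.
    """
    if mode not in ("max", "second_best"):
        raise ValueError("mode must be 'max' or 'second_best'")
    absz = np.abs(associations["z"].to_numpy(dtype=float))
    pvals = associations["p"].to_numpy(dtype=float)
    ok = associations["converged"].to_numpy(dtype=bool)
    snp_ids = associations["snp_id"].to_numpy()

    rows = []
    for region_id, idx in mapping.items():
        usable = idx[ok[idx]]
        if usable.size == 0:
            logger.warning("region %s: no converged SNP fit; dropped from k", region_id)
            continue
        vals = absz[usable]
        order = np.argsort(-vals, kind="stable")  # stable: ties keep panel order
        best = usable[order[0]]
        if mode == "second_best" and usable.size >= 2:
            score_idx = usable[order[1]]
        else:
            if mode == "second_best":
                logger.info("region %s has one SNP; second_best falls back to it", region_id)
            score_idx = best
        rows.append(
            (
                region_id,
                snp_ids[best],
                float(absz[score_idx]),
                int(idx.size),
                int((pvals[usable] <= 0.05).sum()),
                float(np.min(pvals[usable])),
            )
        )
    return pd.DataFrame(
        rows, columns=["region_id", "best_snp_id", "score", "n_snps", "n_snps_p05", "min_p"]
    )


def set_statistics(
    scores: pd.DataFrame, member_region_ids: list[str] | None = None, label: str = "All genes"
) -> SetStatistics:
    """SUMSTAT/SUMSQ over the scored regions of one set.

    ``member_region_ids = None`` means the full set.  Subgroup sets reuse
    the same per-region scores; nothing is refit.
    """
    if member_region_ids is None:
        sub = scores
    else:
        sub = scores[scores["region_id"].isin(member_region_ids)]
    if len(sub) == 0:
        raise ValueError(f"set {label!r} has no scored regions")
    s = sub["score"].to_numpy(dtype=float)
    return SetStatistics(label=label, k=int(s.size), sumstat=float(s.sum()), sumsq=float((s**2).sum()))


def subgroup_sets(regions: list[GeneRegion]) -> dict[str, list[str]]:
    """Named sets: the full set plus one per subgroup label present."""
    sets: dict[str, list[str]] = {"All genes": [r.region_id for r in regions]}
    from .formats_io import SUBGROUP_LABELS

    for lab in SUBGROUP_LABELS:
        members = [r.region_id for r in regions if lab in r.subgroups]
        if members:
            sets[lab] = members
    return sets
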