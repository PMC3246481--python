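"""Readers and writers for the text formats the pipeline touches.

Genotypes travel as PLINK-style text pedigree/map pairs; gene regions as a
tab-separated table.  Coordinates are 1-based inclusive throughout (the map
file convention); any half-open arithmetic is internal to callers.

Cluster membership (the geographic stratum used both as a regression
covariate and as the permutation block) is carried in the pedigree family-ID
column, so a panel is portable as a single ped/map pair.

X-chromosome genotypes are treated as ordinary autosomal minor-allele
counts.  No special hemizygosity coding is applied; male X genotypes are
whatever the pedigree file says (0/2 under the usual homozygous coding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in the count matrix.
MISSING: int = -1

#: Vocabulary of functional subgroup labels a gene region may carry.
SUBGROUP_LABELS: tuple[str, ...] = ("Treg", "Anergy", "Costim", "tDC", "Secreted")

PHENOTYPE_CODES = {"1": "control", "2": "case"}


class FormatError(ValueError):
    """Malformed input file (carries the offending line number)."""


@dataclass
class GenotypePanel:
    """A case-control genotype panel: minor-allele counts plus metadata.

    Attributes
    ----------
    genotypes
        ``(n_samples, n_snps)`` int8 matrix of minor-allele counts in
        ``{0, 1, 2}``; :data:`MISSING` marks no-calls.
    snps
        One row per SNP: ``snp_id, chrom, pos, minor_allele, major_allele``.
    samples
        One row per sample: ``sample_id, phenotype`` (``"case"`` or
        ``"control"``) and ``cluster`` (the geographic stratum label).
    covariates
        Optional numeric covariates (e.g. principal components supplied by
        the user), row-aligned with ``samples``.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["phenotype"] == "case").to_numpy()

    @property
    def clusters(self) -> np.ndarray:
        return self.samples["cluster"].to_numpy()

    def validate(self) -> None:
        n_s, n_v = self.genotypes.shape
        if len(self.samples) != n_s:
            raise ValueError(
                f"sample metadata rows ({len(self.samples)}) != matrix rows ({n_s})"
            )
        if len(self.snps) != n_v:
            raise ValueError(
                f"snp metadata rows ({len(self.snps)}) != matrix columns ({n_v})"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype matrix holds values outside {0,1,2,missing}")
        if n_v and (self.snps["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1 (1-based)")
        if not self.samples["phenotype"].isin(("case", "control")).all():
            raise ValueError("every sample needs phenotype 'case' or 'control'")
        if self.samples["cluster"].isna().any():
            raise ValueError("every sample needs a cluster label")
        if self.covariates is not None and len(self.covariates) != n_s:
            raise ValueError("covariate rows must match sample count")

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the SNP columns in ``index`` (order kept)."""
        return GenotypePanel(
            genotypes=self.genotypes[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            samples=self.samples,
            covariates=self.covariates,
        )


@dataclass(frozen=True)
class RegionRecord:
    """One row of a gene-region definition file."""

    gene: str
    chrom: str
    start: int
    end: int
    subgroups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene}: start must be >= 1")
        unknown = set(self.subgroups) - set(SUBGROUP_LABELS)
        if unknown:
            raise ValueError(f"{self.gene}: unknown subgroup label(s) {sorted(unknown)}")


# ---------------------------------------------------------------------------
# PLINK-style text pedigree / map
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypePanel:
    """Read a text pedigree/map pair into a :class:`GenotypePanel`.

    The pedigree dialect: ``FID IID PAT MAT SEX PHENO`` followed by two
    allele fields per SNP; ``0`` is the missing-allele code, phenotype ``1``
    is control and ``2`` case.  The family ID column carries the cluster
    label.  The minor allele is determined empirically from pooled counts;
    at an exact 0.5 frequency the lexicographically smaller allele is taken
    as minor, and for a monomorphic SNP the absent allele is recorded as
    ``"."`` with all counts 0.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)

    sample_rows: list[tuple[str, str, str]] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            fid, iid, _pat, _mat, _sex, pheno = parts[:6]
            if pheno not in PHENOTYPE_CODES:
                raise FormatError(
                    f"{ped_path}:{lineno}: phenotype code {pheno!r} (need 1=control, 2=case)"
                )
            sample_rows.append((iid, PHENOTYPE_CODES[pheno], fid))
            alleles = parts[6:]
            allele_pairs.append(list(zip(alleles[0::2], alleles[1::2])))

    n_samples = len(sample_rows)
    genotypes = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    snp_meta = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        counts: dict[str, int] = {}
        for i in range(n_samples):
            a, b = allele_pairs[i][j]
            if a == "0" or b == "0":
                continue
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        minor, major = _orient_alleles(counts)
        for i in range(n_samples):
            a, b = allele_pairs[i][j]
            if a == "0" or b == "0":
                continue
            genotypes[i, j] = (a == minor) + (b == minor)
        snp_meta.append((snp_id, chrom, pos, minor, major))

    snps = pd.DataFrame(snp_meta, columns=["snp_id", "chrom", "pos", "minor_allele", "major_allele"])
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "phenotype", "cluster"])
    return GenotypePanel(genotypes=genotypes, snps=snps, samples=samples)


def _orient_alleles(counts: dict[str, int]) -> tuple[str, str]:
    """(minor, major) from pooled allele counts; lexicographic tie-break."""
    if not counts:
        return ".", "."
    if len(counts) == 1:
        (major,) = counts
        return ".", major
    if len(counts) > 2:
        raise FormatError(f"more than two alleles observed: {sorted(counts)}")
    (a1, n1), (a2, n2) = sorted(counts.items())  # lexicographic order
    if n1 == n2:
        return a1, a2  # tie: smaller allele is minor
    return (a1, a2) if n1 < n2 else (a2, a1)


def write_plink_text(panel: GenotypePanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel back out as a pedigree/map pair (inverse of the reader)."""
    with open(map_path, "w") as fh:
        for row in panel.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")

    pheno_out = {"control": "1", "case": "2"}
    with open(ped_path, "w") as fh:
        for i, row in enumerate(panel.samples.itertuples(index=False)):
            fields = [str(row.cluster), str(row.sample_id), "0", "0", "0", pheno_out[row.phenotype]]
            g_row = panel.genotypes[i]
            for j, g in enumerate(g_row):
                minor = panel.snps.at[j, "minor_allele"]
                major = panel.snps.at[j, "major_allele"]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [major, major]
                elif g == 1:
                    fields += [minor, major]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene-region table
# ---------------------------------------------------------------------------

def read_region_file(path: str | Path) -> list[RegionRecord]:
    """Read a tab-separated gene table: gene, chrom, start, end, subgroups.

    Lines starting with ``#`` are comments; the first non-comment line is the
    header.  The subgroup field is a comma-separated subset of
    :data:`SUBGROUP_LABELS`; empty means the gene belongs only to the full
    set.  Records come back in file order.
    """
    records: list[RegionRecord] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            gene, chrom, start, end = parts[0], parts[1], parts[2], parts[3]
            raw_sub = parts[4].strip() if len(parts) > 4 else ""
            subgroups = tuple(s.strip() for s in raw_sub.split(",") if s.strip())
            try:
                rec = RegionRecord(gene, chrom, int(start), int(end), subgroups)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_region_file(records: list[RegionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstart\tend\tsubgroups\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.chrom}\t{r.start}\t{r.end}\t{','.join(r.subgroups)}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Serialise result tables as TSV under ``out_dir``.

    Floats use a fixed ``%.6g`` format so reruns are byte-identical; the
    files round-trip through :func:`pandas.read_csv` with ``sep="\\t"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(table))
    return written
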