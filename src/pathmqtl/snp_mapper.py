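"""Gene-window SNP mapping: gene body plus fixed flanks, per-metabolite SNP sets.

Every gene in a metabolite's gene set is widened by a flanking window
(default 50 kb on each side) and intersected with a SNP catalogue.  The
per-metabolite SNP set is the deduplicated union over genes; a SNP falling
in two genes' windows is attributed to both in the per-gene map but counted
once in the union — this "unique SNP set" is what enters the test count.

Coordinates are 0-based half-open internally.  BED input is native; VCF
positions (1-based) are converted on read.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneInterval:
    """Gene span (outermost transcript boundaries), 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval for {self.gene_id!r}: "
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class SNPRecord:
    snp_id: str
    chrom: str
    pos: int  # 0-based


class SNPCatalogue:
    """SNP catalogue indexed per chromosome for fast interval queries.

    Positions are held in sorted numpy arrays per chromosome so a window
    query is two binary searches.
    """

    def __init__(self, records: Iterable[SNPRecord]):
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        seen: set[str] = set()
        n = 0
        for rec in records:
            if rec.snp_id in seen:
                raise ValueError(f"duplicate SNP id {rec.snp_id!r} in catalogue")
            seen.add(rec.snp_id)
            by_chrom.setdefault(rec.chrom, []).append((rec.pos, rec.snp_id))
            n += 1
        self._n = n
        self._pos: dict[str, np.ndarray] = {}
        self._ids: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            self._pos[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            self._ids[chrom] = np.array([s for _, s in pairs], dtype=object)

    def __len__(self) -> int:
        return self._n

    def query(self, chrom: str, start: int, end: int) -> frozenset[str]:
        """SNP ids with the given chromosome and start <= pos < end."""
        pos = self._pos.get(chrom)
        if pos is None:
            return frozenset()
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return frozenset(self._ids[chrom][lo:hi])


@dataclass
class SNPSet:
    """Unique SNP set for one metabolite with per-gene attribution."""

    metabolite: str
    snps: frozenset[str]
    per_gene: dict[str, frozenset[str]]
    unmapped_genes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.snps)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.metabolite, gene, snp)
            for gene, snps in sorted(self.per_gene.items())
            for snp in sorted(snps)
        ]
        return pd.DataFrame(rows, columns=["metabolite", "gene_id", "snp_id"])


DEFAULT_FLANK = 50_000


def snps_for_gene(
    gene: GeneInterval, catalogue: SNPCatalogue, flank: int = DEFAULT_FLANK
) -> frozenset[str]:
    """SNPs on the gene's chromosome with max(0, start-flank) <= pos < end+flank."""
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    return catalogue.query(gene.chrom, max(0, gene.start - flank), gene.end + flank)


def snp_set_for_metabolite(
    gene_set,
    intervals: Mapping[str, GeneInterval],
    catalogue: SNPCatalogue,
    flank: int = DEFAULT_FLANK,
) -> SNPSet:
    """Build the per-metabolite SNP set from a gene set and gene intervals.

    Genes without a coordinate interval are reported in
    ``SNPSet.unmapped_genes`` (with a warning) rather than failing the run:
    database gene identifiers routinely include entries absent from a given
    annotation build.
    """
    per_gene: dict[str, frozenset[str]] = {}
    unmapped: list[str] = []
    for gene_id in sorted(gene_set.genes):
        interval = intervals.get(gene_id)
        if interval is None:
            unmapped.append(gene_id)
            continue
        per_gene[gene_id] = snps_for_gene(interval, catalogue, flank=flank)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} gene(s) without coordinates for "
            f"{gene_set.metabolite!r}; excluded from the SNP set",
            stacklevel=2,
        )
    union: set[str] = set()
    for snps in per_gene.values():
        union |= snps
    return SNPSet(
        metabolite=gene_set.metabolite,
        snps=frozenset(union),
        per_gene=per_gene,
        unmapped_genes=tuple(unmapped),
    )


# ---------------------------------------------------------------------------
# readers


def read_bed(path: str | Path) -> dict[str, GeneInterval]:
    """Gene intervals from BED (chrom, start, end, gene_id in column 4)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str},
    )
    intervals: dict[str, GeneInterval] = {}
    for row in df.itertuples(index=False):
        if row.gene_id in intervals:
            raise ValueError(f"duplicate gene id {row.gene_id!r} in BED file")
        intervals[row.gene_id] = GeneInterval(
            gene_id=row.gene_id, chrom=row.chrom, start=int(row.start), end=int(row.end)
        )
    return intervals


def read_snp_catalogue(path: str | Path) -> SNPCatalogue:
    """SNP catalogue from VCF (``*.vcf``/``*.vcf.gz``) or 3-column TSV.

    VCF positions are 1-based and converted to the internal 0-based
    convention.  The TSV format is ``snp_id  chrom  pos`` with a header
    line; a header token ``pos_1based`` marks 1-based positions, plain
    ``pos`` is taken as 0-based.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_tsv(path)


def _read_vcf(path: Path) -> SNPCatalogue:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.id is None:
                continue
            # pysam exposes POS as 0-based rec.start
            records.append(SNPRecord(snp_id=rec.id, chrom=rec.chrom, pos=rec.start))
    return SNPCatalogue(records)


def _read_tsv(path: Path) -> SNPCatalogue:
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().strip().split("\t")
        if len(header) < 3:
            raise ValueError(f"SNP TSV {path} needs 3 columns: snp_id, chrom, pos")
        one_based = header[2].strip().lower() == "pos_1based"
        records = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            snp_id, chrom, pos = line.split("\t")[:3]
            records.append(
                SNPRecord(snp_id=snp_id, chrom=chrom, pos=int(pos) - int(one_based))
            )
    return SNPCatalogue(records)
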