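"""Matching metabolite SNP sets against GWAS summary statistics.

For each gene in a metabolite's SNP set the matched association records for
the corresponding trait are summarised by the minimum p-value (best SNP per
gene); candidates are those below a lenient screening cutoff (default 1e-2)
and are taken forward to replication/meta-analysis.  Sensitivity against a
reference study's top-hit genes quantifies how much of the known signal the
knowledge-driven gene sets retain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .snp_mapper import SNPSet

GWAS_COLUMNS = ("snp_id", "trait", "p_value")


@dataclass(frozen=True)
class AssociationHit:
    """Best association for one gene and one trait."""

    gene_id: str
    trait: str
    best_snp: str
    p_value: float


def read_gwas(path: str | Path) -> pd.DataFrame:
    """GWAS summary statistics from TSV (snp_id, trait, p_value); gzip ok."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "trait": str})
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table {path} lacks columns: {sorted(missing)}")
    return df[list(GWAS_COLUMNS)]


def _normalize_trait(label: str) -> str:
    return " ".join(str(label).split())


def match(
    snp_set: SNPSet, gwas: pd.DataFrame, trait: str
) -> list[AssociationHit]:
    """Intersect a metabolite SNP set with one trait's summary statistics.

    Returns one :class:`AssociationHit` per gene with at least one matched
    SNP; the hit carries the minimum p-value over the gene's matched SNPs,
    ties broken by the lexicographically smallest SNP id.  Trait labels are
    compared after whitespace normalization.  Records with p outside (0, 1]
    are rejected with a warning; an absent trait yields an empty list with
    a warning.
    """
    want = _normalize_trait(trait)
    rows = gwas.loc[gwas["trait"].map(_normalize_trait) == want]
    if rows.empty:
        warnings.warn(f"trait {trait!r} not present in the GWAS table", stacklevel=2)
        return []
    bad = ~((rows["p_value"] > 0) & (rows["p_value"] <= 1))
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} record(s) for trait {trait!r} with p outside (0, 1] "
            "rejected",
            stacklevel=2,
        )
        rows = rows.loc[~bad]
    p_by_snp = dict(zip(rows["snp_id"], rows["p_value"]))

    hits: list[AssociationHit] = []
    for gene_id in sorted(snp_set.per_gene):
        best: tuple[float, str] | None = None
        for snp in snp_set.per_gene[gene_id]:
            p = p_by_snp.get(snp)
            if p is None:
                continue
            key = (p, snp)
            if best is None or key < best:
                best = key
        if best is not None:
            hits.append(
                AssociationHit(
                    gene_id=gene_id, trait=trait, best_snp=best[1], p_value=best[0]
                )
            )
    return hits


def select_candidates(
    hits: Iterable[AssociationHit], cutoff: float = 1e-2
) -> list[AssociationHit]:
    """Hits with p strictly below the screening cutoff, sorted ascending by p."""
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    kept = [h for h in hits if h.p_value < cutoff]
    return sorted(kept, key=lambda h: (h.p_value, h.gene_id, h.trait))


def sensitivity(retrieved_genes: set | frozenset, reference_hits: set | frozenset) -> float:
    """Fraction of reference top-hit genes present in the retrieved set."""
    if not reference_hits:
        raise ValueError("reference_hits must be non-empty")
    return len(set(retrieved_genes) & set(reference_hits)) / len(set(reference_hits))


def hits_to_frame(
    hits: Sequence[AssociationHit], cutoff: float = 1e-2
) -> pd.DataFrame:
    """Tabulate hits with a passes_cutoff flag for file output."""
    return pd.DataFrame(
        [
            (h.gene_id, h.trait, h.best_snp, h.p_value, h.p_value < cutoff)
            for h in hits
        ],
        columns=["gene_id", "trait", "best_snp", "p_value", "passes_cutoff"],
    )


def read_reference_hits(path: str | Path) -> frozenset[str]:
    """Reference top-hit gene list, one gene id per line; # comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return frozenset(genes)


def load_trait_map(path: str | Path) -> Mapping[str, str]:
    """Optional 2-column TSV mapping study trait labels to metabolite labels."""
    df = pd.read_csv(path, sep="\t", header=None, names=["trait", "metabolite"])
    return dict(zip(df["trait"].map(_normalize_trait), df["metabolite"]))
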