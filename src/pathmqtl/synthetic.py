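"""Synthetic inputs with planted signals for end-to-end testing.

Generates, deterministically from one seed, every input the pipeline
consumes: a pathway/reaction knowledgebase (random bipartite
compound–reaction graph with gene assignments and pathway groupings), a
gene annotation (BED), a SNP catalogue (TSV or VCF), a metabolite
configuration, and GWAS summary statistics in which background p-values are
i.i.d. uniform(0, 1) and chosen "planted" genes carry one SNP with a
prescribed p-value for a prescribed trait.  Planted genes are wired into
the reaction graph at a controlled distance from the trait's seed compound,
so traversal, mapping, matching and selection can all be checked against
construction.

The generator emulates the *statistical* structure of a metabolomics GWAS
screen (set sizes, uniform null, a few strong true signals).  It does not
emulate linkage disequilibrium, allele frequencies or effect-size
distributions; see the package documentation for what that implies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .knowledgebase import FilterConfig, KnowledgeBase, build_knowledgebase
from .snp_mapper import SNPSet


@dataclass(frozen=True)
class PlantedSignal:
    """One causal gene to wire into the graph and into the GWAS table."""

    gene_id: str
    trait: str
    target_p: float
    distance: int = 1  # reaction-shells between the trait seed and the gene

    def __post_init__(self):
        if not (0 < self.target_p < 1):
            raise ValueError(f"target_p must be in (0, 1), got {self.target_p}")
        if self.distance not in (1, 2):
            raise ValueError(f"distance must be 1 or 2, got {self.distance}")


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes, rates and planted signals for one synthetic study."""

    seed: int = 0
    n_compounds: int = 48
    n_reactions: int = 36
    n_pathways: int = 6
    n_genes: int = 60
    hub_fraction: float = 0.10
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_snps: int = 1_500
    traits: tuple[str, ...] = ("met_A", "met_B")
    planted: tuple[PlantedSignal, ...] = ()
    source: str = "synthetic"

    def __post_init__(self):
        if min(self.n_compounds, self.n_genes, self.n_chromosomes) < 1:
            raise ValueError("compound, gene and chromosome counts must be positive")
        if self.n_compounds < 2 and self.n_reactions > 0:
            raise ValueError(
                "reactions need at least 2 participant compounds; "
                f"spec has n_compounds={self.n_compounds}"
            )
        gene_ids = {_gene_id(i) for i in range(self.n_genes)}
        for p in self.planted:
            if p.gene_id not in gene_ids:
                raise ValueError(f"planted gene {p.gene_id!r} does not exist")
            if p.trait not in self.traits:
                raise ValueError(f"planted trait {p.trait!r} not in traits")


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _compound_id(i: int) -> str:
    return f"C{i:04d}"


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # one root seed, independent streams per artifact
    return np.random.default_rng([spec.seed, stream])


def trait_seed_compounds(spec: FixtureSpec) -> dict[str, str]:
    """Deterministic seed compound per trait (non-hub by construction)."""
    hubs = hub_compound_ids(spec)
    free = [
        _compound_id(i) for i in range(spec.n_compounds) if _compound_id(i) not in hubs
    ]
    if len(free) < len(spec.traits):
        raise ValueError("not enough non-hub compounds for the requested traits")
    return {t: free[i] for i, t in enumerate(spec.traits)}


def hub_compound_ids(spec: FixtureSpec) -> frozenset[str]:
    n_hubs = int(round(spec.hub_fraction * spec.n_compounds))
    # hubs drawn from the tail of the id range so trait seeds (head) stay free
    rng = _rng(spec, 0)
    lo = spec.n_compounds // 2
    if n_hubs > spec.n_compounds - lo:
        n_hubs = spec.n_compounds - lo
    picked = rng.choice(np.arange(lo, spec.n_compounds), size=n_hubs, replace=False)
    return frozenset(_compound_id(int(i)) for i in sorted(picked))


def generate_knowledgebase_doc(spec: FixtureSpec) -> dict:
    """Interchange-format document for the synthetic knowledgebase."""
    rng = _rng(spec, 1)
    compounds = [
        {"id": _compound_id(i), "name": _compound_id(i)}
        for i in range(spec.n_compounds)
    ]
    all_compounds = [c["id"] for c in compounds]
    all_genes = [_gene_id(i) for i in range(spec.n_genes)]
    planted_genes = {p.gene_id for p in spec.planted}
    background_genes = [g for g in all_genes if g not in planted_genes]
    if spec.n_reactions > 0 and not background_genes:
        raise ValueError("all genes are planted; none left for background reactions")

    reactions = []
    for i in range(spec.n_reactions):
        k = int(rng.integers(2, min(4, spec.n_compounds) + 1))
        parts = rng.choice(all_compounds, size=k, replace=False)
        g = int(rng.integers(1, 4))
        genes = rng.choice(background_genes, size=min(g, len(background_genes)),
                           replace=False)
        reactions.append(
            {
                "id": f"R{i:04d}",
                "participants": sorted(str(c) for c in parts),
                "genes": sorted(str(g) for g in genes),
            }
        )

    # wire planted signals at their prescribed reaction distance, on dedicated
    # reactions so the planted gene is reachable at exactly that radius
    seeds = trait_seed_compounds(spec)
    hubs = hub_compound_ids(spec)
    stepping = [c for c in all_compounds if c not in hubs and c not in seeds.values()]
    for j, p in enumerate(spec.planted):
        seed_cpd = seeds[p.trait]
        if p.distance == 1:
            reactions.append(
                {
                    "id": f"RP{j:03d}",
                    "participants": sorted([seed_cpd, stepping[j % len(stepping)]]),
                    "genes": [p.gene_id],
                }
            )
        else:
            mid = stepping[j % len(stepping)]
            far = stepping[(j + 1) % len(stepping)]
            reactions.append(
                {
                    "id": f"RP{j:03d}a",
                    "participants": sorted([seed_cpd, mid]),
                    "genes": [],
                }
            )
            reactions.append(
                {
                    "id": f"RP{j:03d}b",
                    "participants": sorted([mid, far]),
                    "genes": [p.gene_id],
                }
            )

    pathways = []
    for i in range(spec.n_pathways):
        nc = int(rng.integers(3, min(10, spec.n_compounds) + 1))
        ng = int(rng.integers(3, min(10, spec.n_genes) + 1))
        pathways.append(
            {
                "id": f"P{i:04d}",
                "name": f"pathway {i}",
                "compounds": sorted(
                    str(c) for c in rng.choice(all_compounds, size=nc, replace=False)
                ),
                "genes": sorted(
                    str(g) for g in rng.choice(all_genes, size=ng, replace=False)
                ),
            }
        )

    return {
        "source": spec.source,
        "compounds": compounds,
        "reactions": reactions,
        "pathways": pathways,
    }


def generate_knowledgebase(
    spec: FixtureSpec, path: str | Path | None = None
) -> KnowledgeBase:
    """Build (and optionally write) the synthetic knowledgebase.

    The written file is byte-identical across runs with the same spec.
    The returned object has hub flags applied from the spec's hub set.
    """
    doc = generate_knowledgebase_doc(spec)
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    config = FilterConfig(hub_compounds=hub_compound_ids(spec))
    return build_knowledgebase(doc, config, spec.source)


def generate_gene_intervals(spec: FixtureSpec) -> pd.DataFrame:
    """Gene spans as a BED-shaped frame (chrom, start, end, gene_id)."""
    rng = _rng(spec, 2)
    rows = []
    for i in range(spec.n_genes):
        chrom = f"chr{i % spec.n_chromosomes + 1}"
        length = int(rng.integers(2_000, 10_000))
        start = int(rng.integers(0, max(1, spec.chrom_length - length)))
        rows.append((chrom, start, start + length, _gene_id(i)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def generate_snp_catalogue(spec: FixtureSpec) -> pd.DataFrame:
    """SNP catalogue as a frame (snp_id, chrom, pos), 0-based positions."""
    rng = _rng(spec, 3)
    chroms = [f"chr{i % spec.n_chromosomes + 1}" for i in range(spec.n_snps)]
    pos = rng.integers(0, spec.chrom_length, size=spec.n_snps)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i:06d}" for i in range(spec.n_snps)],
            "chrom": chroms,
            "pos": pos.astype(np.int64),
        }
    )


def write_snp_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_snp_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Minimal sites-only VCF (positions converted to 1-based)."""
    chroms = sorted(df["chrom"].unique())
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for row in df.sort_values(["chrom", "pos"]).itertuples(index=False):
        lines.append(f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\tA\tG\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def metabolite_config(spec: FixtureSpec) -> list[dict]:
    """Per-trait metabolite entries (label, multiplicity 1, seed compound)."""
    seeds = trait_seed_compounds(spec)
    return [
        {"label": t, "multiplicity": 1, "seeds": {spec.source: seeds[t]}}
        for t in spec.traits
    ]


def generate_gwas(
    spec: FixtureSpec, snp_sets: Mapping[str, SNPSet]
) -> pd.DataFrame:
    """GWAS summary statistics with uniform background and planted signals.

    One row per (trait, SNP in the trait's SNP set); background p-values
    are i.i.d. uniform(0, 1).  For each planted signal the lexicographically
    first SNP in the planted gene's window is assigned the target p-value.

    Raises if a planted gene has no mapped SNPs for its trait.
    """
    rng = _rng(spec, 4)
    frames = []
    for trait in spec.traits:
        snps = sorted(snp_sets[trait].snps)
        ps = rng.uniform(0.0, 1.0, size=len(snps))
        frames.append(
            pd.DataFrame({"snp_id": snps, "trait": trait, "p_value": ps})
        )
    gwas = pd.concat(frames, ignore_index=True)
    for p in spec.planted:
        per_gene = snp_sets[p.trait].per_gene.get(p.gene_id, frozenset())
        if not per_gene:
            raise ValueError(
                f"planted gene {p.gene_id!r} has no mapped SNPs for trait "
                f"{p.trait!r}; cannot plant the signal"
            )
        target_snp = min(per_gene)
        mask = (gwas["trait"] == p.trait) & (gwas["snp_id"] == target_snp)
        gwas.loc[mask, "p_value"] = p.target_p
    return gwas


def write_study(spec: FixtureSpec, outdir: str | Path, vcf: bool = False) -> dict:
    """Write every pipeline input for the spec into ``outdir``.

    Returns the paths written, keyed by role.  GWAS generation needs the
    per-trait SNP sets, so the traversal and mapping stages are run here
    with the package's own operations (default flank and radius).
    """
    from .interrogation import MetaboliteClass, gene_sets_for_metabolite
    from .snp_mapper import (
        SNPCatalogue,
        SNPRecord,
        snp_set_for_metabolite,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "knowledgebase": outdir / "knowledgebase.json",
        "hub_compounds": outdir / "hub_compounds.txt",
        "genes_bed": outdir / "genes.bed",
        "snps": outdir / ("snps.vcf" if vcf else "snps.tsv"),
        "metabolites": outdir / "metabolites.json",
        "gwas": outdir / "gwas.tsv",
    }

    kb = generate_knowledgebase(spec, paths["knowledgebase"])
    paths["hub_compounds"].write_text(
        "".join(f"{c}\n" for c in sorted(hub_compound_ids(spec)))
    )

    bed = generate_gene_intervals(spec)
    bed.to_csv(paths["genes_bed"], sep="\t", index=False, header=False)

    snp_df = generate_snp_catalogue(spec)
    if vcf:
        write_snp_vcf(snp_df, paths["snps"])
    else:
        write_snp_tsv(snp_df, paths["snps"])
    catalogue = SNPCatalogue(
        SNPRecord(snp_id=r.snp_id, chrom=r.chrom, pos=int(r.pos))
        for r in snp_df.itertuples(index=False)
    )
    from .snp_mapper import GeneInterval

    intervals = {
        r.gene_id: GeneInterval(
            gene_id=r.gene_id, chrom=r.chrom, start=int(r.start), end=int(r.end)
        )
        for r in bed.itertuples(index=False)
    }

    mets = metabolite_config(spec)
    paths["metabolites"].write_text(json.dumps(mets, indent=1) + "\n")
    snp_sets = {}
    for met in mets:
        mc = MetaboliteClass(
            name=met["label"],
            seed_compounds=met["seeds"],
            multiplicity=met["multiplicity"],
        )
        _, pooled = gene_sets_for_metabolite([kb], mc)
        snp_sets[met["label"]] = snp_set_for_metabolite(pooled, intervals, catalogue)

    gwas = generate_gwas(spec, snp_sets)
    gwas.to_csv(paths["gwas"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def default_planted_spec(seed: int = 0) -> FixtureSpec:
    """Study conditions used by the examples and end-to-end checks."""
    return FixtureSpec(
        seed=seed,
        planted=(
            PlantedSignal(gene_id=_gene_id(1), trait="met_A", target_p=1e-9),
            PlantedSignal(
                gene_id=_gene_id(2), trait="met_B", target_p=1e-8, distance=2
            ),
        ),
    )


def study_run_config(paths: Mapping[str, str], outdir: str | Path, **overrides):
    """RunConfig wired to the files written by :func:`write_study`."""
    from .pipeline import RunConfig

    kwargs = dict(
        knowledgebases=[paths["knowledgebase"]],
        genes_bed=paths["genes_bed"],
        snp_catalogue=paths["snps"],
        gwas=[paths["gwas"]],
        metabolites=paths["metabolites"],
        hub_compounds=paths["hub_compounds"],
        outdir=str(outdir),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
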