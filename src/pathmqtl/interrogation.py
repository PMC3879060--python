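"""Metabolite-specific gene-set generation: pathway scheme and reaction scheme.

Two independent retrieval routes build a candidate gene set for a seed
metabolite:

* **pathway scheme** — collect every gene of every (non-excluded) pathway
  that contains the seed compound;
* **reaction scheme** — breadth-first expansion in reaction space: take the
  reactions the seed participates in, step to their other participants
  (skipping hub compounds), take *their* reactions, and so on out to a
  configurable radius (default 2 shells); collect the genes catalysing every
  reaction reached.

The union of the per-database, per-scheme sets, deduplicated, is the gene
set for the metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .knowledgebase import KnowledgeBase, pathways_of, reactions_of

SCHEME_PATHWAY = "pathway"
SCHEME_REACTION = "reaction"
SCHEME_POOLED = "pooled"


@dataclass(frozen=True)
class GeneSet:
    """Non-redundant gene identifiers for one metabolite from one route."""

    metabolite: str
    source: str
    scheme: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def write_text(self, path: str | Path) -> None:
        """One gene id per line (sorted for stable output)."""
        Path(path).write_text("".join(f"{g}\n" for g in sorted(self.genes)))


@dataclass(frozen=True)
class MetaboliteClass:
    """A measured metabolite or aggregated class of measured species.

    Aggregated classes (e.g. 41 carnitines, 92 phosphatidylcholines,
    15 sphingomyelins measured as distinct species) share a single
    database-level seed compound because pathway databases do not resolve
    species-level lipid structures; ``multiplicity`` is the number of
    measured species the class stands for and multiplies the test count.
    """

    name: str
    seed_compounds: Mapping[str, str] = field(default_factory=dict)
    multiplicity: int = 1
    members: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")
        if self.members is not None and len(self.members) != self.multiplicity:
            raise ValueError(
                f"multiplicity {self.multiplicity} != number of members "
                f"{len(self.members)} for class {self.name!r}"
            )


def pathway_scheme(
    kb: KnowledgeBase, compound_id: str, metabolite: str | None = None
) -> GeneSet:
    """Genes of all non-excluded pathways containing the seed compound."""
    genes: set[str] = set()
    for pid in pathways_of(kb, compound_id):
        genes |= kb.pathways[pid].genes
    return GeneSet(
        metabolite=metabolite or compound_id,
        source=kb.source,
        scheme=SCHEME_PATHWAY,
        genes=frozenset(genes),
    )


def reaction_scheme(
    kb: KnowledgeBase,
    compound_id: str,
    radius: int = 2,
    metabolite: str | None = None,
) -> GeneSet:
    """Breadth-first expansion over the reaction network around the seed.

    Shell 1 holds the reactions the seed participates in; the frontier for
    the next shell is the set of participants of those reactions, minus hub
    compounds and minus compounds already visited.  Hubs never enter the
    frontier (they would connect everything to everything), but a hub *seed*
    is still expanded: the filter exists to stop non-specific transit, not
    to forbid the query.  Genes of every reaction in every shell are pooled.

    radius 0 expands no shells and returns an empty set.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    kb._require_compound(compound_id)

    hubs = kb.hub_compound_ids()
    visited_compounds = {compound_id}
    seen_reactions: set[str] = set()
    genes: set[str] = set()
    frontier = [compound_id]
    for _shell in range(radius):
        next_frontier: set[str] = set()
        for cid in frontier:
            for rid in reactions_of(kb, cid):
                if rid in seen_reactions:
                    continue
                seen_reactions.add(rid)
                rxn = kb.reactions[rid]
                genes |= rxn.genes
                next_frontier |= rxn.participants
        next_frontier -= visited_compounds
        next_frontier -= hubs
        visited_compounds |= next_frontier
        frontier = sorted(next_frontier)
        if not frontier:
            break
    return GeneSet(
        metabolite=metabolite or compound_id,
        source=kb.source,
        scheme=SCHEME_REACTION,
        genes=frozenset(genes),
    )


def pooled_gene_set(gene_sets: Sequence[GeneSet]) -> GeneSet:
    """Union of scheme-level gene sets for one metabolite, deduplicated."""
    if not gene_sets:
        raise ValueError("pooled_gene_set requires at least one input set")
    labels = {gs.metabolite for gs in gene_sets}
    if len(labels) > 1:
        raise ValueError(f"mixed metabolite labels in pooled_gene_set: {sorted(labels)}")
    genes: set[str] = set()
    sources = sorted({gs.source for gs in gene_sets})
    for gs in gene_sets:
        genes |= gs.genes
    return GeneSet(
        metabolite=gene_sets[0].metabolite,
        source="+".join(sources),
        scheme=SCHEME_POOLED,
        genes=frozenset(genes),
    )


def gene_sets_for_metabolite(
    kbs: Iterable[KnowledgeBase],
    met: MetaboliteClass,
    radius: int = 2,
) -> tuple[list[GeneSet], GeneSet]:
    """Run both schemes against every database and pool the results.

    Databases for which the class has no seed compound are skipped (a class
    may be absent from one resource).  Returns the per-scheme sets and the
    pooled set.
    """
    per_scheme: list[GeneSet] = []
    for kb in kbs:
        seed = met.seed_compounds.get(kb.source)
        if seed is None:
            continue
        per_scheme.append(pathway_scheme(kb, seed, metabolite=met.name))
        per_scheme.append(reaction_scheme(kb, seed, radius=radius, metabolite=met.name))
    if not per_scheme:
        raise ValueError(f"no knowledgebase provides a seed for {met.name!r}")
    return per_scheme, pooled_gene_set(per_scheme)
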