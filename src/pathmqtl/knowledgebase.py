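"""Local pathway/reaction knowledgebase: data model, loader, and query layer.

A :class:`KnowledgeBase` is an offline snapshot of one pathway database
(e.g. a KEGG-like or BioCyc-like resource) holding compounds, reactions,
pathways and the genes attached to them.  The interchange format is a single
JSON document with top-level arrays ``compounds``, ``reactions`` and
``pathways``; gene records are implied by the identifiers referenced from
reactions and pathways.  Working from a snapshot rather than live web
services keeps every analysis reproducible: pathway databases drift between
releases, and a run is only meaningful against a pinned version.

Hub compounds (ubiquitous currency metabolites such as ATP, NAD(P)H or
water) and catch-all overview pathways connect essentially everything to
everything; both are flagged at load time from a :class:`FilterConfig` so
that downstream traversals can skip them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class KnowledgeBaseError(Exception):
    """Base class for knowledgebase loading/lookup problems."""


class SchemaError(KnowledgeBaseError):
    """A record in the interchange file violates the schema."""


class IntegrityError(KnowledgeBaseError):
    """A reaction or pathway references an identifier that does not exist."""


class LookupError_(KnowledgeBaseError):
    """An unknown compound/pathway/gene identifier was queried."""


#: Reconstructed default hub-compound names.  Ubiquitous cofactors and
#: currency metabolites whose presence in a reaction says nothing specific
#: about the chemistry of the seed metabolite.  Matching is by compound
#: *name* (case-insensitive) or id; fully configurable.
DEFAULT_HUB_COMPOUNDS = (
    "ATP", "ADP", "AMP",
    "NAD+", "NADH", "NADP+", "NADPH",
    "FAD", "FADH2",
    "coenzyme A", "acetyl-CoA",
    "H2O", "CO2", "O2",
    "phosphate", "diphosphate", "H+",
)

#: Default excluded pathways: global overview maps that aggregate most of
#: metabolism and would connect every compound to thousands of genes.
DEFAULT_EXCLUDED_PATHWAYS = ("Metabolic pathways",)


@dataclass(frozen=True)
class FilterConfig:
    """Hub-compound and pathway-exclusion lists.

    Both lists accept identifiers or names; comparison against names is
    case-insensitive.  Empty config disables all filtering.
    """

    hub_compounds: frozenset[str] = frozenset()
    excluded_pathways: frozenset[str] = frozenset()

    @classmethod
    def default(cls) -> "FilterConfig":
        return cls(
            hub_compounds=frozenset(DEFAULT_HUB_COMPOUNDS),
            excluded_pathways=frozenset(DEFAULT_EXCLUDED_PATHWAYS),
        )

    @classmethod
    def from_files(
        cls,
        hub_path: str | Path | None = None,
        excluded_path: str | Path | None = None,
    ) -> "FilterConfig":
        """Read plain-text lists, one identifier/name per line.

        Blank lines and ``#`` comments are ignored.
        """
        return cls(
            hub_compounds=frozenset(_read_list(hub_path)),
            excluded_pathways=frozenset(_read_list(excluded_path)),
        )

    def _norm(self, values: Iterable[str]) -> frozenset[str]:
        return frozenset(v.casefold() for v in values)

    def is_hub(self, compound_id: str, name: str = "") -> bool:
        hubs = self._norm(self.hub_compounds)
        return compound_id.casefold() in hubs or (name != "" and name.casefold() in hubs)

    def is_excluded(self, pathway_id: str, name: str = "") -> bool:
        excl = self._norm(self.excluded_pathways)
        return pathway_id.casefold() in excl or (name != "" and name.casefold() in excl)


def _read_list(path: str | Path | None) -> list[str]:
    if path is None:
        return []
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@dataclass(frozen=True)
class Compound:
    id: str
    name: str = ""
    is_hub: bool = False


@dataclass(frozen=True)
class Reaction:
    """One reaction, stored undirected: participants = substrates ∪ products."""

    id: str
    participants: frozenset[str]
    genes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str = ""
    compounds: frozenset[str] = frozenset()
    genes: frozenset[str] = frozenset()
    excluded: bool = False


@dataclass(frozen=True)
class Gene:
    id: str
    symbol: str | None = None


@dataclass
class KnowledgeBase:
    """One source database snapshot with identifier-indexed collections."""

    source: str
    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    # -- derived indexes, built on first use ------------------------------
    _compound_to_reactions: dict[str, frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )
    _compound_to_pathways: dict[str, frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def _require_compound(self, compound_id: str) -> Compound:
        try:
            return self.compounds[compound_id]
        except KeyError:
            raise LookupError_(
                f"unknown compound {compound_id!r} in knowledgebase {self.source!r}"
            ) from None

    def hub_compound_ids(self) -> frozenset[str]:
        return frozenset(c.id for c in self.compounds.values() if c.is_hub)

    def validate(self) -> None:
        """Exhaustively re-check referential integrity."""
        for rxn in self.reactions.values():
            if not rxn.participants:
                raise IntegrityError(f"reaction {rxn.id!r} has no participants")
            for cid in rxn.participants:
                if cid not in self.compounds:
                    raise IntegrityError(
                        f"reaction {rxn.id!r} references undefined compound {cid!r}"
                    )
            for gid in rxn.genes:
                if gid not in self.genes:
                    raise IntegrityError(
                        f"reaction {rxn.id!r} references undefined gene {gid!r}"
                    )
        for pw in self.pathways.values():
            for cid in pw.compounds:
                if cid not in self.compounds:
                    raise IntegrityError(
                        f"pathway {pw.id!r} references undefined compound {cid!r}"
                    )
            for gid in pw.genes:
                if gid not in self.genes:
                    raise IntegrityError(
                        f"pathway {pw.id!r} references undefined gene {gid!r}"
                    )


def load_knowledgebase(
    path: str | Path,
    filter_config: FilterConfig | None = None,
    source: str | None = None,
) -> KnowledgeBase:
    """Load and validate a knowledgebase snapshot from the JSON interchange file.

    Parameters
    ----------
    path
        JSON document with arrays ``compounds[{id,name}]``,
        ``reactions[{id,participants[],genes[]}]`` and
        ``pathways[{id,name,compounds[],genes[]}]``.  A top-level ``source``
        string is honoured unless overridden.
    filter_config
        Hub/exclusion lists applied at load time; defaults to no filtering.
    source
        Label for this database (e.g. ``"kegg"``); overrides the file's.

    Raises
    ------
    SchemaError
        Malformed record (missing/empty id, wrong types, duplicate id).
    IntegrityError
        Dangling compound or gene reference.
    """
    filter_config = filter_config or FilterConfig()
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, Mapping):
        raise SchemaError("top level of the knowledgebase file must be a JSON object")
    return build_knowledgebase(doc, filter_config, source or doc.get("source", "unknown"))


def build_knowledgebase(
    doc: Mapping, filter_config: FilterConfig, source: str
) -> KnowledgeBase:
    """Construct and validate a :class:`KnowledgeBase` from a parsed document."""
    kb = KnowledgeBase(source=source, filter_config=filter_config)

    for rec in doc.get("compounds", []):
        cid = _req_str(rec, "id", "compound")
        if cid in kb.compounds:
            raise SchemaError(f"duplicate compound id {cid!r}")
        name = str(rec.get("name", ""))
        kb.compounds[cid] = Compound(
            id=cid, name=name, is_hub=filter_config.is_hub(cid, name)
        )

    # genes may be declared explicitly or implied by reaction/pathway links
    for rec in doc.get("genes", []):
        gid = _req_str(rec, "id", "gene")
        if gid in kb.genes:
            raise SchemaError(f"duplicate gene id {gid!r}")
        kb.genes[gid] = Gene(id=gid, symbol=rec.get("symbol"))
    for rec in list(doc.get("reactions", [])) + list(doc.get("pathways", [])):
        for gid in rec.get("genes", []):
            kb.genes.setdefault(str(gid), Gene(id=str(gid)))

    for rec in doc.get("reactions", []):
        rid = _req_str(rec, "id", "reaction")
        if rid in kb.reactions:
            raise SchemaError(f"duplicate reaction id {rid!r}")
        participants = frozenset(str(c) for c in rec.get("participants", []))
        if not participants:
            raise SchemaError(f"reaction {rid!r} has an empty participant list")
        kb.reactions[rid] = Reaction(
            id=rid,
            participants=participants,
            genes=frozenset(str(g) for g in rec.get("genes", [])),
        )

    for rec in doc.get("pathways", []):
        pid = _req_str(rec, "id", "pathway")
        if pid in kb.pathways:
            raise SchemaError(f"duplicate pathway id {pid!r}")
        name = str(rec.get("name", ""))
        kb.pathways[pid] = Pathway(
            id=pid,
            name=name,
            compounds=frozenset(str(c) for c in rec.get("compounds", [])),
            genes=frozenset(str(g) for g in rec.get("genes", [])),
            excluded=filter_config.is_excluded(pid, name),
        )

    kb.validate()
    return kb


def _req_str(rec: Mapping, key: str, kind: str) -> str:
    val = rec.get(key)
    if not isinstance(val, str) or not val:
        raise SchemaError(f"{kind} record {rec!r} lacks a non-empty string {key!r}")
    return val


def pathways_of(kb: KnowledgeBase, compound_id: str) -> frozenset[str]:
    """All non-excluded pathway ids whose compound list contains the compound.

    Excluded (overview) pathways are never returned.
    """
    kb._require_compound(compound_id)
    if kb._compound_to_pathways is None:
        idx: dict[str, set[str]] = {}
        for pw in kb.pathways.values():
            if pw.excluded:
                continue
            for cid in pw.compounds:
                idx.setdefault(cid, set()).add(pw.id)
        kb._compound_to_pathways = {c: frozenset(s) for c, s in idx.items()}
    return kb._compound_to_pathways.get(compound_id, frozenset())


def reactions_of(kb: KnowledgeBase, compound_id: str) -> frozenset[str]:
    """All reaction ids listing the compound among their participants."""
    kb._require_compound(compound_id)
    if kb._compound_to_reactions is None:
        idx: dict[str, set[str]] = {}
        for rxn in kb.reactions.values():
            for cid in rxn.participants:
                idx.setdefault(cid, set()).add(rxn.id)
        kb._compound_to_reactions = {c: frozenset(s) for c, s in idx.items()}
    return kb._compound_to_reactions.get(compound_id, frozenset())
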