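"""End-to-end orchestration: gene sets → SNP sets → test counts → matching → meta.

``run_pipeline`` chains the three stages of the prioritization strategy —
(i) knowledge-driven gene-set generation, (ii) SNP-set construction from
gene windows, (iii) matching against GWAS summary statistics with
multiple-testing accounting — and, when several studies are supplied,
combines per-gene best p-values across studies with Stouffer's method.
All stage outputs are written to the run directory together with a
machine-readable JSON report; the run is a pure function of its inputs and
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accounting import count_tests
from .gwas_match import (
    hits_to_frame,
    load_trait_map,
    match,
    read_gwas,
    select_candidates,
)
from .interrogation import MetaboliteClass, gene_sets_for_metabolite
from .knowledgebase import FilterConfig, load_knowledgebase
from .meta_analysis import stouffer_combine
from .snp_mapper import read_bed, read_snp_catalogue, snp_set_for_metabolite

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or incomplete run configuration."""


class StageError(Exception):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    knowledgebases: list[str]
    genes_bed: str
    snp_catalogue: str
    gwas: list[str]
    metabolites: str
    outdir: str
    hub_compounds: str | None = None
    excluded_pathways: str | None = None
    trait_map: str | None = None
    alpha: float = 0.05
    flank: int = 50_000
    radius: int = 2
    cutoff: float = 1e-2
    study_labels: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat TOML config file."""
        import tomllib

        try:
            data = tomllib.loads(Path(path).read_text())
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"knowledgebases", "genes_bed", "snp_catalogue", "gwas",
                   "metabolites", "outdir"} - set(data)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(**data)

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0 < self.cutoff <= 1):
            raise ConfigError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.flank < 0 or self.radius < 0:
            raise ConfigError("flank and radius must be >= 0")
        for p in [
            *self.knowledgebases, self.genes_bed, self.snp_catalogue,
            *self.gwas, self.metabolites,
            *(x for x in (self.hub_compounds, self.excluded_pathways,
                          self.trait_map) if x),
        ]:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.study_labels and len(self.study_labels) != len(self.gwas):
            raise ConfigError("study_labels must match the number of GWAS tables")

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_metabolites(path: str | Path) -> list[MetaboliteClass]:
    """Metabolite config: JSON list of {label, multiplicity, seeds{db: id}}."""
    entries = json.loads(Path(path).read_text())
    out = []
    for rec in entries:
        out.append(
            MetaboliteClass(
                name=rec["label"],
                seed_compounds=dict(rec.get("seeds", {})),
                multiplicity=int(rec.get("multiplicity", 1)),
                members=tuple(rec["members"]) if rec.get("members") else None,
            )
        )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write per-stage outputs plus ``report.json``.

    Returns the report.  On stage failure a marker file ``FAILED.<stage>``
    is left in the output directory and :class:`StageError` is raised;
    completed stage outputs are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, exc: Exception) -> StageError:
        (outdir / f"FAILED.{stage}").write_text(f"{exc}\n")
        return StageError(stage, str(exc))

    report: dict = {
        "tool": "pathmqtl",
        "version": __version__,
        "config_hash": config.content_hash(),
        "alpha": config.alpha,
        "flank": config.flank,
        "radius": config.radius,
        "cutoff": config.cutoff,
    }

    # stage i: gene sets ---------------------------------------------------
    try:
        filters = FilterConfig.from_files(config.hub_compounds,
                                          config.excluded_pathways)
        kbs = [load_knowledgebase(p, filters) for p in config.knowledgebases]
        metabolites = load_metabolites(config.metabolites)
        pooled_sets = {}
        scheme_rows = []
        for met in metabolites:
            per_scheme, pooled = gene_sets_for_metabolite(
                kbs, met, radius=config.radius
            )
            pooled_sets[met.name] = pooled
            for gs in [*per_scheme, pooled]:
                scheme_rows.append((gs.metabolite, gs.source, gs.scheme, len(gs)))
        pd.DataFrame(
            scheme_rows, columns=["metabolite", "source", "scheme", "n_genes"]
        ).to_csv(outdir / "gene_set_sizes.tsv", sep="\t", index=False)
        gene_rows = [
            (m, g) for m, gs in sorted(pooled_sets.items()) for g in sorted(gs.genes)
        ]
        pd.DataFrame(gene_rows, columns=["metabolite", "gene_id"]).to_csv(
            outdir / "gene_sets.tsv", sep="\t", index=False
        )
        report["gene_set_sizes"] = {m: len(gs) for m, gs in pooled_sets.items()}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail("gene_sets", exc) from exc

    # stage ii: SNP sets ---------------------------------------------------
    try:
        intervals = read_bed(config.genes_bed)
        catalogue = read_snp_catalogue(config.snp_catalogue)
        snp_sets = {
            m: snp_set_for_metabolite(gs, intervals, catalogue, flank=config.flank)
            for m, gs in pooled_sets.items()
        }
        pd.concat([s.to_frame() for s in snp_sets.values()]).to_csv(
            outdir / "snp_sets.tsv", sep="\t", index=False
        )
        report["snp_set_sizes"] = {m: len(s) for m, s in snp_sets.items()}
        report["unmapped_genes"] = {
            m: len(s.unmapped_genes) for m, s in snp_sets.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise fail("snp_sets", exc) from exc

    # stage iii: accounting, matching, selection ---------------------------
    try:
        mult = {m.name: m.multiplicity for m in metabolites}
        account = count_tests(
            [(m, len(s), mult[m]) for m, s in sorted(snp_sets.items())],
            alpha=config.alpha,
        )
        report["test_counts"] = {
            e.label: e.n_tests for e in account.entries
        }
        report["total_tests"] = account.total_tests
        report["bonferroni_threshold"] = account.threshold

        trait_map = load_trait_map(config.trait_map) if config.trait_map else {}
        labels = config.study_labels or [
            f"study{i + 1}" for i in range(len(config.gwas))
        ]
        per_study_hits: dict[str, list] = {}
        candidates_frames = []
        for label, gwas_path in zip(labels, config.gwas):
            gwas = read_gwas(gwas_path)
            traits = sorted(gwas["trait"].unique())
            hits = []
            for trait in traits:
                met = trait_map.get(trait, trait)
                snp_set = snp_sets.get(met)
                if snp_set is None:
                    logger.warning(
                        "trait %r (metabolite %r) has no SNP set; skipped",
                        trait, met,
                    )
                    continue
                hits.extend(match(snp_set, gwas, trait))
            per_study_hits[label] = hits
            cand = select_candidates(hits, cutoff=config.cutoff)
            frame = hits_to_frame(cand, cutoff=config.cutoff)
            frame.insert(0, "study", label)
            frame["passes_threshold"] = frame["p_value"] < account.threshold
            candidates_frames.append(frame)
        candidates = (
            pd.concat(candidates_frames, ignore_index=True)
            if candidates_frames
            else pd.DataFrame(
                columns=["study", "gene_id", "trait", "best_snp", "p_value",
                         "passes_cutoff", "passes_threshold"]
            )
        )
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        report["candidates"] = {
            label: [
                {
                    "gene_id": h.gene_id,
                    "trait": h.trait,
                    "best_snp": h.best_snp,
                    "p_value": h.p_value,
                    "passes_threshold": h.p_value < account.threshold,
                }
                for h in select_candidates(hits, cutoff=config.cutoff)
            ]
            for label, hits in per_study_hits.items()
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise fail("matching", exc) from exc

    # meta-analysis across studies ----------------------------------------
    try:
        meta_rows = []
        if len(labels) >= 2:
            best: dict[tuple[str, str], dict[str, float]] = {}
            for label, hits in per_study_hits.items():
                for h in hits:
                    best.setdefault((h.gene_id, h.trait), {})[label] = h.p_value
            for (gene, trait), per_study in sorted(best.items()):
                if len(per_study) < 2:
                    continue
                ordered = [per_study[lb] for lb in labels if lb in per_study]
                res = stouffer_combine(ordered, gene_id=gene, trait=trait)
                meta_rows.append(
                    {
                        "gene_id": gene,
                        "trait": trait,
                        "n_studies": len(ordered),
                        "combined_p": res.combined_p,
                    }
                )
        pd.DataFrame(
            meta_rows,
            columns=["gene_id", "trait", "n_studies", "combined_p"],
        ).to_csv(outdir / "meta_results.tsv", sep="\t", index=False)
        report["meta_results"] = meta_rows
    except Exception as exc:  # noqa: BLE001
        raise fail("meta", exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=1) + "\n")
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report
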