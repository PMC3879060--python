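# Methods

## Overview

`pathmqtl` implements a knowledge-driven screen for metabolite quantitative
trait loci (mQTL). Rather than testing all SNPs against all metabolite
phenotypes, it tests, per metabolite, only the SNPs near genes that a
pathway/reaction knowledgebase places in the metabolite's biochemical
vicinity. The stages are: (i) gene-set generation from one or more
knowledgebase snapshots; (ii) SNP-set construction from gene windows;
(iii) multiple-testing accounting, matching against GWAS summary
statistics, candidate screening, and cross-study combination.

## Knowledgebase model

A knowledgebase is a local snapshot (JSON interchange format) of one
pathway database, holding compounds, undirected reactions
(participants = substrates ∪ products), pathways (compound and gene
membership) and genes. Reactions are stored undirected because the
traversal asks which compounds co-participate in a reaction, not which
direction the chemistry runs. Referential integrity is enforced at load
time; queries (`pathways_of`, `reactions_of`) are pure functions over
identifier-indexed collections with lazily built reverse indexes.

Two filters, supplied as plain-text configuration rather than code, tame
non-specific connectivity:

* **hub compounds** — ubiquitous currency metabolites (default list: ATP,
  ADP, AMP, NAD(P)(H), FAD(H₂), coenzyme A, acetyl-CoA, H₂O, CO₂, O₂,
  phosphate, diphosphate, H⁺). Any two random metabolites are connected in
  one step through ATP; barring hubs from the traversal frontier keeps the
  reaction scheme specific. The default list is a curated reconstruction of
  common practice and is fully configurable; matching is by id or
  case-insensitive name.
* **excluded pathways** — catch-all overview maps (default: "Metabolic
  pathways") that would otherwise attach thousands of genes to every
  compound.

## Interrogation schemes

* **Pathway scheme**: union of the gene sets of every non-excluded pathway
  containing the seed compound.
* **Reaction scheme**: breadth-first expansion in reaction space. Shell 1
  is the set of reactions containing the seed; the next frontier is the
  participants of those reactions minus hub compounds and minus compounds
  already visited; shell 2 is their reactions; continue to `radius`
  (default 2 shells). The result is the union of the catalysing genes of
  all reactions reached. Two deliberate choices:
  * a hub *seed* is still expanded — the filter stops non-specific
    transit, it does not forbid asking about a hub;
  * each compound is expanded at most once (visited set). Whether repeat
    visits are re-expanded does not change the gene union (a re-expanded
    compound contributes exactly the reactions it contributed the first
    time), so this is purely an efficiency choice; the test suite verifies
    equivalence against a shortest-path oracle that uses no visited set.

The per-metabolite gene set is the deduplicated union over
databases × schemes ("pooled"). Aggregated classes (carnitines,
phosphatidylcholines, sphingomyelins) use one database-level seed compound
per database, because knowledgebases do not resolve species-level lipid
structures; the class's `multiplicity` records how many species were
actually measured.

## SNP mapping

Coordinates are 0-based half-open internally; BED is read natively and VCF
positions (1-based) are converted on read, preventing off-by-one drift
between sources. A gene's window is `[max(0, start − flank), end + flank)`
with `flank` defaulting to 50 kb — wide enough to catch regulatory
variants and tag-SNPs of the gene without LD modelling. The catalogue is
indexed as per-chromosome sorted position arrays, so a window query is two
binary searches. A SNP in two genes' windows is attributed to both genes
but counted once in the metabolite's unique SNP set; genes absent from the
annotation are reported as unmapped, not fatal.

## Multiple-testing accounting

* Single metabolite: tests = unique SNP-set size.
* Aggregated class of m species: tests = unique SNP-set size × m.
* Cross-class ratio A/B: tests = |SNP(A) ∪ SNP(B)| × class multiplicity,
  with the unordered pair counted once — under the linear association
  model the p-values for A/B and B/A are treated as equal.
* Within-class ratios of an m-species class: unique SNP-set size × m(m−1)/2.
* Threshold: Bonferroni, `alpha / total tests`, alpha defaulting to 0.05.

For replication panels of correlated phenotypes the effective number of
independent variables is estimated from the eigenvalues λ of the phenotype
correlation matrix as `m_eff = Σ [I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)]` (the Li & Ji
form), clipped into [1, n]; the replication threshold is
`alpha / (independent SNPs × m_eff)`. The estimator is pluggable (a
Cheverud/Nyholt variance-based variant is included) because reasonable
practice varies; the LD pruning that produces the "independent SNPs" count
is an input, not implemented here (no single standard r²/window choice
exists, and the choice belongs to the genotype data owner). Numerical
note: the Li–Ji score is discontinuous at integer eigenvalues, so
eigenvalues are snapped to 9 decimals before scoring; otherwise roundoff
in an exactly-degenerate spectrum (e.g. equicorrelation) could flip a term
by almost 1.

## Matching, screening, sensitivity

Per gene and trait the summary is the minimum p over the gene's matched
SNPs (best-SNP-per-locus reporting; no gene-based combination statistic),
ties broken by smallest SNP id for determinism. Records with p outside
(0, 1] are rejected with a warning. Candidates are hits with p strictly
below the screening cutoff (default 1e-2). Trait labels are matched by
exact string equality after whitespace normalization, with an optional
mapping file for cross-study label differences. Sensitivity is
|retrieved ∩ reference| / |reference| against a reference list of top-hit
genes.

## Stouffer combination

Per-gene best p-values across studies are combined as
`Z = Σ wᵢ zᵢ / √(Σ wᵢ²)` with `zᵢ = Φ⁻¹(1 − pᵢ)` computed as `−ndtri(pᵢ)`
(exact for small p, where `1 − p` would lose all precision) and the
combined p as `exp(log_ndtr(−Z))`. The log-space survival function keeps
full relative precision down to the double underflow limit (~1e-308); a
`combined_log10_p` channel stays finite beyond it. A property test checks
that quantile→survival round-trips recover p to at least 12 significant
digits over p ∈ [1e-300, 0.999].

Weights default to equal: with only per-study p-values available (no
effect sizes), inverse-variance weighting is not possible, and equal
weights reproduce the published combined values this implementation is
validated against. Direction of effect is not aligned (inputs are p-values
only), which is anti-conservative if studies disagree in sign; this is a
documented caveat of p-value-only combination, appropriate for a screening
step in which each study must independently support the locus.

## Synthetic studies

The generator emulates the statistical structure of the screen, with all
randomness flowing from a single integer seed through independent named
streams (graph, annotation, catalogue, GWAS):

* a random bipartite compound–reaction graph (defaults: 48 compounds, 36
  reactions of 2–4 participants, 6 pathways, 60 genes, 10% hub compounds)
  — large enough that traversals are non-trivial and per-metabolite SNP
  sets land in the hundreds, small enough that a full pipeline run takes
  well under a second;
* gene spans of 2–10 kb on 2 chromosomes of 1 Mb; 1,500 catalogue SNPs
  (≈0.75 SNPs/kb, so a gene window of ~100 kb captures ~75 SNPs);
* GWAS background p-values i.i.d. uniform(0, 1); each planted causal gene
  is wired into the reaction graph at a prescribed shell distance (1 or 2)
  from its trait's seed compound on dedicated reactions, and one SNP in
  its window is assigned the prescribed p-value (default plants: 1e-9 at
  distance 1 and 1e-8 at distance 2, both far below the Bonferroni
  threshold that the fixture's own test count implies, ~3e-5).

What passing tests on these fixtures do show: the traversal, mapping,
counting, matching, screening and combination machinery is correct, and a
signal the knowledgebase connects to its metabolite is recovered end to
end. What they do not show: robustness to LD (background p-values are
independent, real ones are locally correlated), to allele-frequency or
effect-size structure, to annotation errors, or to the biases of real
pathway curation — none of which the generator models.

## Degenerate inputs and tie-breaks

Empty gene sets, empty SNP sets and empty GWAS tables flow through the
pipeline and produce empty (not failing) outputs; unmapped genes and
absent traits warn. All set-valued outputs are emitted in sorted order and
all random artifacts are byte-identical for a fixed seed, so reruns of a
configuration are reproducible file-for-file.

## Known limitations

* Knowledgebase content is taken as given; results are only as good as the
  snapshot (no cross-database compound-identifier reconciliation, no
  species-level lipid resolution).
* Per-gene best-SNP summaries ignore LD between SNPs within a window; the
  screening cutoff is therefore anti-conservative for long genes.
* The Stouffer step combines p-values without effect directions and
  without any multiplicity adjustment of the per-gene minimum before
  combination.
* Ratio accounting assumes p(A/B) ≈ p(B/A); this holds for log-scaled
  linear-model association tests but is an approximation otherwise.
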