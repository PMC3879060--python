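# pathmqtl

Pathway-knowledge-driven prioritization of SNP–metabolite associations in
metabolomics GWAS.

## The problem

Genome-wide association studies of blood metabolite panels test every SNP
against every measured metabolite — and, increasingly, against every
pairwise metabolite *ratio*. With hundreds of metabolites the resulting
multiple-testing burden (hundreds of millions of tests for ratios) pushes
the Bonferroni significance threshold so low that genuine SNP–metabolite
pairs with moderate effect sizes never reach it.

`pathmqtl` restricts testing to SNPs that are *a priori* plausible: for
each metabolite it interrogates pathway/reaction knowledgebases (offline
snapshots of KEGG-like or BioCyc-like resources) to collect the genes
acting in the metabolite's biochemical vicinity, maps each gene to the
SNPs within its body ± 50 kb flanks, and counts only those SNPs as tests.
This typically reduces the burden by about two orders of magnitude, so
candidate loci that a genome-wide scan discards can be screened, replicated
in an independent study, and combined across studies.

It is a library plus a CLI for:

1. **Gene-set generation** — two interrogation schemes per database:
   the *pathway scheme* (all genes of every pathway containing the seed
   compound, with catch-all overview pathways excluded) and the *reaction
   scheme* (breadth-first expansion of 2 reaction shells around the seed,
   with ubiquitous hub compounds such as ATP or H₂O barred from the
   traversal frontier). The non-redundant union over schemes and databases
   is the metabolite's gene set.
2. **SNP mapping** — each gene interval (BED) widened by a configurable
   flank (default 50 kb) and intersected with a SNP catalogue (VCF or TSV);
   the deduplicated union is the metabolite's unique SNP set.
3. **Multiple-testing accounting** — per-metabolite test counts
   (unique SNP set × number of measured species in the class), ratio
   combinatorics (union SNP set × multiplicity for cross-class pairs,
   `n(n−1)/2` combinations within a class, A/B ≡ B/A), Bonferroni
   thresholds, and the eigenvalue-based effective number of independent
   phenotypes `m_eff = Σ [I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)]` for replication panels
   of correlated traits.
4. **GWAS matching** — per-gene best (minimum) p-value against summary
   statistics, screening at p < 1e-2, sensitivity scoring against a
   reference hit list.
5. **Meta-analysis** — equal-weight one-sided Stouffer combination
   `Z = Σ wᵢ Φ⁻¹(1 − pᵢ) / √(Σ wᵢ²)`, evaluated in log space so p-values
   down to ~1e-300 keep full relative precision.
6. **Synthetic studies** — a seeded generator for knowledgebase, BED, SNP
   catalogue and GWAS tables with planted causal genes, so the whole
   pipeline is testable end to end without any external downloads.

## Worked example

```python
from pathmqtl import count_tests, bonferroni_threshold, stouffer_combine

account = count_tests([
    ("glycine",             20767,  1),   # unique SNP set, measured singly
    ("carnitine",           11239, 41),   # class of 41 measured species
    ("phosphatidylcholine", 31676, 92),
])
print("total tests:", account.total_tests)
print("threshold:  %.3g" % account.threshold)

res = stouffer_combine([5.67e-6, 5.17e-4], gene_id="CBS", trait="PC ae C40:6")
print("combined z: %.3f" % res.combined_z)
print("combined p: %.3g" % res.combined_p)
```

prints

```
total tests: 3395758
threshold:  1.47e-08
combined z: 5.424
combined p: 2.91e-08
```

The carnitine class contributes 11,239 × 41 = 460,799 tests; the threshold
is 0.05 divided by the grand total. The Stouffer line combines a
discovery-study p of 5.67e-6 with a replication p of 5.17e-4 for the same
gene into genome-wide-credible evidence of 2.9e-8.

A full synthetic run from the shell:

```bash
pathmqtl simulate --seed 7 --outdir study/      # all pipeline inputs
cat > run.toml <<EOF
knowledgebases = ["study/knowledgebase.json"]
hub_compounds = "study/hub_compounds.txt"
genes_bed = "study/genes.bed"
snp_catalogue = "study/snps.tsv"
gwas = ["study/gwas.tsv"]
metabolites = "study/metabolites.json"
outdir = "study/out"
EOF
pathmqtl run-all --config run.toml
```

which writes per-stage TSVs plus `study/out/report.json` containing the
gene-set and SNP-set sizes, the test counts and threshold, the screened
candidates (the planted causal genes appear with their planted p-values and
pass the computed threshold), and cross-study meta results when several
GWAS tables are configured. Stages are also available individually
(`build-genesets`, `map-snps`, `count-tests`, `match`, `meta`).

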