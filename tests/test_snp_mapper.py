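import numpy as np
import pytest

from pathmqtl.interrogation import GeneSet
from pathmqtl.snp_mapper import (
    GeneInterval,
    SNPCatalogue,
    SNPRecord,
    read_bed,
    read_snp_catalogue,
    snp_set_for_metabolite,
    snps_for_gene,
)
from pathmqtl.synthetic import (
    FixtureSpec,
    generate_snp_catalogue,
    write_snp_tsv,
    write_snp_vcf,
)


def _catalogue(records):
    return SNPCatalogue(SNPRecord(*r) for r in records)


def _gene_set(genes, metabolite="m"):
    return GeneSet(
        metabolite=metabolite, source="toy", scheme="pooled", genes=frozenset(genes)
    )


class TestSnpsForGene:
    GENE = GeneInterval(gene_id="g", chrom="chr1", start=100_000, end=110_000)

    @pytest.mark.parametrize(
        "pos,included",
        [
            (50_000, True),   # exactly start - flank
            (49_999, False),  # one below the window
            (159_999, True),  # last position of the half-open window
            (160_000, False),  # end + flank itself is outside
        ],
    )
    def test_window_boundaries(self, pos, included):
        cat = _catalogue([("s", "chr1", pos)])
        got = snps_for_gene(self.GENE, cat, flank=50_000)
        assert (got == {"s"}) is included

    def test_empty_catalogue(self):
        assert snps_for_gene(self.GENE, _catalogue([])) == frozenset()

    def test_window_clipped_at_zero(self):
        gene = GeneInterval(gene_id="g", chrom="chr1", start=10, end=20)
        cat = _catalogue([("s", "chr1", 0)])
        assert snps_for_gene(gene, cat, flank=50_000) == {"s"}

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            snps_for_gene(self.GENE, _catalogue([]), flank=-1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        snps = [
            (f"rs{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 1_000_000)))
            for i in range(1_000)
        ]
        cat = _catalogue(snps)
        for j in range(10):
            start = int(rng.integers(0, 900_000))
            gene = GeneInterval(
                gene_id=f"g{j}",
                chrom=f"chr{rng.integers(1, 3)}",
                start=start,
                end=start + int(rng.integers(1_000, 50_000)),
            )
            flank = int(rng.integers(0, 60_000))
            oracle = {
                sid
                for sid, chrom, pos in snps
                if chrom == gene.chrom
                and max(0, gene.start - flank) <= pos < gene.end + flank
            }
            assert snps_for_gene(gene, cat, flank=flank) == oracle

    def test_flank_monotonicity(self):
        rng = np.random.default_rng(1)
        snps = [("rs%d" % i, "chr1", int(rng.integers(0, 200_000))) for i in range(500)]
        cat = _catalogue(snps)
        gene = GeneInterval(gene_id="g", chrom="chr1", start=90_000, end=95_000)
        prev = frozenset()
        for flank in [0, 1_000, 10_000, 50_000, 100_000]:
            cur = snps_for_gene(gene, cat, flank=flank)
            assert prev <= cur
            prev = cur

    def test_chromosome_isolation(self):
        gene = GeneInterval(gene_id="g", chrom="chr1", start=0, end=10_000)
        base = [("a", "chr1", 5_000), ("b", "chr2", 5_000), ("c", "chr2", 6_000)]
        permuted = [("a", "chr1", 5_000), ("b", "chr2", 6_000), ("c", "chr2", 5_000)]
        assert snps_for_gene(gene, _catalogue(base)) == snps_for_gene(
            gene, _catalogue(permuted)
        )


class TestSnpSetForMetabolite:
    def test_unmapped_genes_warn_not_fail(self):
        cat = _catalogue([("s", "chr1", 5)])
        with pytest.warns(UserWarning, match="without coordinates"):
            out = snp_set_for_metabolite(_gene_set({"gX", "gY"}), {}, cat)
        assert out.snps == frozenset()
        assert set(out.unmapped_genes) == {"gX", "gY"}

    def test_shared_snp_counted_once_in_union(self):
        intervals = {
            "g1": GeneInterval(gene_id="g1", chrom="chr1", start=0, end=10),
            "g2": GeneInterval(gene_id="g2", chrom="chr1", start=5, end=15),
        }
        cat = _catalogue([("s", "chr1", 7)])
        out = snp_set_for_metabolite(_gene_set({"g1", "g2"}), intervals, cat, flank=0)
        assert out.per_gene == {"g1": {"s"}, "g2": {"s"}}
        assert out.snps == {"s"}
        assert len(out.snps) <= sum(len(v) for v in out.per_gene.values())

    def test_union_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        snps = [("rs%d" % i, "chr1", int(rng.integers(0, 500_000))) for i in range(200)]
        cat = _catalogue(snps)
        intervals = {}
        for j in range(5):
            start = int(rng.integers(0, 450_000))
            intervals[f"g{j}"] = GeneInterval(
                gene_id=f"g{j}", chrom="chr1", start=start, end=start + 20_000
            )
        out = snp_set_for_metabolite(
            _gene_set(set(intervals)), intervals, cat, flank=10_000
        )
        oracle = {
            sid
            for sid, chrom, pos in snps
            for iv in intervals.values()
            if max(0, iv.start - 10_000) <= pos < iv.end + 10_000
        }
        assert out.snps == oracle


class TestReaders:
    def test_bed_roundtrip(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tgA\nchr2\t0\t50\tgB\n")
        intervals = read_bed(bed)
        assert intervals["gA"] == GeneInterval("gA", "chr1", 100, 200)
        assert intervals["gB"].chrom == "chr2"

    def test_bed_duplicate_gene_rejected(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tgA\nchr1\t300\t400\tgA\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_bed(bed)

    def test_tsv_zero_and_one_based(self, tmp_path):
        zero = tmp_path / "zero.tsv"
        zero.write_text("snp_id\tchrom\tpos\nrs1\tchr1\t100\n")
        one = tmp_path / "one.tsv"
        one.write_text("snp_id\tchrom\tpos_1based\nrs1\tchr1\t101\n")
        a = read_snp_catalogue(zero)
        b = read_snp_catalogue(one)
        assert a.query("chr1", 100, 101) == b.query("chr1", 100, 101) == {"rs1"}

    def test_vcf_and_tsv_agree(self, tmp_path):
        df = generate_snp_catalogue(FixtureSpec(seed=5, n_snps=200))
        write_snp_tsv(df, tmp_path / "snps.tsv")
        write_snp_vcf(df, tmp_path / "snps.vcf")
        tsv = read_snp_catalogue(tmp_path / "snps.tsv")
        vcf = read_snp_catalogue(tmp_path / "snps.vcf")
        assert len(tsv) == len(vcf) == 200
        for chrom in ["chr1", "chr2"]:
            assert tsv.query(chrom, 0, 10**9) == vcf.query(chrom, 0, 10**9)

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _catalogue([("s", "chr1", 1), ("s", "chr1", 2)])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GeneInterval(gene_id="g", chrom="chr1", start=10, end=10)
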