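import numpy as np
import pandas as pd
import pytest

from pathmqtl.gwas_match import (
    hits_to_frame,
    match,
    read_gwas,
    read_reference_hits,
    select_candidates,
    sensitivity,
)
from pathmqtl.snp_mapper import SNPSet


def _snp_set(per_gene, metabolite="m"):
    per_gene = {g: frozenset(s) for g, s in per_gene.items()}
    union = frozenset().union(*per_gene.values()) if per_gene else frozenset()
    return SNPSet(metabolite=metabolite, snps=union, per_gene=per_gene)


def _gwas(rows):
    return pd.DataFrame(rows, columns=["snp_id", "trait", "p_value"])


class TestMatch:
    def test_disjoint_ids_give_empty(self):
        snp_set = _snp_set({"g1": {"s1"}})
        gwas = _gwas([("other", "m", 0.01)])
        assert match(snp_set, gwas, "m") == []

    def test_minimum_p_per_gene(self):
        snp_set = _snp_set({"g1": {"s1", "s2"}})
        gwas = _gwas([("s1", "m", 0.04), ("s2", "m", 0.002)])
        (hit,) = match(snp_set, gwas, "m")
        assert (hit.best_snp, hit.p_value) == ("s2", 0.002)

    def test_tie_broken_by_smallest_snp_id(self):
        snp_set = _snp_set({"g1": {"sB", "sA"}})
        gwas = _gwas([("sB", "m", 0.01), ("sA", "m", 0.01)])
        (hit,) = match(snp_set, gwas, "m")
        assert hit.best_snp == "sA"

    def test_absent_trait_warns_and_returns_empty(self):
        snp_set = _snp_set({"g1": {"s1"}})
        with pytest.warns(UserWarning, match="not present"):
            assert match(snp_set, _gwas([("s1", "other", 0.5)]), "m") == []

    def test_invalid_p_rejected_with_warning(self):
        snp_set = _snp_set({"g1": {"s1", "s2"}})
        gwas = _gwas([("s1", "m", 0.0), ("s2", "m", 0.3)])
        with pytest.warns(UserWarning, match="rejected"):
            (hit,) = match(snp_set, gwas, "m")
        assert hit.best_snp == "s2"

    def test_trait_whitespace_normalized(self):
        snp_set = _snp_set({"g1": {"s1"}})
        gwas = _gwas([("s1", "PC  ae   C40:6", 0.01)])
        (hit,) = match(snp_set, gwas, "PC ae C40:6")
        assert hit.p_value == 0.01

    @pytest.mark.parametrize("seed", range(3))
    def test_minima_match_groupby_oracle(self, seed):
        rng = np.random.default_rng(seed)
        snp_ids = [f"s{i}" for i in range(500)]
        per_gene = {
            f"g{j}": set(rng.choice(snp_ids, size=30, replace=False))
            for j in range(50)
        }
        gwas = _gwas([(s, "m", float(p)) for s, p in
                      zip(snp_ids, rng.uniform(1e-6, 1, size=500))])
        hits = {h.gene_id: h.p_value for h in match(_snp_set(per_gene), gwas, "m")}
        p_by_snp = dict(zip(gwas["snp_id"], gwas["p_value"]))
        oracle = {
            g: min(p_by_snp[s] for s in snps if s in p_by_snp)
            for g, snps in per_gene.items()
            if any(s in p_by_snp for s in snps)
        }
        assert hits == oracle

    def test_every_reported_p_exists_verbatim(self):
        gwas = _gwas([("s1", "m", 0.123), ("s2", "m", 0.456)])
        hits = match(_snp_set({"g1": {"s1"}, "g2": {"s2"}}), gwas, "m")
        assert {h.p_value for h in hits} <= set(gwas["p_value"])

    def test_row_order_invariance(self):
        snp_set = _snp_set({"g1": {"s1", "s2"}, "g2": {"s3"}})
        rows = [("s1", "m", 0.002), ("s2", "m", 0.5), ("s3", "m", 0.004)]
        a = select_candidates(match(snp_set, _gwas(rows), "m"))
        b = select_candidates(match(snp_set, _gwas(rows[::-1]), "m"))
        assert [(h.gene_id, h.p_value) for h in a] == [(h.gene_id, h.p_value) for h in b]


class TestSelectCandidates:
    def _hits(self, ps):
        snp_set = _snp_set({f"g{i}": {f"s{i}"} for i in range(len(ps))})
        gwas = _gwas([(f"s{i}", "m", p) for i, p in enumerate(ps)])
        return match(snp_set, gwas, "m")

    def test_all_above_cutoff(self):
        assert select_candidates(self._hits([0.5, 0.9]), cutoff=1e-2) == []

    def test_boundary_is_strict(self):
        assert select_candidates(self._hits([1e-2]), cutoff=1e-2) == []
        assert len(select_candidates(self._hits([0.99e-2]), cutoff=1e-2)) == 1

    def test_filter_and_sort_oracle(self):
        rng = np.random.default_rng(9)
        ps = list(rng.uniform(1e-5, 1, size=200))
        got = [h.p_value for h in select_candidates(self._hits(ps), cutoff=0.05)]
        assert got == sorted(p for p in ps if p < 0.05)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            select_candidates([], cutoff=0.0)


class TestSensitivity:
    def test_superset_is_one(self):
        assert sensitivity({"a", "b", "c"}, {"a", "b"}) == 1.0

    def test_disjoint_is_zero(self):
        assert sensitivity({"a"}, {"b"}) == 0.0

    def test_monotone_in_retrieved(self):
        ref = {f"r{i}" for i in range(10)}
        prev = 0.0
        retrieved = set()
        for i in range(10):
            retrieved.add(f"r{i}")
            cur = sensitivity(retrieved, ref)
            assert cur >= prev
            prev = cur

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            sensitivity({"a"}, set())


class TestIO:
    def test_read_gwas_requires_columns(self, tmp_path):
        path = tmp_path / "gwas.tsv"
        path.write_text("snp_id\ttrait\n")
        with pytest.raises(ValueError, match="p_value"):
            read_gwas(path)

    def test_read_gwas_gzip_transparent(self, tmp_path):
        import gzip

        path = tmp_path / "gwas.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("snp_id\ttrait\tp_value\nrs1\tm\t0.5\n")
        df = read_gwas(path)
        assert df.loc[0, "p_value"] == 0.5

    def test_hits_frame_flags_cutoff(self):
        snp_set = _snp_set({"g1": {"s1"}, "g2": {"s2"}})
        gwas = _gwas([("s1", "m", 0.001), ("s2", "m", 0.5)])
        frame = hits_to_frame(match(snp_set, gwas, "m"), cutoff=0.01)
        assert list(frame["passes_cutoff"]) == [True, False]

    def test_reference_hits_reader(self, tmp_path):
        path = tmp_path / "ref.txt"
        path.write_text("# top hits\nFADS1\nSCD\n")
        assert read_reference_hits(path) == {"FADS1", "SCD"}
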