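"""Region arithmetic, consensus classification, gene overlap, enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from divscan.regions import (
    build_regions,
    consensus_classify,
    intersect_genes,
    method_map,
    read_gene_annotation,
    term_enrichment,
    write_bed,
)


def cand(rows):
    return pd.DataFrame(rows, columns=["locus_id", "scaffold", "position"])


class TestBuildRegions:
    LEN = {"scf1": 10**6}

    def test_single_snp_flanks(self):
        regs = build_regions(cand([("a", "scf1", 60_000)]), self.LEN)
        assert len(regs) == 1
        r = regs[0]
        assert (r.start, r.end) == (10_000, 110_000)
        assert r.to_bed_row("x").startswith("scf1\t9999\t110000\t")

    def test_overlap_merge(self):
        regs = build_regions(
            cand([("a", "scf1", 100_000), ("b", "scf1", 150_000)]), self.LEN
        )
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (50_000, 200_000)
        assert regs[0].supporting_loci == {"a", "b"}

    def test_abutting_intervals_merge(self):
        regs = build_regions(
            cand([("a", "scf1", 100_000), ("b", "scf1", 200_001)]), self.LEN
        )
        assert len(regs) == 1  # [50000,150000] and [150001,250001] abut

    def test_clamping_at_origin_and_end(self):
        regs = build_regions(
            cand([("a", "scf1", 20_000), ("b", "scf1", 990_000)]), self.LEN
        )
        assert regs[0].start == 1
        assert regs[1].end == 10**6

    def test_unknown_scaffold_is_error(self):
        with pytest.raises(ValueError, match="unknown scaffold"):
            build_regions(cand([("a", "nope", 100)]), self.LEN)

    def test_order_independence_and_support_conservation(self):
        rng = np.random.default_rng(8)
        rows = [
            (f"L{i}", f"s{rng.integers(3)}", int(rng.integers(1, 10**6)))
            for i in range(60)
        ]
        lengths = {f"s{j}": 10**6 for j in range(3)}
        a = build_regions(cand(rows), lengths, flank_bp=30_000)
        b = build_regions(cand(rows[::-1]), lengths, flank_bp=30_000)
        assert [(r.scaffold, r.start, r.end) for r in a] == [
            (r.scaffold, r.start, r.end) for r in b
        ]
        assert sum(len(r.supporting_loci) for r in a) == 60

        # brute-force interval union oracle
        for scf in lengths:
            ivs = sorted(
                (max(1, p - 30_000), min(10**6, p + 30_000))
                for _, s, p in rows
                if s == scf
            )
            merged = []
            for s0, e0 in ivs:
                if merged and s0 <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e0)
                else:
                    merged.append([s0, e0])
            got = [(r.start, r.end) for r in a if r.scaffold == scf]
            assert got == [tuple(m) for m in merged]

    def test_regions_disjoint_after_merge(self):
        rng = np.random.default_rng(9)
        rows = [("L%d" % i, "scf1", int(rng.integers(1, 10**6))) for i in range(80)]
        regs = build_regions(cand(rows), self.LEN)
        for r1, r2 in zip(regs, regs[1:]):
            assert r1.end < r2.start


class TestConsensus:
    def test_disjoint_sets(self):
        _, tallies = consensus_classify(
            {"m1": {"a", "b", "c"}, "m2": {"d", "e", "f", "g"}, "m3": set("hijkl")}
        )
        assert tallies == {1: 12, 2: 0, 3: 0}

    def test_identical_sets(self):
        _, tallies = consensus_classify({m: set("abcdefg") for m in "xyz"})
        assert tallies == {1: 0, 2: 0, 3: 7}

    def test_mixed_overlap_hand_example(self):
        support, tallies = consensus_classify(
            {"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c"}}
        )
        assert tallies == {1: 2, 2: 1, 3: 1}
        assert support["c"] == 3 and support["a"] == 1

    def test_tallies_sum_to_union(self):
        rng = np.random.default_rng(3)
        sets = {
            f"m{j}": {f"L{i}" for i in rng.integers(0, 50, size=20)} for j in range(3)
        }
        support, tallies = consensus_classify(sets)
        assert sum(tallies.values()) == len(set().union(*sets.values()))
        mm = method_map(sets)
        assert all(len(mm[locus]) == support[locus] for locus in support.index)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            consensus_classify({})


class TestGeneIntersection:
    def regions_fixture(self):
        return build_regions(
            cand([("a", "scf1", 100_000), ("b", "scf1", 400_000)]),
            {"scf1": 10**6},
        )

    def test_contained_gene_assigned(self):
        regs = self.regions_fixture()
        annot = pd.DataFrame(
            [("g1", "scf1", 60_000, 70_000)],
            columns=["gene_id", "scaffold", "start", "end"],
        )
        intersect_genes(regs, annot)
        assert regs[0].genes == {"g1"}

    def test_one_bp_boundary_overlap_assigned(self):
        regs = self.regions_fixture()  # first region spans 50,000..150,000
        annot = pd.DataFrame(
            [("gl", "scf1", 40_000, 50_000), ("gr", "scf1", 150_000, 160_000),
             ("gout", "scf1", 150_001, 160_000)],
            columns=["gene_id", "scaffold", "start", "end"],
        )
        intersect_genes(regs, annot)
        assert regs[0].genes == {"gl", "gr"}

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(12)
        regs = build_regions(
            cand([(f"L{i}", "scf1", int(p)) for i, p in
                  enumerate(rng.choice(np.arange(1, 10**6), 8, replace=False))]),
            {"scf1": 10**6},
        )
        genes = [
            (f"g{i}", "scf1", int(s), int(s + rng.integers(500, 80_000)))
            for i, s in enumerate(rng.integers(1, 10**6, size=25))
        ]
        annot = pd.DataFrame(genes, columns=["gene_id", "scaffold", "start", "end"])
        intersect_genes(regs, annot)
        for r in regs:
            expected = {
                g for g, _, s, e in genes if s <= r.end and e >= r.start
            }
            assert r.genes == expected

    def test_bed_and_gff_readers(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("scf1\t999\t2000\tgeneA\t0\t+\nbadline\n")
        df = read_gene_annotation(bed)
        assert df.iloc[0].tolist() == ["geneA", "scf1", 1000, 2000]
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "scf1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneB;Name=b\n"
            "scf1\tsrc\texon\t1000\t1500\t.\t+\t.\tID=exon1\n"
        )
        df2 = read_gene_annotation(gff)
        assert df2["gene_id"].tolist() == ["geneB"]
        assert df2.iloc[0]["start"] == 1000 and df2.iloc[0]["end"] == 2000

    def test_write_bed(self, tmp_path):
        regs = self.regions_fixture()
        write_bed(regs, tmp_path / "r.bed")
        lines = (tmp_path / "r.bed").read_text().strip().split("\n")
        assert len(lines) == len(regs)
        assert lines[0].split("\t")[1] == "49999"


def hypergeom_tail_oracle(k, K_term, n_sel, N):
    """P(X >= k) for X ~ Hypergeom(N, K_term, n_sel), by direct summation."""
    total = 0
    for x in range(k, min(K_term, n_sel) + 1):
        total += comb(K_term, x) * comb(N - K_term, n_sel - x)
    return total / comb(N, n_sel)


class TestTermEnrichment:
    def test_perfect_separation_matches_hypergeometric(self):
        selected = {f"s{i}" for i in range(5)}
        background = selected | {f"b{i}" for i in range(20)}
        term_map = {g: {"T1"} for g in selected}
        df = term_enrichment(selected, background, term_map)
        row = df[df["term"] == "T1"].iloc[0]
        assert row["P"] == pytest.approx(hypergeom_tail_oracle(5, 5, 5, 25), abs=1e-10)

    def test_fisher_matches_oracle_on_small_margins(self):
        rng = np.random.default_rng(2)
        background = {f"g{i}" for i in range(40)}
        selected = set(sorted(background)[:12])
        term_map = {g: {"T"} for g in rng.choice(sorted(background), 15, replace=False)}
        df = term_enrichment(selected, background, term_map)
        k = df.iloc[0]["count_selected"]
        assert df.iloc[0]["P"] == pytest.approx(
            hypergeom_tail_oracle(int(k), 15, 12, 40), abs=1e-10
        )

    def test_no_enrichment_term(self):
        background = {f"g{i}" for i in range(40)}
        selected = {f"g{i}" for i in range(10)}
        term_map = {f"g{i}": {"T"} for i in range(0, 40, 2)}  # 50% everywhere
        df = term_enrichment(selected, background, term_map)
        assert df.iloc[0]["P"] >= 0.5

    def test_bh_fdr_monotone(self):
        rng = np.random.default_rng(4)
        background = {f"g{i}" for i in range(60)}
        selected = {f"g{i}" for i in range(15)}
        term_map = {}
        for t in range(8):
            for g in rng.choice(sorted(background), rng.integers(5, 30), replace=False):
                term_map.setdefault(g, set()).add(f"T{t}")
        df = term_enrichment(selected, background, term_map)
        assert (df.sort_values("P")["FDR"].diff().dropna() >= -1e-12).all()

    def test_empty_selection_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            term_enrichment(set(), {"g"}, {})

    def test_selected_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            term_enrichment({"x"}, {"g"}, {})
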