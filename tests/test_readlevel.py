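"""Read classification, fragment metrics, ASM testing, mLD and block calls."""

import math
from fractions import Fraction

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import iv, make_reads, make_track
from oracles import bh_naive, fisher_two_sided_exact, pearson_r2
from epimosaic.io import ReadRecord
from epimosaic.readlevel import (
    METHYLATED,
    UNDETERMINED,
    UNMETHYLATED,
    adjacent_mld,
    bh_adjust,
    classify_read,
    find_blocks,
    fisher_two_sided,
    fragment_metrics,
    select_imr_blocks,
    CpGPairLD,
    SKIP_FEW_READS,
)
from epimosaic.readlevel import test_allele_asm as allele_asm
from epimosaic.readlevel import test_allele_asm_batch as allele_asm_batch

POS10 = tuple(range(0, 100, 10))
REGION = iv("chr1", 0, 100)


class TestClassifyRead:
    @pytest.mark.parametrize(
        "n_meth, expected",
        [(7, METHYLATED), (10, METHYLATED), (3, UNMETHYLATED),
         (0, UNMETHYLATED), (5, UNDETERMINED), (6, UNDETERMINED)],
    )
    def test_70_30_rule(self, n_meth, expected):
        pattern = "M" * n_meth + "U" * (10 - n_meth)
        [read] = make_reads("chr1", [pattern], POS10)
        assert classify_read(read, REGION) == expected

    def test_no_in_region_calls_is_exclusion(self):
        [read] = make_reads("chr1", ["MM"], (500, 510))
        assert classify_read(read, REGION) is None


class TestFragmentMetrics:
    def test_fully_methylated_reads(self):
        reads = make_reads("chr1", ["MMMM"] * 12, POS10[:4])
        m = fragment_metrics(reads, REGION)
        assert m.pdr == 0
        assert m.entropy == 0
        assert m.mhl == 1
        assert m.chalm == 1
        assert m.mcr == 1
        assert m.mbs == 1

    def test_two_pure_patterns(self):
        # half fully methylated, half fully unmethylated over 4 CpGs
        reads = make_reads("chr1", ["MMMM"] * 6 + ["UUUU"] * 6, POS10[:4])
        m = fragment_metrics(reads, REGION)
        assert m.pdr == 0
        assert m.entropy == pytest.approx(1.0)  # 1 bit
        assert m.mean_adjacent_r2 == pytest.approx(1.0)
        assert m.chalm == 0.5

    def test_independent_coin_calls_pdr(self, rng):
        # 4 CpGs, fair-coin calls: 2 of 16 patterns concordant, E[pdr] = 7/8
        n = 4000
        patterns = ["".join("MU"[b] for b in rng.integers(0, 2, 4))
                    for _ in range(n)]
        reads = make_reads("chr1", patterns, POS10[:4])
        m = fragment_metrics(reads, REGION)
        se = math.sqrt((7 / 8) * (1 / 8) / n)
        assert abs(m.pdr - 7 / 8) < 3 * se

    def test_no_qualifying_reads_all_missing(self):
        reads = make_reads("chr1", ["M..."], POS10[:4])  # single call
        m = fragment_metrics(reads, REGION)
        assert all(math.isnan(v) for v in
                   (m.pdr, m.entropy, m.chalm, m.mhl, m.mcr, m.mbs))

    def test_metrics_bounded(self, rng):
        patterns = ["".join("MU"[b] for b in rng.integers(0, 2, 6))
                    for _ in range(40)]
        m = fragment_metrics(make_reads("chr1", patterns, POS10[:6]), REGION)
        for v in (m.pdr, m.chalm, m.mhl, m.mcr, m.mbs):
            assert 0 <= v <= 1
        assert m.entropy >= 0


class TestFisher:
    def test_printed_value_reproduced_exactly(self):
        # (9,1)/(1,9) table: two-sided p = 202/184756
        assert fisher_two_sided_exact(9, 1, 1, 9) == Fraction(202, 184756)
        assert fisher_two_sided(9, 1, 1, 9) == pytest.approx(202 / 184756,
                                                             abs=1e-12)

    @pytest.mark.parametrize("table", [(0, 0, 0, 0), (5, 0, 0, 5),
                                       (3, 7, 7, 3), (12, 2, 1, 9)])
    def test_matches_enumeration(self, table):
        a, b, c, d = table
        assert abs(fisher_two_sided(a, b, c, d)
                   - float(fisher_two_sided_exact(a, b, c, d))) < 1e-10


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.05, 1.0], [0.10, 1.0]),
            ([], []),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert bh_adjust(p).tolist() == pytest.approx(expected)

    def test_matches_naive_oracle_exactly(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            got = bh_adjust(p)
            assert np.array_equal(got, bh_naive(p))

    def test_matches_statsmodels(self, rng):
        p = rng.random(200)
        assert np.allclose(bh_adjust(p),
                           multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_monotone_in_rank_order(self, rng):
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= 0)
        # q >= p up to one rounding step of p*m/j
        assert np.all(q >= p * (1 - 1e-12))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestAdjacentMLD:
    def test_perfect_comethylation(self):
        reads = make_reads("chr1", ["MM"] * 5 + ["UU"] * 5, POS10[:2])
        [ld] = adjacent_mld(reads, POS10[:2])
        assert ld.r2 == pytest.approx(1.0)

    def test_independence(self):
        reads = make_reads("chr1", ["MM", "MU", "UM", "UU"] * 3, POS10[:2])
        [ld] = adjacent_mld(reads, POS10[:2])
        assert ld.r2 == pytest.approx(0.0, abs=1e-12)

    def test_partial_linkage_closed_form(self):
        reads = make_reads("chr1", ["MM"] * 4 + ["MU"] * 2 + ["UU"] * 4,
                           POS10[:2])
        [ld] = adjacent_mld(reads, POS10[:2])
        assert ld.r2 == pytest.approx(4 / 9)

    def test_min_pair_reads(self):
        reads = make_reads("chr1", ["MM"] * 5 + ["UU"] * 4, POS10[:2])
        [ld] = adjacent_mld(reads, POS10[:2])
        assert ld.r2 is None and ld.n_reads == 9

    def test_zero_variance_undefined(self):
        reads = make_reads("chr1", ["MM"] * 6 + ["MU"] * 6, POS10[:2])
        [ld] = adjacent_mld(reads, POS10[:2])
        assert ld.r2 is None

    def test_matches_textbook_pearson(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 40))
            x = rng.integers(0, 2, n)
            y = (x ^ (rng.random(n) < 0.3)).astype(int)
            if x.var() == 0 or y.var() == 0:
                continue
            patterns = ["".join("UM"[v] for v in pair)
                        for pair in zip(x, y)]
            reads = make_reads("chr1", patterns, POS10[:2])
            [ld] = adjacent_mld(reads, POS10[:2])
            assert abs(ld.r2 - pearson_r2(x, y)) < 1e-12


def pairs_from_r2(r2s, chrom="chr1"):
    return [CpGPairLD(chrom, 10 * i, 10 * (i + 1), 20, r2)
            for i, r2 in enumerate(r2s)]


class TestFindBlocks:
    def test_five_cpgs_all_passing(self):
        [b] = find_blocks(pairs_from_r2([0.9] * 4))
        assert b.cpg_positions == (0, 10, 20, 30, 40)
        assert b.interval.start == 0 and b.interval.end == 42

    def test_three_cpgs_below_minimum(self):
        assert find_blocks(pairs_from_r2([0.9, 0.9])) == []

    def test_run_decomposition_at_threshold(self):
        blocks = find_blocks(pairs_from_r2([0.9, 0.9, 0.9, 0.2, 0.8]))
        assert [b.cpg_positions for b in blocks] == [(0, 10, 20, 30)]

    def test_undefined_pair_breaks_run(self):
        blocks = find_blocks(pairs_from_r2([0.9, 0.9, 0.9, None, 0.9, 0.9, 0.9]))
        assert [b.cpg_positions for b in blocks] == [(0, 10, 20, 30),
                                                     (40, 50, 60, 70)]

    def test_non_adjacent_pairs_do_not_chain(self):
        pairs = [CpGPairLD("chr1", 0, 10, 20, 0.9),
                 CpGPairLD("chr1", 50, 60, 20, 0.9),
                 CpGPairLD("chr1", 60, 70, 20, 0.9),
                 CpGPairLD("chr1", 70, 80, 20, 0.9)]
        assert [b.cpg_positions for b in find_blocks(pairs)] == [(50, 60, 70, 80)]


class TestAlleleASM:
    def strong_asm_reads(self):
        ref = make_reads("chr1", ["MMMM"] * 9 + ["UUUU"], POS10[:4],
                         allele_tags=["ref"] * 10, prefix="ref")
        alt = make_reads("chr1", ["MMMM"] + ["UUUU"] * 9, POS10[:4],
                         allele_tags=["alt"] * 10, prefix="alt")
        return ref + alt

    def test_hypergeometric_p_value(self):
        res = allele_asm(self.strong_asm_reads(), REGION)
        assert res.p == pytest.approx(202 / 184756, abs=1e-12)
        assert (res.ref_meth, res.ref_unmeth, res.alt_meth,
                res.alt_unmeth) == (9, 1, 1, 9)

    def test_symmetric_table_not_asm(self):
        reads = make_reads("chr1", ["MMMM"] * 5 + ["UUUU"] * 5, POS10[:4],
                           allele_tags=["ref"] * 10, prefix="ref")
        reads += make_reads("chr1", ["MMMM"] * 5 + ["UUUU"] * 5, POS10[:4],
                            allele_tags=["alt"] * 10, prefix="alt")
        res = allele_asm(reads, REGION)
        assert res.p == pytest.approx(1.0)

    def test_small_group_skipped(self):
        reads = self.strong_asm_reads()[:16]  # alt group has 6 reads
        assert allele_asm(reads, REGION) == (None, SKIP_FEW_READS)

    def test_undetermined_reads_outside_table(self):
        reads = self.strong_asm_reads()
        reads += make_reads("chr1", ["MMUU"] * 4, POS10[:4],
                            allele_tags=["ref"] * 4, prefix="und")
        res = allele_asm(reads, REGION)
        assert (res.ref_meth, res.ref_unmeth) == (9, 1)

    def test_short_span_reads_dropped(self):
        reads = self.strong_asm_reads()
        reads += make_reads("chr1", ["MMM."] * 4, POS10[:4],
                            allele_tags=["alt"] * 4, prefix="short")
        res = allele_asm(reads, REGION, min_cpgs=4)
        assert (res.alt_meth, res.alt_unmeth) == (1, 9)

    def test_batch_assigns_bh_q(self):
        regions = [(REGION, self.strong_asm_reads())] * 3
        tested, skipped = allele_asm_batch(regions)
        assert len(tested) == 3 and not skipped
        assert all(t.q == pytest.approx(202 / 184756) for t in tested)
        assert all(t.is_asm for t in tested)


class TestSelectIMRBlocks:
    def block(self):
        [b] = find_blocks(pairs_from_r2([0.9] * 4))
        return b

    def normal(self, frac, name="n"):
        rows = [("chr1", p, "combined", int(frac * 20), 20 - int(frac * 20))
                for p in (0, 10, 20, 30, 40)]
        return make_track(name, rows)

    def test_intermediate_in_all_normals_kept(self):
        kept, excluded = select_imr_blocks([self.block()],
                                           [self.normal(0.5)] * 4)
        assert len(kept) == 1 and not excluded
        assert kept[0].normal_means == (0.5,) * 4

    def test_one_extreme_normal_excludes(self):
        tracks = [self.normal(0.5), self.normal(0.9)]
        kept, excluded = select_imr_blocks([self.block()], tracks)
        assert not kept and len(excluded) == 1

    def test_consistency_required_across_all_samples(self):
        tracks = [self.normal(0.5)] * 3 + [self.normal(0.75)]
        kept, _ = select_imr_blocks([self.block()], tracks)
        assert not kept

    def test_uncovered_block_excluded_with_reason(self):
        empty = make_track("n", [("chr9", 5, "combined", 5, 5)])
        kept, excluded = select_imr_blocks([self.block()], [empty])
        assert not kept
        assert excluded[0][1] == "no_coverage_in_normal"
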