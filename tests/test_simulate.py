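"""Generator contracts: determinism, conservation, planted-signal geometry."""

import math

import numpy as np
import pandas as pd
import pytest

from epimosaic.aggregate import aggregate_intervals
from epimosaic.io import write_read_table
from epimosaic.simulate import (
    ASM_LIKE,
    CONST_METH,
    CONST_UNMETH,
    IMPRINTED,
    RANDOM_ASM,
    SimulationConfig,
    emit_reads,
    layout_genome,
    simulate_clone_set,
    simulate_population,
    simulate_tissue_panel,
)

SMALL = dict(n_asm_blocks=20, n_meth_blocks=4, n_unmeth_blocks=4,
             n_epimutated_blocks=4, n_imprinted_blocks=3, n_sv_blocks=3,
             n_snp_dense_blocks=3, n_chrx_blocks=3)


class TestConfig:
    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            SimulationConfig(asm_prob=1.5)

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cells=0)


class TestLayout:
    def test_block_geometry(self):
        truth = layout_genome(SimulationConfig(seed=4))
        sizes = [b.n_cpgs for b in truth.blocks]
        assert min(sizes) >= 4 and max(sizes) <= 20
        assert 10 < np.mean(sizes) < 14
        spans = [b.interval.length for b in truth.blocks]
        assert 120 < np.mean(spans) < 260

    def test_every_block_has_one_label(self):
        truth = layout_genome(SimulationConfig(seed=4, **SMALL))
        cfg = SimulationConfig(seed=4, **SMALL)
        expected_n = (cfg.n_asm_blocks + cfg.n_meth_blocks + cfg.n_unmeth_blocks
                      + cfg.n_epimutated_blocks + cfg.n_imprinted_blocks
                      + cfg.n_sv_blocks + cfg.n_snp_dense_blocks
                      + cfg.n_chrx_blocks + cfg.n_null_blocks)
        assert len(truth.blocks) == expected_n
        assert len({b.block_id for b in truth.blocks}) == expected_n

    def test_sv_breakpoints_within_1kb(self):
        truth = layout_genome(SimulationConfig(seed=4, **SMALL))
        for b in truth.by_label("SV-adjacent"):
            chrom, pos = b.sv_breakpoint
            assert b.interval.distance(chrom, pos) <= 1000

    def test_dense_windows_contain_their_blocks(self):
        truth = layout_genome(SimulationConfig(seed=4, **SMALL))
        for b in truth.by_label("SNP-dense"):
            assert truth.dense_windows.overlaps(b.interval)


class TestDeterminism:
    def test_clone_set_identical_under_same_seed(self):
        cfg = SimulationConfig(seed=9, **SMALL, n_clones=3)
        a = simulate_clone_set(cfg)
        b = simulate_clone_set(cfg)
        pd.testing.assert_frame_equal(a.normal_track.df, b.normal_track.df)
        for clone in a.clone_tracks:
            pd.testing.assert_frame_equal(a.clone_tracks[clone].df,
                                          b.clone_tracks[clone].df)
        pd.testing.assert_frame_equal(a.clone_states, b.clone_states)

    def test_reads_identical_under_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=9, **SMALL)
        truth = layout_genome(cfg)
        r1 = emit_reads(truth, cfg, rng=cfg.rng())
        r2 = emit_reads(truth, cfg, rng=cfg.rng())
        assert r1 == r2
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_read_table(r1, p1)
        write_read_table(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        c1 = SimulationConfig(seed=9, **SMALL, n_clones=2)
        c2 = SimulationConfig(seed=10, **SMALL, n_clones=2)
        a, b = simulate_clone_set(c1), simulate_clone_set(c2)
        assert not a.normal_track.df.equals(b.normal_track.df)


class TestPopulation:
    def test_bulk_equals_cell_sum_exactly(self):
        cfg = SimulationConfig(seed=5, **SMALL, n_cells=200)
        sim = simulate_population(cfg)
        for hap in ("hap1", "hap2"):
            col = sim.cell_calls[hap].sum(axis=0)
            sub = sim.bulk_track.haplotype(hap)
            assert np.array_equal(col, sub.meth.to_numpy())
            assert np.array_equal(np.full(col.shape, cfg.n_cells),
                                  (sub.meth + sub.unmeth).to_numpy())

    def test_large_population_haplotype_balance(self):
        # pi = 0.5 with 10,000 cells and no error: per-haplotype block
        # methylation concentrates at 0.5 (binomial SE ~ 0.005)
        cfg = SimulationConfig(seed=6, **SMALL, n_cells=10_000, error_rate=0.0)
        sim = simulate_population(cfg)
        for hap in ("hap1", "hap2"):
            for b in sim.truth.by_label(RANDOM_ASM):
                [s] = aggregate_intervals(sim.bulk_track, [b.interval],
                                          haplotype=hap)
                assert abs(s.weighted_mean - 0.5) < 0.02

    def test_single_cell_is_fully_allelic(self):
        cfg = SimulationConfig(seed=7, **SMALL, n_cells=1, error_rate=0.0)
        sim = simulate_population(cfg)
        for b in sim.truth.by_label(RANDOM_ASM):
            m1 = aggregate_intervals(sim.bulk_track, [b.interval],
                                     haplotype="hap1")[0].weighted_mean
            m2 = aggregate_intervals(sim.bulk_track, [b.interval],
                                     haplotype="hap2")[0].weighted_mean
            assert {m1, m2} == {0.0, 1.0}


class TestCloneSet:
    def test_noiseless_clone_block_means_match_truth(self):
        cfg = SimulationConfig(seed=8, **SMALL, n_clones=3, error_rate=0.0)
        sim = simulate_clone_set(cfg)
        clone = "clone01"
        track = sim.clone_tracks[clone]
        for b in sim.truth.blocks:
            state = sim.clone_states.at[b.block_id, clone]
            if state == "null":
                continue
            m1 = aggregate_intervals(track, [b.interval],
                                     haplotype="hap1")[0].weighted_mean
            m2 = aggregate_intervals(track, [b.interval],
                                     haplotype="hap2")[0].weighted_mean
            expected = {"hap1": (1.0, 0.0), "hap2": (0.0, 1.0),
                        "meth": (1.0, 1.0), "hyper": (1.0, 1.0),
                        "unmeth": (0.0, 0.0), "hypo": (0.0, 0.0)}[state]
            assert (m1, m2) == expected

    def test_pi_one_always_methylates_hap1(self):
        cfg = SimulationConfig(seed=8, **SMALL, n_clones=5, asm_prob=1.0)
        sim = simulate_clone_set(cfg)
        for b in sim.truth.by_label(*ASM_LIKE):
            if b.label in ("epimutated-hyper", "epimutated-hypo"):
                continue
            assert set(sim.clone_states.loc[b.block_id]) == {"hap1"}

    def test_zero_epimutation_rate_keeps_asm_blocks_allelic(self):
        cfg = SimulationConfig(seed=8, **SMALL, n_clones=5,
                               epimutation_rate=0.0)
        sim = simulate_clone_set(cfg)
        for b in sim.truth.by_label(RANDOM_ASM):
            assert set(sim.clone_states.loc[b.block_id]) <= {"hap1", "hap2"}

    def test_epimutation_rate_one_converts_all(self):
        cfg = SimulationConfig(seed=8, **SMALL, n_clones=5,
                               epimutation_rate=1.0)
        sim = simulate_clone_set(cfg)
        for b in sim.truth.by_label(RANDOM_ASM):
            assert set(sim.clone_states.loc[b.block_id]) <= {"hyper", "hypo"}

    def test_bulk_is_exact_pool_of_clones(self):
        cfg = SimulationConfig(seed=8, **SMALL, n_clones=4)
        sim = simulate_clone_set(cfg)
        total = sum(t.df.meth.sum() for t in sim.clone_tracks.values())
        assert sim.bulk_track.df.meth.sum() == total


class TestEmitReads:
    def test_noiseless_clonal_long_reads_are_pure(self):
        cfg = SimulationConfig(seed=12, **SMALL, error_rate=0.0)
        truth = layout_genome(cfg)
        states = {b.block_id: "hap1" for b in truth.blocks}
        reads = emit_reads(truth, cfg, mode="long", block_states=states,
                           rng=cfg.rng())
        by_block = {}
        for b in truth.blocks:
            if b.label == "independent-null":
                continue
            for r in reads:
                if (r.chrom == b.interval.chrom
                        and b.interval.start <= r.calls[0][0] < b.interval.end):
                    calls = {c for _, c in r.calls}
                    assert calls == ({"M"} if r.haplotype_tag == "hap1"
                                     else {"U"})

    def test_poisson_coverage_mean_recovery(self):
        cfg = SimulationConfig(seed=13, n_asm_blocks=120, mean_coverage=30.0)
        truth = layout_genome(cfg)
        reads = emit_reads(truth, cfg, mode="long", rng=cfg.rng())
        depth: dict[tuple, int] = {}
        for r in reads:
            for pos, _ in r.calls:
                depth[(r.chrom, pos)] = depth.get((r.chrom, pos), 0) + 1
        n_cpgs = sum(b.n_cpgs for b in truth.blocks)
        assert n_cpgs >= 1000
        mean_depth = sum(depth.values()) / n_cpgs
        assert abs(mean_depth - 30.0) < 1.0

    def test_short_fragments_over_snp_carry_allele_tags(self):
        cfg = SimulationConfig(seed=14, **SMALL)
        truth = layout_genome(cfg)
        reads = emit_reads(truth, cfg, mode="short", rng=cfg.rng())
        snp_by_chrom = {(b.interval.chrom, b.snp_pos) for b in truth.blocks}
        n_tagged = 0
        for r in reads:
            lo, hi = r.calls[0][0], r.calls[-1][0]
            covers = any(c == r.chrom and lo <= p <= hi
                         for c, p in snp_by_chrom)
            if covers:
                assert r.allele_tag in ("ref", "alt")
                n_tagged += 1
            else:
                assert r.allele_tag == "none"
        assert n_tagged > 0

    def test_fragments_span_at_least_four_cpgs(self):
        cfg = SimulationConfig(seed=14, **SMALL)
        truth = layout_genome(cfg)
        for r in emit_reads(truth, cfg, mode="short", rng=cfg.rng()):
            assert len(r.calls) >= 4


class TestTissuePanel:
    def test_structure_and_determinism(self):
        cfg = SimulationConfig(seed=15, n_tissue_blocks=8, n_pan_tissue_blocks=4,
                               n_inconsistent_blocks=2, n_class_regions=5)
        a = simulate_tissue_panel(cfg)
        b = simulate_tissue_panel(cfg)
        assert a.tissues == b.tissues == ["tissue1", "tissue2", "tissue3"]
        for t in a.tissues:
            assert len(a.block_sets[t]) == cfg.samples_per_tissue
            for sa, sb in zip(a.block_sets[t], b.block_sets[t]):
                assert sa == sb
            for ta, tb in zip(a.normal_tracks[t], b.normal_tracks[t]):
                pd.testing.assert_frame_equal(ta.df, tb.df)

    def test_matched_blocks_intermediate_and_others_extreme(self):
        cfg = SimulationConfig(seed=16, n_tissue_blocks=8, n_pan_tissue_blocks=4,
                               n_inconsistent_blocks=0, n_class_regions=2,
                               mean_coverage=60.0)
        sim = simulate_tissue_panel(cfg)
        from epimosaic.intervals import GenomicInterval
        specific = sim.tissue_blocks[sim.tissue_blocks.label == "tissue-specific"]
        for row in specific.itertuples(index=False):
            region = GenomicInterval(cfg.chrom, row.start, row.end)
            matched = sim.normal_tracks[row.tissue][0]
            [s] = aggregate_intervals(matched, [region])
            assert 0.3 <= s.weighted_mean <= 0.7
            other_tissue = next(t for t in sim.tissues if t != row.tissue)
            [o] = aggregate_intervals(sim.normal_tracks[other_tissue][0],
                                      [region])
            assert o.weighted_mean < 0.3 or o.weighted_mean > 0.7
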