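"""Haplotype-resolved ASM discovery, exclusion filters and block-level calls.

The block-level callers follow count-based Fisher testing of CpG calls:

* ASM — methylated vs unmethylated CpG call counts between the two
  haplotypes of one sample; significant at FDR < 0.05 with an absolute
  haplotype methylation difference > 0.4;
* epimutation — aggregated counts (haplotype-agnostic) between a test sample
  and a pooled normal reference; significant at FDR < 0.05 with an absolute
  difference > 0.3.

Both require >= 4 covered CpGs per block and an adjusted CpG coverage (total
CpG call count divided by the number of CpGs in the block) of at least 5 per
haplotype (ASM) or per sample (epimutation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dmr import DMRCall, call_dmrs
from .intervals import GenomicInterval, IntervalSet
from .io import MethylationTrack
from .readlevel import bh_adjust, fisher_two_sided

SEX_CHROMS = ("chrX", "chrY", "X", "Y")

REASON_SEX = "sex_chrom"
REASON_IMPRINTED = "imprinted"
REASON_SV = "sv_proximal"
REASON_SNP_DENSE = "snp_dense"
REASON_LOW_COVERAGE = "insufficient_coverage"

ASM_HAP1 = "ASM_hap1_meth"
ASM_HAP2 = "ASM_hap2_meth"
HYPER = "hyper"
HYPO = "hypo"
INTERMEDIATE = "intermediate"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class FilterMasks:
    imprinted: IntervalSet
    sv_breakpoints: tuple[tuple[str, int], ...]
    snp_dense: IntervalSet
    sex_chroms: frozenset[str] = frozenset(SEX_CHROMS)


def hap_dmrs(
    track: MethylationTrack,
    fdr: float = 0.05,
    min_diff: float = 0.4,
    **kwargs,
) -> list[DMRCall]:
    """ASM regions: DMRs between the two haplotypes of one sample."""
    for hap in ("hap1", "hap2"):
        if track.haplotype(hap).empty:
            raise ValueError(f"track {track.sample_id}: missing {hap} records")
    kwargs.setdefault("autosomes_only", False)  # filtering handled by masks
    return call_dmrs(
        track, track, fdr=fdr, min_diff=min_diff,
        haplotypes=("hap1", "hap2"), **kwargs,
    )


def high_snp_density_windows(
    snp_positions: Iterable[tuple[str, int]],
    genome_span: Mapping[str, int],
    window: int = 10_000,
    top_fraction: float = 0.01,
) -> IntervalSet:
    """Non-overlapping windows whose SNP count is in the genome-wide top 1%.

    All tiled windows enter the quantile (including SNP-free ones). A window
    is masked when its count is strictly greater than the (1 - top_fraction)
    empirical quantile, so a flat density masks nothing.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts: dict[tuple[str, int], int] = {}
    all_windows: list[tuple[str, int]] = []
    for chrom, length in genome_span.items():
        for w in range(math.ceil(length / window)):
            all_windows.append((chrom, w))
    index = {w: 0 for w in all_windows}
    for chrom, pos in snp_positions:
        key = (chrom, pos // window)
        if key in index:
            index[key] += 1
    values = np.array([index[w] for w in all_windows])
    if values.size == 0 or values.sum() == 0:
        return IntervalSet([], label="snp_dense")
    cutoff = float(np.quantile(values, 1 - top_fraction))
    dense = [
        GenomicInterval(chrom, w * window, min((w + 1) * window, genome_span[chrom]))
        for (chrom, w), v in zip(all_windows, values)
        if v > cutoff
    ]
    return IntervalSet(dense, label="snp_dense")


def asm_region_filter(
    regions: Sequence[GenomicInterval],
    masks: FilterMasks,
    sv_distance: int = 1_000,
) -> tuple[list[GenomicInterval], list[tuple[GenomicInterval, tuple[str, ...]]]]:
    """Apply the exclusion filters to candidate ASM regions.

    A region is excluded when it (a) lies on a sex chromosome, (b) overlaps a
    known imprinted interval, (c) has a structural-variant breakpoint within
    ``sv_distance`` bp, or (d) overlaps a dense-SNP window. All matching
    reasons are reported.
    """
    retained: list[GenomicInterval] = []
    excluded: list[tuple[GenomicInterval, tuple[str, ...]]] = []
    for region in regions:
        reasons = []
        if region.chrom in masks.sex_chroms:
            reasons.append(REASON_SEX)
        if masks.imprinted.overlaps(region):
            reasons.append(REASON_IMPRINTED)
        if any(
            region.distance(chrom, pos) <= sv_distance
            for chrom, pos in masks.sv_breakpoints
        ):
            reasons.append(REASON_SV)
        if masks.snp_dense.overlaps(region):
            reasons.append(REASON_SNP_DENSE)
        if reasons:
            excluded.append((region, tuple(reasons)))
        else:
            retained.append(region)
    return retained, excluded


# ---------------------------------------------------------------------------
# block-level calls


@dataclass(frozen=True)
class BlockASMCall:
    block: GenomicInterval
    hap1_meth: int
    hap1_unmeth: int
    hap2_meth: int
    hap2_unmeth: int
    adjusted_cov_hap1: float
    adjusted_cov_hap2: float
    p: float
    q: float = float("nan")
    is_asm: bool = False

    @property
    def hap1_mean(self) -> float:
        t = self.hap1_meth + self.hap1_unmeth
        return self.hap1_meth / t if t else float("nan")

    @property
    def hap2_mean(self) -> float:
        t = self.hap2_meth + self.hap2_unmeth
        return self.hap2_meth / t if t else float("nan")

    @property
    def diff(self) -> float:
        return self.hap1_mean - self.hap2_mean

    @property
    def methylated_hap(self) -> str:
        if not self.is_asm:
            return "none"
        return "hap1" if self.diff > 0 else "hap2"


@dataclass(frozen=True)
class BlockEpimutationCall:
    block: GenomicInterval
    sample_meth: int
    sample_unmeth: int
    normal_meth: int
    normal_unmeth: int
    adjusted_cov_sample: float
    adjusted_cov_normal: float
    p: float
    q: float = float("nan")
    is_epimutation: bool = False

    @property
    def sample_mean(self) -> float:
        t = self.sample_meth + self.sample_unmeth
        return self.sample_meth / t if t else float("nan")

    @property
    def normal_mean(self) -> float:
        t = self.normal_meth + self.normal_unmeth
        return self.normal_meth / t if t else float("nan")

    @property
    def diff(self) -> float:
        return self.sample_mean - self.normal_mean

    @property
    def direction(self) -> str:
        if not self.is_epimutation:
            return "none"
        return HYPER if self.diff > 0 else HYPO


def _block_counts(track: MethylationTrack, block, haplotype: str):
    """(meth, unmeth, n_covered, n_block_cpgs) over the block's CpGs."""
    positions = getattr(block, "cpg_positions", None)
    interval = getattr(block, "interval", block)
    sub = track.haplotype(haplotype)
    sub = sub[(sub.chrom == interval.chrom)]
    if positions is not None:
        sub = sub[sub.pos.isin(positions)]
        n_block = len(positions)
    else:
        sub = sub[(sub.pos >= interval.start) & (sub.pos < interval.end)]
        n_block = len(sub)
    meth = int(sub.meth.sum())
    unmeth = int(sub.unmeth.sum())
    covered = int(((sub.meth + sub.unmeth) > 0).sum())
    return meth, unmeth, covered, n_block


def block_asm_test(
    block,
    hap_track: MethylationTrack,
    min_covered_cpgs: int = 4,
    min_adjusted_cov: float = 5.0,
) -> BlockASMCall | tuple[None, str]:
    """Fisher test of summed CpG calls between haplotypes for one block."""
    m1, u1, cov1, n = _block_counts(hap_track, block, "hap1")
    m2, u2, cov2, _ = _block_counts(hap_track, block, "hap2")
    interval = getattr(block, "interval", block)
    if n == 0 or min(cov1, cov2) < min_covered_cpgs:
        return None, REASON_LOW_COVERAGE
    adj1 = (m1 + u1) / n
    adj2 = (m2 + u2) / n
    if adj1 < min_adjusted_cov or adj2 < min_adjusted_cov:
        return None, REASON_LOW_COVERAGE
    p = fisher_two_sided(m1, u1, m2, u2)
    return BlockASMCall(interval, m1, u1, m2, u2, adj1, adj2, p)


def block_asm_batch(
    blocks: Sequence,
    hap_track: MethylationTrack,
    alpha: float = 0.05,
    min_diff: float = 0.4,
    min_covered_cpgs: int = 4,
    min_adjusted_cov: float = 5.0,
) -> tuple[list[BlockASMCall], list[tuple[GenomicInterval, str]]]:
    """ASM-test all blocks for one sample; BH across evaluable blocks."""
    tested: list[BlockASMCall] = []
    skipped: list[tuple[GenomicInterval, str]] = []
    for block in blocks:
        res = block_asm_test(
            block, hap_track,
            min_covered_cpgs=min_covered_cpgs, min_adjusted_cov=min_adjusted_cov,
        )
        if isinstance(res, tuple):
            skipped.append((getattr(block, "interval", block), res[1]))
        else:
            tested.append(res)
    if tested:
        qs = bh_adjust([c.p for c in tested])
        tested = [
            BlockASMCall(
                c.block, c.hap1_meth, c.hap1_unmeth, c.hap2_meth, c.hap2_unmeth,
                c.adjusted_cov_hap1, c.adjusted_cov_hap2, c.p, float(q),
                bool(q < alpha and abs(c.diff) > min_diff),
            )
            for c, q in zip(tested, qs)
        ]
    return tested, skipped


def block_epimutation_test(
    block,
    sample_track: MethylationTrack,
    normal_track: MethylationTrack,
    min_covered_cpgs: int = 4,
    min_adjusted_cov: float = 5.0,
) -> BlockEpimutationCall | tuple[None, str]:
    """Fisher test of combined CpG calls between a sample and pooled normal."""
    ms, us, cov_s, n = _block_counts(sample_track, block, "combined")
    mn, un, cov_n, _ = _block_counts(normal_track, block, "combined")
    interval = getattr(block, "interval", block)
    if n == 0 or min(cov_s, cov_n) < min_covered_cpgs:
        return None, REASON_LOW_COVERAGE
    adj_s = (ms + us) / n
    adj_n = (mn + un) / n
    if adj_s < min_adjusted_cov or adj_n < min_adjusted_cov:
        return None, REASON_LOW_COVERAGE
    p = fisher_two_sided(ms, us, mn, un)
    return BlockEpimutationCall(interval, ms, us, mn, un, adj_s, adj_n, p)


def block_epimutation_batch(
    blocks: Sequence,
    sample_track: MethylationTrack,
    normal_track: MethylationTrack,
    alpha: float = 0.05,
    min_diff: float = 0.3,
    min_covered_cpgs: int = 4,
    min_adjusted_cov: float = 5.0,
) -> tuple[list[BlockEpimutationCall], list[tuple[GenomicInterval, str]]]:
    tested: list[BlockEpimutationCall] = []
    skipped: list[tuple[GenomicInterval, str]] = []
    for block in blocks:
        res = block_epimutation_test(
            block, sample_track, normal_track,
            min_covered_cpgs=min_covered_cpgs, min_adjusted_cov=min_adjusted_cov,
        )
        if isinstance(res, tuple):
            skipped.append((getattr(block, "interval", block), res[1]))
        else:
            tested.append(res)
    if tested:
        qs = bh_adjust([c.p for c in tested])
        tested = [
            BlockEpimutationCall(
                c.block, c.sample_meth, c.sample_unmeth, c.normal_meth,
                c.normal_unmeth, c.adjusted_cov_sample, c.adjusted_cov_normal,
                c.p, float(q), bool(q < alpha and abs(c.diff) > min_diff),
            )
            for c, q in zip(tested, qs)
        ]
    return tested, skipped


def classify_block_state(
    asm_call: BlockASMCall | None,
    epimutation_call: BlockEpimutationCall | None,
    block_mean: float,
    low: float = 0.3,
    high: float = 0.7,
) -> str:
    """Per-block, per-sample state with precedence ASM > epimutation.

    A block with both calls significant is labelled ASM (the more specific
    claim); otherwise a significant epimutation gives hyper/hypo by diff
    sign; otherwise intermediate when the block mean lies in [low, high],
    else indeterminate.
    """
    if asm_call is not None and asm_call.is_asm:
        return ASM_HAP1 if asm_call.methylated_hap == "hap1" else ASM_HAP2
    if epimutation_call is not None and epimutation_call.is_epimutation:
        return epimutation_call.direction
    if not math.isnan(block_mean) and low <= block_mean <= high:
        return INTERMEDIATE
    return INDETERMINATE
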