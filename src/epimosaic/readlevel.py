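"""Read-level methylation analysis.

This module holds the fragment-level machinery of the pipeline:

* classification of individual reads as methylated / unmethylated /
  undetermined using the 70% / 30% rule;
* fragment heterogeneity metrics (PDR, entropy, CHALM, MHL, MCR, MBS, mean
  adjacent r²) over a region;
* SNP-partitioned allele-specific-methylation (ASM) testing on classified
  reads (Fisher exact, BH-adjusted);
* methylation linkage disequilibrium (mLD) between adjacent CpGs, measured as
  the squared Pearson correlation of binary call vectors across reads, and
  the derivation of methylation haplotype blocks (MHBs): maximal runs of at
  least four consecutive CpGs whose every adjacent pair has r² >= 0.5;
* selection of IMR blocks: MHBs whose aggregate methylation is intermediate
  (0.3–0.7) in every normal sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .aggregate import aggregate_intervals
from .intervals import GenomicInterval
from .io import MethylationTrack, ReadRecord

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNDETERMINED = "undetermined"


def classify_read(
    read: ReadRecord,
    region: GenomicInterval,
    low: float = 0.3,
    high: float = 0.7,
) -> str | None:
    """Classify a read by the fraction of its in-region CpG calls that are M.

    Returns ``None`` (exclusion, not a classification) when the read has no
    calls inside the region.
    """
    calls = read.calls_in(region.start, region.end)
    if read.chrom != region.chrom or not calls:
        return None
    frac = sum(1 for _, c in calls if c == "M") / len(calls)
    if frac >= high:
        return METHYLATED
    if frac <= low:
        return UNMETHYLATED
    return UNDETERMINED


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1;
    tied p-values share the smaller adjusted value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# fragment metrics


@dataclass(frozen=True)
class FragmentMetrics:
    pdr: float
    entropy: float
    chalm: float
    mhl: float
    mcr: float
    mbs: float
    mean_adjacent_r2: float


def _region_call_vectors(
    reads: Sequence[ReadRecord], region: GenomicInterval, min_calls: int = 2
) -> list[list[tuple[int, str]]]:
    vecs = []
    for read in reads:
        if read.chrom != region.chrom:
            continue
        calls = read.calls_in(region.start, region.end)
        if len(calls) >= min_calls:
            vecs.append(list(calls))
    return vecs


def fragment_metrics(
    reads: Sequence[ReadRecord],
    region: GenomicInterval,
    min_pair_reads: int = 10,
    entropy_window: int = 4,
) -> FragmentMetrics:
    """Fragment-level heterogeneity metrics over one region.

    Reads with fewer than 2 in-region calls are excluded. With no qualifying
    reads every metric is NaN. Definitions:

    * PDR — fraction of reads carrying both M and U calls;
    * entropy — mean Shannon entropy (bits) of the read-pattern distribution
      over sliding windows of ``entropy_window`` consecutive CpGs;
    * CHALM — fraction of reads with at least one M call;
    * MHL — length-weighted (w_l = l) average over substring lengths l of the
      frequency of fully methylated l-mers among read substrings;
    * MCR — fraction of within-read adjacent call pairs that are concordant;
    * MBS — per-read sum of (methylated-run length / read length)^2, averaged
      over reads;
    * mean_adjacent_r2 — mean of defined adjacent-pair mLD r² values.
    """
    nan = float("nan")
    vecs = _region_call_vectors(reads, region)
    if not vecs:
        return FragmentMetrics(nan, nan, nan, nan, nan, nan, nan)

    n = len(vecs)
    pdr = sum(
        1 for v in vecs if {"M", "U"} <= {c for _, c in v}
    ) / n
    chalm = sum(1 for v in vecs if any(c == "M" for _, c in v)) / n

    positions = sorted({p for v in vecs for p, _ in v})

    # entropy over pattern windows
    window = min(entropy_window, len(positions))
    entropies = []
    for i in range(len(positions) - window + 1):
        win = positions[i : i + window]
        patterns: dict[str, int] = {}
        for v in vecs:
            got = {p: c for p, c in v}
            if all(p in got for p in win):
                pat = "".join(got[p] for p in win)
                patterns[pat] = patterns.get(pat, 0) + 1
        tot = sum(patterns.values())
        if tot == 0:
            continue
        h = -sum((k / tot) * math.log2(k / tot) for k in patterns.values())
        entropies.append(h)
    entropy = float(np.mean(entropies)) if entropies else nan

    # MHL over substring lengths 1..L with linear weights
    num = 0.0
    den = 0.0
    max_len = max(len(v) for v in vecs)
    for length in range(1, max_len + 1):
        instances = 0
        fully = 0
        for v in vecs:
            for j in range(len(v) - length + 1):
                instances += 1
                if all(c == "M" for _, c in v[j : j + length]):
                    fully += 1
        if instances == 0:
            continue
        num += length * (fully / instances)
        den += length
    mhl = num / den if den else nan

    # MCR: concordance of within-read adjacent call pairs
    pairs = 0
    concordant = 0
    for v in vecs:
        for (_, c1), (_, c2) in zip(v, v[1:]):
            pairs += 1
            concordant += c1 == c2
    mcr = concordant / pairs if pairs else nan

    # MBS: squared methylated-run lengths normalized by read length
    scores = []
    for v in vecs:
        length = len(v)
        run = 0
        score = 0.0
        for _, c in v + [(None, "U")]:
            if c == "M":
                run += 1
            else:
                score += (run / length) ** 2
                run = 0
        scores.append(score)
    mbs = float(np.mean(scores))

    lds = adjacent_mld(reads, positions, min_pair_reads=min_pair_reads)
    defined = [ld.r2 for ld in lds if ld.r2 is not None]
    mean_r2 = float(np.mean(defined)) if defined else nan

    return FragmentMetrics(pdr, entropy, chalm, mhl, mcr, mbs, mean_r2)


# ---------------------------------------------------------------------------
# SNP-partitioned ASM (short-read mode)


@dataclass(frozen=True)
class AlleleASMResult:
    region: GenomicInterval
    ref_meth: int
    ref_unmeth: int
    alt_meth: int
    alt_unmeth: int
    p: float
    q: float = float("nan")
    is_asm: bool = False


SKIP_NO_SNP = "no_tagged_snp"
SKIP_FEW_READS = "group_below_min_reads"


def test_allele_asm(
    reads: Sequence[ReadRecord],
    region: GenomicInterval,
    min_reads: int = 8,
    min_cpgs: int = 4,
) -> AlleleASMResult | tuple[None, str]:
    """Fisher test of methylated vs unmethylated reads between SNP alleles.

    Reads spanning fewer than ``min_cpgs`` in-region CpGs are dropped;
    remaining reads are classified and undetermined reads excluded from the
    2x2 table. Each allele group must retain at least ``min_reads`` classified
    reads, else the region is skipped with a reason code. The returned result
    carries the raw p; q/is_asm are filled by :func:`test_allele_asm_batch`.
    """
    counts = {("ref", METHYLATED): 0, ("ref", UNMETHYLATED): 0,
              ("alt", METHYLATED): 0, ("alt", UNMETHYLATED): 0}
    tagged = False
    for read in reads:
        if read.allele_tag not in ("ref", "alt"):
            continue
        tagged = True
        if len(read.calls_in(region.start, region.end)) < min_cpgs:
            continue
        label = classify_read(read, region)
        if label in (METHYLATED, UNMETHYLATED):
            counts[(read.allele_tag, label)] += 1
    if not tagged:
        return None, SKIP_NO_SNP
    ref_m = counts[("ref", METHYLATED)]
    ref_u = counts[("ref", UNMETHYLATED)]
    alt_m = counts[("alt", METHYLATED)]
    alt_u = counts[("alt", UNMETHYLATED)]
    if ref_m + ref_u < min_reads or alt_m + alt_u < min_reads:
        return None, SKIP_FEW_READS
    p = fisher_two_sided(ref_m, ref_u, alt_m, alt_u)
    return AlleleASMResult(region, ref_m, ref_u, alt_m, alt_u, p)


def test_allele_asm_batch(
    regions_reads: Sequence[tuple[GenomicInterval, Sequence[ReadRecord]]],
    alpha: float = 0.05,
    min_reads: int = 8,
    min_cpgs: int = 4,
) -> tuple[list[AlleleASMResult], list[tuple[GenomicInterval, str]]]:
    """Run :func:`test_allele_asm` over regions; BH across tested regions."""
    tested: list[AlleleASMResult] = []
    skipped: list[tuple[GenomicInterval, str]] = []
    for region, reads in regions_reads:
        res = test_allele_asm(reads, region, min_reads=min_reads, min_cpgs=min_cpgs)
        if isinstance(res, tuple):
            skipped.append((region, res[1]))
        else:
            tested.append(res)
    if tested:
        qs = bh_adjust([r.p for r in tested])
        tested = [
            AlleleASMResult(
                r.region, r.ref_meth, r.ref_unmeth, r.alt_meth, r.alt_unmeth,
                r.p, float(q), bool(q < alpha),
            )
            for r, q in zip(tested, qs)
        ]
    return tested, skipped


# ---------------------------------------------------------------------------
# methylation LD and block discovery


@dataclass(frozen=True)
class CpGPairLD:
    chrom: str
    pos_a: int
    pos_b: int
    n_reads: int
    r2: float | None  # None when undefined (few reads or zero variance)


@dataclass(frozen=True)
class MHBlock:
    """A methylation haplotype block: >=4 consecutive CpGs, adjacent r2 >= 0.5."""

    interval: GenomicInterval
    cpg_positions: tuple[int, ...]
    r2_values: tuple[float, ...]

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def adjacent_mld(
    reads: Sequence[ReadRecord],
    cpg_positions: Sequence[int],
    min_pair_reads: int = 10,
    chrom: str | None = None,
) -> list[CpGPairLD]:
    """mLD r² for each adjacent CpG pair of ``cpg_positions``.

    r² is the squared Pearson correlation between the two binary call vectors
    over reads covering both CpGs; it is undefined (``None``) when fewer than
    ``min_pair_reads`` reads cover the pair or either CpG has zero variance.
    """
    positions = sorted(cpg_positions)
    if chrom is None and reads:
        chrom = reads[0].chrom
    use = [r for r in reads if chrom is None or r.chrom == chrom]
    wanted = set(positions)
    per_read = [
        {p: 1 if c == "M" else 0 for p, c in r.calls if p in wanted} for r in use
    ]
    out = []
    for a, b in zip(positions, positions[1:]):
        x = []
        y = []
        for calls in per_read:
            if a in calls and b in calls:
                x.append(calls[a])
                y.append(calls[b])
        n = len(x)
        r2: float | None = None
        if n >= min_pair_reads:
            xa = np.asarray(x, dtype=float)
            ya = np.asarray(y, dtype=float)
            vx = xa.var()
            vy = ya.var()
            if vx > 0 and vy > 0:
                cov = ((xa - xa.mean()) * (ya - ya.mean())).mean()
                r2 = float(cov * cov / (vx * vy))
        out.append(CpGPairLD(chrom or "", a, b, n, r2))
    return out


def find_blocks(
    pair_lds: Sequence[CpGPairLD],
    r2_threshold: float = 0.5,
    min_cpgs: int = 4,
) -> list[MHBlock]:
    """Maximal runs of consecutive CpGs whose every adjacent pair passes.

    An undefined pair (r² None) breaks a run. A run of k passing pairs spans
    k + 1 CpGs and becomes a block when that count reaches ``min_cpgs``. The
    block interval covers the CpG dinucleotides: [first_pos, last_pos + 2).
    """
    blocks: list[MHBlock] = []
    run_pairs: list[CpGPairLD] = []

    def flush() -> None:
        if len(run_pairs) + 1 >= min_cpgs:
            positions = [run_pairs[0].pos_a] + [p.pos_b for p in run_pairs]
            blocks.append(
                MHBlock(
                    GenomicInterval(run_pairs[0].chrom, positions[0], positions[-1] + 2),
                    tuple(positions),
                    tuple(p.r2 for p in run_pairs),  # type: ignore[arg-type]
                )
            )
        run_pairs.clear()

    for ld in pair_lds:
        passes = ld.r2 is not None and ld.r2 >= r2_threshold
        chained = (
            run_pairs
            and ld.chrom == run_pairs[-1].chrom
            and ld.pos_a == run_pairs[-1].pos_b
        )
        if passes and (chained or not run_pairs):
            run_pairs.append(ld)
        else:
            flush()
            if passes:
                run_pairs.append(ld)
    flush()
    return blocks


EXCLUDE_OUT_OF_RANGE = "normal_mean_outside_range"
EXCLUDE_NO_COVERAGE = "no_coverage_in_normal"


@dataclass(frozen=True)
class IMRBlock:
    """An MHB with consistently intermediate methylation in all normal samples."""

    block: MHBlock
    normal_means: tuple[float, ...]

    @property
    def interval(self) -> GenomicInterval:
        return self.block.interval

    @property
    def cpg_positions(self) -> tuple[int, ...]:
        return self.block.cpg_positions


def select_imr_blocks(
    blocks: Sequence[MHBlock],
    normal_tracks: Sequence[MethylationTrack],
    low: float = 0.3,
    high: float = 0.7,
) -> tuple[list[IMRBlock], list[tuple[MHBlock, str]]]:
    """Retain blocks whose weighted mean lies in [low, high] in every normal."""
    per_track = [
        aggregate_intervals(t, [b.interval for b in blocks]) for t in normal_tracks
    ]
    kept: list[IMRBlock] = []
    excluded: list[tuple[MHBlock, str]] = []
    for i, block in enumerate(blocks):
        means = [per_track[t][i].weighted_mean for t in range(len(normal_tracks))]
        if any(math.isnan(m) for m in means):
            excluded.append((block, EXCLUDE_NO_COVERAGE))
        elif all(low <= m <= high for m in means):
            kept.append(IMRBlock(block, tuple(means)))
        else:
            excluded.append((block, EXCLUDE_OUT_OF_RANGE))
    return kept, excluded
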