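"""DMR calling, recurrence hotspots, IMR flagging and chromatin-state enrichment.

The DMR caller here is a deliberately simple stand-in for smoothed
beta-binomial callers (DSS-style): it runs a per-CpG two-sided Fisher exact
test on (meth, unmeth) counts between a sample and a reference track,
BH-adjusts across tested CpGs, merges significant CpGs into regions and
retains regions by CpG count and coverage-weighted methylation difference.
It is validated on synthetic data only; the scientific payload of this module
is the recurrence ("hotspot") logic layered on top of any per-sample DMR set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import aggregate_intervals
from .intervals import GenomicInterval, IntervalSet, multi_intersect
from .io import MethylationTrack
from .readlevel import bh_adjust, fisher_two_sided

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class DMRCall:
    interval: GenomicInterval
    n_cpgs: int
    sample_mean: float
    reference_mean: float
    p: float
    q: float

    @property
    def diff(self) -> float:
        return self.sample_mean - self.reference_mean


@dataclass(frozen=True)
class HotspotRegion:
    interval: GenomicInterval
    recurrence: int
    n_cpgs: int


@dataclass(frozen=True)
class EnrichmentRow:
    state_label: str
    block_fraction: float
    background_fraction: float

    @property
    def fold(self) -> float:
        if self.background_fraction == 0:
            return float("nan")
        return self.block_fraction / self.background_fraction


def call_dmrs(
    sample_track: MethylationTrack,
    reference_track: MethylationTrack,
    fdr: float = 0.05,
    min_diff: float = 0.3,
    cpg_q: float = 0.05,
    cpg_min_delta: float = 0.1,
    merge_gap: int = 300,
    min_cpgs: int = 3,
    autosomes_only: bool = True,
    haplotypes: tuple[str, str] = ("combined", "combined"),
) -> list[DMRCall]:
    """Stand-in DMR caller between a sample and a reference track.

    Per-CpG Fisher exact tests on shared covered CpGs are BH-adjusted;
    significant CpGs (q < ``cpg_q`` and per-CpG |delta| >= ``cpg_min_delta``)
    closer than ``merge_gap`` bp are merged; a region is reported when it
    contains >= ``min_cpgs`` significant CpGs, its coverage-weighted
    |difference| exceeds ``min_diff`` and its region-level q < ``fdr``.
    """
    s = sample_track.haplotype(haplotypes[0])
    r = reference_track.haplotype(haplotypes[1])
    merged = s.merge(r, on=["chrom", "pos"], suffixes=("_s", "_r"))
    merged = merged[
        (merged.meth_s + merged.unmeth_s > 0) & (merged.meth_r + merged.unmeth_r > 0)
    ]
    if autosomes_only:
        merged = merged[~merged["chrom"].isin(SEX_CHROMS)]
    if merged.empty:
        return []
    merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
    ps = np.array(
        [
            fisher_two_sided(row.meth_s, row.unmeth_s, row.meth_r, row.unmeth_r)
            for row in merged.itertuples(index=False)
        ]
    )
    qs = bh_adjust(ps)
    frac_s = merged.meth_s / (merged.meth_s + merged.unmeth_s)
    frac_r = merged.meth_r / (merged.meth_r + merged.unmeth_r)
    sig = (qs < cpg_q) & (np.abs(frac_s - frac_r) >= cpg_min_delta)

    candidates: list[tuple[str, list[int]]] = []
    cur_chrom = None
    cur: list[int] = []
    for idx in np.flatnonzero(sig.to_numpy() if hasattr(sig, "to_numpy") else sig):
        chrom = merged.chrom.iat[idx]
        pos = int(merged.pos.iat[idx])
        if cur and chrom == cur_chrom and pos - cur[-1] <= merge_gap:
            cur.append(pos)
        else:
            if cur:
                candidates.append((cur_chrom, cur))
            cur_chrom, cur = chrom, [pos]
    if cur:
        candidates.append((cur_chrom, cur))

    calls: list[tuple[GenomicInterval, int, float, float, float]] = []
    for chrom, positions in candidates:
        if len(positions) < min_cpgs:
            continue
        iv = GenomicInterval(chrom, positions[0], positions[-1] + 2)
        in_iv = (merged.chrom == chrom) & (merged.pos >= iv.start) & (merged.pos < iv.end)
        ms, us = int(merged.meth_s[in_iv].sum()), int(merged.unmeth_s[in_iv].sum())
        mr, ur = int(merged.meth_r[in_iv].sum()), int(merged.unmeth_r[in_iv].sum())
        mean_s = ms / (ms + us)
        mean_r = mr / (mr + ur)
        if abs(mean_s - mean_r) <= min_diff:
            continue
        p_region = fisher_two_sided(ms, us, mr, ur)
        calls.append((iv, len(positions), mean_s, mean_r, p_region))
    if not calls:
        return []
    qs_region = bh_adjust([c[4] for c in calls])
    return [
        DMRCall(iv, n, mean_s, mean_r, p, float(q))
        for (iv, n, mean_s, mean_r, p), q in zip(calls, qs_region)
        if q < fdr
    ]


def find_hotspots(
    dmr_sets: Sequence[IntervalSet],
    track: MethylationTrack,
    min_recurrence: int = 25,
    min_cpgs: int = 5,
) -> list[HotspotRegion]:
    """Recurrence hotspots from per-sample DMR interval sets.

    Per-sample sets are already normalized (IntervalSet), so each sample
    contributes at most once per base. Segments covered by >= min_recurrence
    samples are merged when adjacent, annotated with the maximum per-base
    recurrence, and dropped unless >= ``min_cpgs`` CpG records of ``track``
    (the pooled-normal track) fall inside.
    """
    segments = multi_intersect(dmr_sets)
    retained = [(iv, n) for iv, n in segments if n >= min_recurrence]
    if not retained:
        return []
    # merge touching retained segments, carrying the max recurrence
    merged: list[tuple[GenomicInterval, int]] = []
    for iv, n in retained:
        if merged and merged[-1][0].chrom == iv.chrom and iv.start <= merged[-1][0].end:
            prev, pn = merged[-1]
            merged[-1] = (GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end)),
                          max(pn, n))
        else:
            merged.append((iv, n))
    sub = track.haplotype("combined")
    out = []
    for iv, n in merged:
        in_iv = (sub.chrom == iv.chrom) & (sub.pos >= iv.start) & (sub.pos < iv.end)
        n_cpg = int(in_iv.sum())
        if n_cpg >= min_cpgs:
            out.append(HotspotRegion(iv, n, n_cpg))
    return out


def flag_intermediate(
    regions: Sequence[GenomicInterval],
    normal_track: MethylationTrack,
    low: float = 0.3,
    high: float = 0.7,
) -> list[tuple[GenomicInterval, bool | None]]:
    """Flag each region as IMR (inclusive bounds); None when unobserved."""
    flags: list[tuple[GenomicInterval, bool | None]] = []
    for summary in aggregate_intervals(normal_track, regions):
        wm = summary.weighted_mean
        if math.isnan(wm):
            flags.append((summary.interval, None))
        else:
            flags.append((summary.interval, low <= wm <= high))
    return flags


def state_enrichment(
    blocks: Sequence[GenomicInterval],
    state_annotation: Mapping[str, IntervalSet],
    genome_span: int,
) -> list[EnrichmentRow]:
    """Fold enrichment of block base pairs per chromatin state vs background.

    fold = (block bp in state / total block bp) / (state bp / genome_span).
    """
    total_block_bp = sum(iv.length for iv in blocks)
    if total_block_bp == 0:
        raise ValueError("no block bp to enrich")
    rows = []
    for label, states in state_annotation.items():
        in_state = sum(states.overlap_bp(iv) for iv in blocks)
        rows.append(
            EnrichmentRow(
                label,
                in_state / total_block_bp,
                states.total_bp() / genome_span,
            )
        )
    return rows


def dmr_calls_to_set(calls: Sequence[DMRCall], label: str = "") -> IntervalSet:
    return IntervalSet([c.interval for c in calls], label=label)


def calls_frame(calls: Sequence[DMRCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "n_cpgs": c.n_cpgs,
                "sample_mean": c.sample_mean,
                "reference_mean": c.reference_mean,
                "diff": c.diff,
                "p": c.p,
                "q": c.q,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "n_cpgs", "sample_mean",
                 "reference_mean", "diff", "p", "q"],
    )
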