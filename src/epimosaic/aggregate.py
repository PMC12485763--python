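"""Coverage-weighted aggregation of CpG counts over intervals, and pooling.

The weighted mean of an interval is the ratio of summed methylated calls to
summed total calls over the CpGs inside it — not the mean of per-CpG
fractions — so deeply covered CpGs carry proportionally more weight.
Zero-coverage intervals get a missing value (NaN), never 0, so downstream
filters can distinguish "unmethylated" from "unobserved".
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import MethylationTrack, TRACK_COLUMNS, ValidationError


@dataclass(frozen=True)
class RegionSummary:
    interval: GenomicInterval
    n_cpgs_covered: int
    meth_sum: int
    total_sum: int

    @property
    def weighted_mean(self) -> float:
        if self.total_sum == 0:
            return float("nan")
        return self.meth_sum / self.total_sum


def aggregate_intervals(
    track: MethylationTrack,
    intervals: Sequence[GenomicInterval],
    haplotype: str = "combined",
) -> list[RegionSummary]:
    """Summarize CpG counts of one haplotype over each interval.

    Membership is half-open: a CpG at ``pos`` belongs to [start, end) iff
    ``start <= pos < end``. ``n_cpgs_covered`` counts CpGs with at least one
    call.
    """
    sub = track.haplotype(haplotype)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValidationError(f"track {track.sample_id}: unsorted positions")
        meth = np.concatenate([[0], np.cumsum(grp["meth"].to_numpy())])
        total = np.concatenate(
            [[0], np.cumsum((grp["meth"] + grp["unmeth"]).to_numpy())]
        )
        covered = np.concatenate(
            [[0], np.cumsum(((grp["meth"] + grp["unmeth"]) > 0).to_numpy())]
        )
        by_chrom[chrom] = (pos, meth, total, covered)
    out = []
    for iv in intervals:
        if iv.chrom not in by_chrom:
            out.append(RegionSummary(iv, 0, 0, 0))
            continue
        pos, meth, total, covered = by_chrom[iv.chrom]
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        out.append(
            RegionSummary(
                iv,
                int(covered[hi] - covered[lo]),
                int(meth[hi] - meth[lo]),
                int(total[hi] - total[lo]),
            )
        )
    return out


def summaries_frame(summaries: Iterable[RegionSummary]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "n_cpgs_covered": s.n_cpgs_covered,
            "meth_sum": s.meth_sum,
            "total_sum": s.total_sum,
            "weighted_mean": s.weighted_mean,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_cpgs_covered",
            "meth_sum",
            "total_sum",
            "weighted_mean",
        ],
    )


def pool_tracks(
    tracks: Sequence[MethylationTrack], sample_id: str = "pooled"
) -> MethylationTrack:
    """Sum counts per (chrom, pos, haplotype) across samples (outer join)."""
    if not tracks:
        raise ValidationError("pool_tracks: no tracks given")
    df = pd.concat([t.df for t in tracks], ignore_index=True)
    pooled = df.groupby(["chrom", "pos", "haplotype"], as_index=False)[
        ["meth", "unmeth"]
    ].sum()
    return MethylationTrack(sample_id, pooled.reindex(columns=TRACK_COLUMNS))


def weighted_mean(track: MethylationTrack, interval: GenomicInterval,
                  haplotype: str = "combined") -> float:
    """Convenience scalar: coverage-weighted mean of one interval."""
    [summary] = aggregate_intervals(track, [interval], haplotype=haplotype)
    return summary.weighted_mean
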