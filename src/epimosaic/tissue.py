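"""Tissue-specific IMR definition and per-region-class epimutation rates.

Tissue-specific intermediately methylated blocks are defined from per-tissue
normal block sets in three steps: (1) keep blocks present (>= 1 bp overlap)
in every normal sample of a tissue; (2) merge retained blocks from all
tissues (minimum block size 50 bp, minimum distance between blocks 50 bp);
(3) keep a block for a tissue iff its matched-tissue mean methylation lies in
[0.3, 0.7] with coefficient of variation <= 0.5 across matched samples and
differs by >= 0.2 from the average of non-matched tissue samples — the delta
filter removes germline-imprint-like blocks that are intermediate everywhere.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .aggregate import aggregate_intervals
from .hapcalls import block_epimutation_batch
from .intervals import GenomicInterval, IntervalSet, merge_intervals
from .io import MethylationTrack

EXCLUDE_NO_COVERAGE = "no_coverage"
EXCLUDE_NOT_INTERMEDIATE = "matched_mean_outside_range"
EXCLUDE_HIGH_CV = "matched_cv_above_max"
EXCLUDE_LOW_DELTA = "delta_below_min"


@dataclass(frozen=True)
class TissueIMRCandidate:
    interval: GenomicInterval
    matched_means: tuple[float, ...]
    other_mean: float

    @property
    def matched_mean(self) -> float:
        return sum(self.matched_means) / len(self.matched_means)

    @property
    def matched_cv(self) -> float:
        """Coefficient of variation (sample sd, n-1) over matched samples."""
        if len(self.matched_means) < 2:
            return 0.0
        mean = self.matched_mean
        if mean == 0:
            return float("inf")
        return statistics.stdev(self.matched_means) / mean

    @property
    def delta(self) -> float:
        return abs(self.matched_mean - self.other_mean)


def consistent_blocks(
    per_tissue_sample_sets: Mapping[str, Sequence[IntervalSet]],
    min_size: int = 50,
    max_gap: int = 50,
) -> IntervalSet:
    """Blocks present in all normal samples per tissue, merged across tissues.

    Presence is >= 1 bp overlap with a block in every sample's set (block
    boundaries vary slightly per sample). The retained blocks from all
    tissues are then merged with the stated minimum size and distance.
    """
    retained: list[GenomicInterval] = []
    for tissue, sample_sets in per_tissue_sample_sets.items():
        if not sample_sets:
            continue
        for block in sample_sets[0]:
            if all(s.overlaps(block) for s in sample_sets[1:]):
                retained.append(block)
    return merge_intervals(retained, max_gap=max_gap, min_size=min_size,
                           label="consistent_blocks")


def tissue_specific_imrs(
    candidates: Sequence[GenomicInterval],
    matched_tracks: Sequence[MethylationTrack],
    other_tracks: Sequence[MethylationTrack],
    low: float = 0.3,
    high: float = 0.7,
    max_cv: float = 0.5,
    min_delta: float = 0.2,
) -> tuple[list[TissueIMRCandidate], list[tuple[GenomicInterval, str]]]:
    """Apply the intermediate/CV/delta filters to candidate blocks.

    ``other_mean`` averages per-sample weighted means (not pooled counts)
    across non-matched samples, so deeply covered samples do not dominate.
    The three predicates commute; exclusion reasons report the first failure
    in the order coverage, range, CV, delta.
    """
    matched = [aggregate_intervals(t, candidates) for t in matched_tracks]
    others = [aggregate_intervals(t, candidates) for t in other_tracks]
    kept: list[TissueIMRCandidate] = []
    excluded: list[tuple[GenomicInterval, str]] = []
    for i, iv in enumerate(candidates):
        m_means = [matched[s][i].weighted_mean for s in range(len(matched_tracks))]
        o_means = [others[s][i].weighted_mean for s in range(len(other_tracks))]
        if any(math.isnan(m) for m in m_means + o_means):
            excluded.append((iv, EXCLUDE_NO_COVERAGE))
            continue
        cand = TissueIMRCandidate(iv, tuple(m_means),
                                  sum(o_means) / len(o_means))
        if not (low <= cand.matched_mean <= high):
            excluded.append((iv, EXCLUDE_NOT_INTERMEDIATE))
        elif cand.matched_cv > max_cv:
            excluded.append((iv, EXCLUDE_HIGH_CV))
        elif cand.delta < min_delta:
            excluded.append((iv, EXCLUDE_LOW_DELTA))
        else:
            kept.append(cand)
    return kept, excluded


def regionclass_epimutation_rates(
    region_sets_by_class: Mapping[str, Sequence[GenomicInterval]],
    tumor_tracks: Sequence[MethylationTrack],
    normal_track: MethylationTrack,
    alpha: float = 0.05,
    min_diff: float = 0.3,
    min_covered_cpgs: int = 4,
    min_adjusted_cov: float = 5.0,
) -> pd.DataFrame:
    """Percent of regions per class with a significant epimutation per sample.

    For every tumor sample and region class the epimutation Fisher test is
    applied per region (coverage rules as for blocks) with BH adjustment per
    class per sample. Percentages over both evaluable regions and all regions
    of the class are reported; a class with zero evaluable regions yields
    missing percentages.
    """
    rows = []
    for track in tumor_tracks:
        for cls, regions in region_sets_by_class.items():
            calls, skipped = block_epimutation_batch(
                list(regions), track, normal_track,
                alpha=alpha, min_diff=min_diff,
                min_covered_cpgs=min_covered_cpgs,
                min_adjusted_cov=min_adjusted_cov,
            )
            n_eval = len(calls)
            n_diff = sum(c.is_epimutation for c in calls)
            rows.append(
                {
                    "sample": track.sample_id,
                    "region_class": cls,
                    "n_regions": len(regions),
                    "n_evaluable": n_eval,
                    "n_differential": n_diff,
                    "percent_of_evaluable": 100 * n_diff / n_eval if n_eval else float("nan"),
                    "percent_of_all": 100 * n_diff / len(regions) if regions else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "region_class", "n_regions", "n_evaluable",
                 "n_differential", "percent_of_evaluable", "percent_of_all"],
    )
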