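"""Synthetic clonal methylome generator with ground truth.

The generator emulates the generative hypothesis under study: discrete blocks
of correlated CpGs at which every cell of a population independently
methylates one haplotype at random (probability ``asm_prob`` for haplotype 1).
A bulk, polyclonal population therefore shows intermediate methylation on
both haplotypes at such blocks, while a single-cell-derived clone shows clean
allele-specific methylation (ASM) whose methylated haplotype varies — or
"switches" — between clones. Epimutated blocks are fully methylated or
unmethylated on both haplotypes; confounder blocks (imprinted, SV-adjacent,
SNP-dense, chrX) carry ASM-like signal that the exclusion filters must
remove; independent-null blocks have per-call coin-flip methylation with no
read-level correlation.

Geometry follows the observed block anatomy: each block has 4–20 CpGs (mean
12) spanning ~186 bp, placed on a synthetic 10 Mb contig "chrS" plus a small
"chrX" decoy. Per-call error is ``error_rate``; read depth is Poisson with
mean ``mean_coverage`` per CpG. All randomness flows through one seeded
generator: identical config (including seed) gives byte-identical output.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import pool_tracks
from .intervals import GenomicInterval, IntervalSet
from .io import MethylationTrack, ReadRecord, TRACK_COLUMNS

# block truth labels
RANDOM_ASM = "random-ASM"
CONST_METH = "constitutive-methylated"
CONST_UNMETH = "constitutive-unmethylated"
EPI_HYPER = "epimutated-hyper"
EPI_HYPO = "epimutated-hypo"
IMPRINTED = "imprinted"
SV_ADJACENT = "SV-adjacent"
SNP_DENSE = "SNP-dense"
CHRX = "chrX"
INDEPENDENT_NULL = "independent-null"

# labels whose per-cell behaviour is a random haplotype choice
ASM_LIKE = (RANDOM_ASM, SV_ADJACENT, SNP_DENSE, CHRX, EPI_HYPER, EPI_HYPO)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic methylome.

    Probabilities must lie in [0, 1]; identical configs produce identical
    output.
    """

    # genome
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    chrx: str = "chrX"
    chrx_length: int = 1_000_000
    # block geometry: 4-20 CpGs per block (mean 12), ~186 bp span
    min_cpgs_per_block: int = 4
    max_cpgs_per_block: int = 20
    block_span_bp_mean: float = 186.0
    # block counts per truth label
    n_asm_blocks: int = 200
    n_meth_blocks: int = 20
    n_unmeth_blocks: int = 20
    n_epimutated_blocks: int = 20
    n_imprinted_blocks: int = 10
    n_sv_blocks: int = 10
    n_snp_dense_blocks: int = 10
    n_chrx_blocks: int = 10
    n_null_blocks: int = 0
    # populations
    n_cells: int = 10_000
    n_clones: int = 11
    n_normal_samples: int = 4
    asm_prob: float = 0.5          # pi: P(cell methylates haplotype 1)
    epimutation_rate: float = 0.0  # P(clone epimutates an ASM block instead)
    hyper_bias: float = 0.7        # P(an epimutation is hyper)
    error_rate: float = 0.02       # epsilon: per-call flip probability
    mean_coverage: float = 30.0    # Poisson mean per CpG (haplotypes sum)
    fragment_span_cpgs: int = 6    # short-read fragment span in CpGs
    # SNP model: a uniform one-SNP-per-window background lattice (plus one
    # het SNP per block) against which dense windows stand out sharply
    snp_window: int = 10_000
    snp_per_window: int = 1
    snp_dense_count: int = 100        # SNPs added to each dense window
    # tissue panel
    n_tissues: int = 3
    samples_per_tissue: int = 3
    n_tissue_blocks: int = 30
    n_pan_tissue_blocks: int = 10
    n_inconsistent_blocks: int = 10
    n_class_regions: int = 40
    tumor_diff_fraction: float = 0.4
    class_diff_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("asm_prob", "epimutation_rate", "hyper_bias", "error_rate",
                     "tumor_diff_fraction", "class_diff_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_cells", "n_clones", "n_normal_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_cpgs_per_block < 2:
            raise ValueError("blocks need at least 2 CpGs")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class BlockTruth:
    block_id: str
    label: str
    interval: GenomicInterval
    cpg_positions: tuple[int, ...]
    snp_pos: int
    sv_breakpoint: tuple[str, int] | None = None

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass
class SyntheticTruth:
    """Planted block anatomy plus per-cell/per-clone methylation states."""

    blocks: list[BlockTruth]
    snp_positions: list[tuple[str, int]]
    sv_breakpoints: list[tuple[str, int]]
    dense_windows: IntervalSet
    clone_states: pd.DataFrame | None = None  # block_id x clone state labels

    def by_label(self, *labels: str) -> list[BlockTruth]:
        return [b for b in self.blocks if b.label in labels]

    def block(self, block_id: str) -> BlockTruth:
        return next(b for b in self.blocks if b.block_id == block_id)

    def imprinted_set(self) -> IntervalSet:
        return IntervalSet([b.interval for b in self.by_label(IMPRINTED)],
                           label="imprinted")


# ---------------------------------------------------------------------------
# genome layout


def _draw_block_positions(rng: np.random.Generator, anchor: int,
                          cfg: SimulationConfig) -> tuple[int, ...]:
    n = int(rng.integers(cfg.min_cpgs_per_block, cfg.max_cpgs_per_block + 1))
    mean_cpgs = (cfg.min_cpgs_per_block + cfg.max_cpgs_per_block) / 2
    mean_gap = max(2.0, cfg.block_span_bp_mean / (mean_cpgs - 1))
    gaps = 2 + rng.poisson(mean_gap - 2, size=n - 1)
    positions = anchor + np.concatenate([[0], np.cumsum(gaps)])
    return tuple(int(p) for p in positions)


def layout_genome(cfg: SimulationConfig,
                  rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Place blocks, SNPs, SV breakpoints and dense windows; no counts yet."""
    if rng is None:
        rng = cfg.rng()
    labels = (
        [RANDOM_ASM] * cfg.n_asm_blocks
        + [CONST_METH] * cfg.n_meth_blocks
        + [CONST_UNMETH] * cfg.n_unmeth_blocks
        + [EPI_HYPER if rng.random() < cfg.hyper_bias else EPI_HYPO
           for _ in range(cfg.n_epimutated_blocks)]
        + [IMPRINTED] * cfg.n_imprinted_blocks
        + [SV_ADJACENT] * cfg.n_sv_blocks
        + [SNP_DENSE] * cfg.n_snp_dense_blocks
        + [INDEPENDENT_NULL] * cfg.n_null_blocks
    )
    labels = [labels[i] for i in rng.permutation(len(labels))]

    blocks: list[BlockTruth] = []
    snps: list[tuple[str, int]] = []
    svs: list[tuple[str, int]] = []
    dense_windows: list[GenomicInterval] = []

    slot = cfg.chrom_length // (len(labels) + 2)
    for i, label in enumerate(labels):
        anchor = (i + 1) * slot + int(rng.integers(0, max(1, slot // 4)))
        if label == SNP_DENSE:
            # anchor the block inside its own 10 kb window and densify it
            wstart = (anchor // cfg.snp_window) * cfg.snp_window
            dense_windows.append(
                GenomicInterval(cfg.chrom, wstart,
                                min(wstart + cfg.snp_window, cfg.chrom_length))
            )
        positions = _draw_block_positions(rng, anchor, cfg)
        interval = GenomicInterval(cfg.chrom, positions[0], positions[-1] + 2)
        mid = len(positions) // 2 - 1
        snp_pos = (positions[mid] + positions[mid + 1]) // 2
        sv = None
        if label == SV_ADJACENT:
            sv = (cfg.chrom, max(0, interval.start - int(rng.integers(100, 900))))
            svs.append(sv)
        blocks.append(BlockTruth(f"b{i:04d}", label, interval, positions, snp_pos, sv))
        snps.append((cfg.chrom, snp_pos))

    xslot = cfg.chrx_length // (cfg.n_chrx_blocks + 2) if cfg.n_chrx_blocks else 0
    for j in range(cfg.n_chrx_blocks):
        anchor = (j + 1) * xslot + int(rng.integers(0, max(1, xslot // 4)))
        positions = _draw_block_positions(rng, anchor, cfg)
        xcfg = GenomicInterval(cfg.chrx, positions[0], positions[-1] + 2)
        mid = len(positions) // 2 - 1
        snp_pos = (positions[mid] + positions[mid + 1]) // 2
        blocks.append(
            BlockTruth(f"x{j:04d}", CHRX, xcfg, positions, snp_pos, None)
        )
        snps.append((cfg.chrx, snp_pos))

    # baseline SNP lattice, then densify the planted windows
    for chrom, length in ((cfg.chrom, cfg.chrom_length), (cfg.chrx, cfg.chrx_length)):
        for w in range(length // cfg.snp_window):
            base = w * cfg.snp_window
            for k in range(cfg.snp_per_window):
                off = (k + 1) * cfg.snp_window // (cfg.snp_per_window + 1)
                snps.append((chrom, base + off))
    for w in dense_windows:
        snps.extend(
            (w.chrom, int(p))
            for p in np.sort(rng.integers(w.start, w.end, size=cfg.snp_dense_count))
        )
    return SyntheticTruth(blocks, snps, svs, IntervalSet(dense_windows, "dense"))


# ---------------------------------------------------------------------------
# per-state methylation probabilities

_STATE_P: dict[str, tuple[str, str]] = {
    "hap1": ("meth", "unmeth"),
    "hap2": ("unmeth", "meth"),
    "meth": ("meth", "meth"),
    "unmeth": ("unmeth", "unmeth"),
    "hyper": ("meth", "meth"),
    "hypo": ("unmeth", "unmeth"),
    "null": ("coin", "coin"),
}


def _p_call(side: str, eps: float) -> float:
    return {"meth": 1.0 - eps, "unmeth": eps, "coin": 0.5}[side]


def state_hap_probs(state: str, eps: float) -> tuple[float, float]:
    """Per-call methylation probability (hap1, hap2) for a cell/clone state."""
    s1, s2 = _STATE_P[state]
    return _p_call(s1, eps), _p_call(s2, eps)


def _clone_state(label: str, cfg: SimulationConfig,
                 rng: np.random.Generator) -> str:
    if label in (RANDOM_ASM, SV_ADJACENT, SNP_DENSE, CHRX):
        if cfg.epimutation_rate > 0 and rng.random() < cfg.epimutation_rate:
            return "hyper" if rng.random() < cfg.hyper_bias else "hypo"
        return "hap1" if rng.random() < cfg.asm_prob else "hap2"
    if label == CONST_METH:
        return "meth"
    if label == CONST_UNMETH:
        return "unmeth"
    if label == EPI_HYPER:
        return "hyper"
    if label == EPI_HYPO:
        return "hypo"
    if label == IMPRINTED:
        return "hap1"
    if label == INDEPENDENT_NULL:
        return "null"
    raise ValueError(f"unknown label {label}")


def _normal_hap_probs(label: str, cfg: SimulationConfig) -> tuple[float, float]:
    """Per-call probabilities in a polyclonal normal population."""
    eps = cfg.error_rate
    pi = cfg.asm_prob
    if label in ASM_LIKE or label == INDEPENDENT_NULL:
        # reads sample random cells: mixture of methylated and unmethylated
        p1 = pi * (1 - eps) + (1 - pi) * eps
        p2 = (1 - pi) * (1 - eps) + pi * eps
        if label == INDEPENDENT_NULL:
            p1 = p2 = 0.5
        return p1, p2
    if label == IMPRINTED:
        return 1 - eps, eps
    if label == CONST_METH:
        return 1 - eps, 1 - eps
    if label == CONST_UNMETH:
        return eps, eps
    raise ValueError(f"unknown label {label}")


def _track_from_counts(sample_id: str, truth: SyntheticTruth,
                       meth: dict[str, np.ndarray],
                       total: dict[str, np.ndarray]) -> MethylationTrack:
    """Build a hap1/hap2/combined track from per-CpG count arrays."""
    chroms = []
    pos = []
    for b in truth.blocks:
        chroms.extend([b.interval.chrom] * b.n_cpgs)
        pos.extend(b.cpg_positions)
    frames = []
    comb_m = meth["hap1"] + meth["hap2"]
    comb_t = total["hap1"] + total["hap2"]
    for hap, m, t in (("combined", comb_m, comb_t),
                      ("hap1", meth["hap1"], total["hap1"]),
                      ("hap2", meth["hap2"], total["hap2"])):
        frames.append(pd.DataFrame({
            "chrom": chroms, "pos": pos, "haplotype": hap,
            "meth": m.astype(np.int64), "unmeth": (t - m).astype(np.int64),
        }))
    df = pd.concat(frames, ignore_index=True)
    return MethylationTrack(sample_id, df.reindex(columns=TRACK_COLUMNS))


# ---------------------------------------------------------------------------
# population and clone simulations


@dataclass
class PopulationSim:
    config: SimulationConfig
    truth: SyntheticTruth
    bulk_track: MethylationTrack
    cell_calls: dict[str, np.ndarray]  # hap -> (n_cells, n_cpgs) uint8
    cpg_index: pd.DataFrame            # block_id, chrom, pos per column


def simulate_population(cfg: SimulationConfig) -> PopulationSim:
    """A polyclonal cell population; each cell contributes one call per CpG
    per haplotype. Bulk counts are the exact per-cell column sums."""
    rng = cfg.rng()
    truth = layout_genome(cfg, rng)
    eps = cfg.error_rate
    n_cells = cfg.n_cells

    index_rows = []
    col_probs_h1 = []
    col_probs_h2 = []
    for b in truth.blocks:
        if b.label in ASM_LIKE:
            hap1_meth_cell = rng.random(n_cells) < cfg.asm_prob
            p1 = np.where(hap1_meth_cell, 1 - eps, eps)
            p2 = np.where(hap1_meth_cell, eps, 1 - eps)
        elif b.label == IMPRINTED:
            p1 = np.full(n_cells, 1 - eps)
            p2 = np.full(n_cells, eps)
        elif b.label == CONST_METH:
            p1 = p2 = np.full(n_cells, 1 - eps)
        elif b.label == CONST_UNMETH:
            p1 = p2 = np.full(n_cells, eps)
        elif b.label == INDEPENDENT_NULL:
            p1 = p2 = np.full(n_cells, 0.5)
        else:
            raise AssertionError(b.label)
        for pos in b.cpg_positions:
            index_rows.append((b.block_id, b.interval.chrom, pos))
            col_probs_h1.append(p1)
            col_probs_h2.append(p2)

    calls = {}
    for hap, cols in (("hap1", col_probs_h1), ("hap2", col_probs_h2)):
        probs = np.stack(cols, axis=1)  # (n_cells, n_cpgs)
        calls[hap] = (rng.random(probs.shape) < probs).astype(np.uint8)
    meth = {h: calls[h].sum(axis=0).astype(np.int64) for h in calls}
    total = {h: np.full(meth[h].shape, n_cells, dtype=np.int64) for h in calls}
    track = _track_from_counts("population_bulk", truth, meth, total)
    cpg_index = pd.DataFrame(index_rows, columns=["block_id", "chrom", "pos"])
    return PopulationSim(cfg, truth, track, calls, cpg_index)


@dataclass
class CloneSim:
    config: SimulationConfig
    truth: SyntheticTruth
    clone_tracks: dict[str, MethylationTrack]
    bulk_track: MethylationTrack
    normal_track: MethylationTrack

    @property
    def clone_states(self) -> pd.DataFrame:
        assert self.truth.clone_states is not None
        return self.truth.clone_states


def simulate_clone_set(cfg: SimulationConfig) -> CloneSim:
    """Single-cell-derived clones plus their bulk and a pooled-normal track.

    Each clone independently draws a methylated haplotype per ASM-like block
    (haplotype 1 with probability ``asm_prob``); epimutated blocks are hyper
    or hypo per the block's truth label in every clone. Per-CpG, per-haplotype
    depth is Poisson(mean_coverage / 2) and methylated counts binomial.
    """
    rng = cfg.rng()
    truth = layout_genome(cfg, rng)
    eps = cfg.error_rate
    clones = [f"clone{i + 1:02d}" for i in range(cfg.n_clones)]

    states = pd.DataFrame(index=[b.block_id for b in truth.blocks],
                          columns=clones, dtype=object)
    for b in truth.blocks:
        for clone in clones:
            states.at[b.block_id, clone] = _clone_state(b.label, cfg, rng)
    truth.clone_states = states

    n_cpgs = sum(b.n_cpgs for b in truth.blocks)
    clone_tracks: dict[str, MethylationTrack] = {}
    for clone in clones:
        meth = {}
        total = {}
        for hi, hap in enumerate(("hap1", "hap2")):
            p = np.empty(n_cpgs)
            at = 0
            for b in truth.blocks:
                probs = state_hap_probs(states.at[b.block_id, clone], eps)
                p[at:at + b.n_cpgs] = probs[hi]
                at += b.n_cpgs
            depth = rng.poisson(cfg.mean_coverage / 2, size=n_cpgs)
            meth[hap] = rng.binomial(depth, p)
            total[hap] = depth
        clone_tracks[clone] = _track_from_counts(clone, truth, meth, total)

    bulk = pool_tracks(list(clone_tracks.values()), sample_id="clone_bulk")

    meth_n = {}
    total_n = {}
    for hi, hap in enumerate(("hap1", "hap2")):
        p = np.empty(n_cpgs)
        at = 0
        for b in truth.blocks:
            p[at:at + b.n_cpgs] = _normal_hap_probs(b.label, cfg)[hi]
            at += b.n_cpgs
        depth = rng.poisson(cfg.n_normal_samples * cfg.mean_coverage / 2,
                            size=n_cpgs)
        meth_n[hap] = rng.binomial(depth, p)
        total_n[hap] = depth
    normal = _track_from_counts("normal_pooled", truth, meth_n, total_n)
    return CloneSim(cfg, truth, clone_tracks, bulk, normal)


# ---------------------------------------------------------------------------
# read emission


def emit_reads(
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    mode: str = "long",
    block_states: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
    prefix: str = "r",
    coverage_scale: float = 1.0,
) -> list[ReadRecord]:
    """Emit per-read CpG calls for one sample.

    ``block_states`` maps block_id to a clone state ("hap1", "hap2", "meth",
    "unmeth", "hyper", "hypo", "null"); when None, the sample is a polyclonal
    population and each molecule draws its own cell state. Long mode emits
    haplotype-tagged reads spanning whole blocks; short mode emits fragments
    of ``fragment_span_cpgs`` consecutive CpGs carrying an allele tag when
    they overlap the block's planted SNP (allele "ref" is haplotype 1).
    Per-CpG depth is approximately Poisson(mean_coverage * coverage_scale);
    pass ``coverage_scale=n_normal_samples`` to emulate reads pooled across
    normal donors, as used for block discovery.
    """
    if mode not in ("long", "short"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = cfg.rng()
    eps = cfg.error_rate
    coverage = cfg.mean_coverage * coverage_scale
    reads: list[ReadRecord] = []
    counter = 0

    def molecule_probs(block: BlockTruth, hap_idx: int) -> float | None:
        """Per-call M probability for one molecule, or None for null blocks."""
        if block.label == INDEPENDENT_NULL:
            return None
        if block_states is not None:
            state = block_states[block.block_id]
        elif block.label in ASM_LIKE:
            state = "hap1" if rng.random() < cfg.asm_prob else "hap2"
        elif block.label == IMPRINTED:
            state = "hap1"
        elif block.label == CONST_METH:
            state = "meth"
        else:
            state = "unmeth"
        return state_hap_probs(state, eps)[hap_idx]

    for block in truth.blocks:
        positions = block.cpg_positions
        if mode == "long":
            for hap_idx, hap in enumerate(("hap1", "hap2")):
                n_reads = rng.poisson(coverage / 2)
                for _ in range(n_reads):
                    p = molecule_probs(block, hap_idx)
                    if p is None:
                        flips = rng.random(len(positions)) < 0.5
                    else:
                        flips = rng.random(len(positions)) < p
                    calls = tuple(
                        (pos, "M" if m else "U") for pos, m in zip(positions, flips)
                    )
                    reads.append(ReadRecord(f"{prefix}{counter:07d}",
                                            block.interval.chrom, calls,
                                            "none", hap))
                    counter += 1
        else:
            # fragments of `span` consecutive CpGs; per-start Poisson rate
            # chosen so interior CpGs see ~mean_coverage total depth
            span = max(cfg.fragment_span_cpgs, 4)
            span = min(span, len(positions))
            starts = range(0, len(positions) - span + 1)
            lam_start = coverage / (2 * span)
            for hap_idx in (0, 1):
                for s in starts:
                    for _ in range(rng.poisson(lam_start)):
                        window = positions[s:s + span]
                        p = molecule_probs(block, hap_idx)
                        if p is None:
                            flips = rng.random(span) < 0.5
                        else:
                            flips = rng.random(span) < p
                        calls = tuple(
                            (pos, "M" if m else "U")
                            for pos, m in zip(window, flips)
                        )
                        allele = "none"
                        if window[0] <= block.snp_pos <= window[-1]:
                            allele = "ref" if hap_idx == 0 else "alt"
                        reads.append(ReadRecord(f"{prefix}{counter:07d}",
                                                block.interval.chrom, calls,
                                                allele, "none"))
                        counter += 1
    return reads


# ---------------------------------------------------------------------------
# tissue panel


@dataclass
class TissueSim:
    config: SimulationConfig
    tissues: list[str]
    block_sets: dict[str, list[IntervalSet]]       # tissue -> per-sample sets
    tissue_blocks: pd.DataFrame                    # block_id, tissue, coords, label
    normal_tracks: dict[str, list[MethylationTrack]]
    tumor_tracks: dict[str, list[MethylationTrack]]
    class_regions: dict[str, list[GenomicInterval]]
    planted_differential: dict[str, set[str]]      # tumor sample -> region keys


def simulate_tissue_panel(cfg: SimulationConfig) -> TissueSim:
    """Multi-tissue normal/tumor panel for the tissue-specific IMR analysis.

    Per tissue: ``n_tissue_blocks`` tissue-specific blocks (intermediate 0.5
    in matched samples, fully methylated or unmethylated elsewhere, direction
    drawn per block), plus shared pan-tissue imprint-like blocks intermediate
    in every tissue, plus blocks present in only a subset of samples
    (label "inconsistent"). CpG-island/TSS/enhancer-like region classes are
    planted with a smaller differential fraction than the IMR blocks.
    """
    rng = cfg.rng()
    tissues = [f"tissue{i + 1}" for i in range(cfg.n_tissues)]
    rows = []
    regions_all: list[tuple[str, str, tuple[int, ...]]] = []

    n_slots = (cfg.n_tissues * cfg.n_tissue_blocks + cfg.n_pan_tissue_blocks
               + cfg.n_inconsistent_blocks + 3 * cfg.n_class_regions)
    slot = cfg.chrom_length // (n_slots + 2)
    slot_i = 0

    def next_positions() -> tuple[int, ...]:
        nonlocal slot_i
        anchor = (slot_i + 1) * slot + int(rng.integers(0, max(1, slot // 4)))
        slot_i += 1
        return _draw_block_positions(rng, anchor, cfg)

    bid = 0
    for tissue in tissues:
        for _ in range(cfg.n_tissue_blocks):
            positions = next_positions()
            direction = "meth" if rng.random() < 0.5 else "unmeth"
            rows.append({"block_id": f"t{bid:04d}", "tissue": tissue,
                         "label": "tissue-specific", "direction": direction,
                         "positions": positions})
            bid += 1
    for _ in range(cfg.n_pan_tissue_blocks):
        rows.append({"block_id": f"t{bid:04d}", "tissue": "all",
                     "label": "pan-tissue", "direction": "none",
                     "positions": next_positions()})
        bid += 1
    for _ in range(cfg.n_inconsistent_blocks):
        tissue = tissues[int(rng.integers(len(tissues)))]
        rows.append({"block_id": f"t{bid:04d}", "tissue": tissue,
                     "label": "inconsistent", "direction": "meth",
                     "positions": next_positions()})
        bid += 1
    blocks = pd.DataFrame(rows)
    blocks["start"] = blocks["positions"].map(lambda p: p[0])
    blocks["end"] = blocks["positions"].map(lambda p: p[-1] + 2)

    class_levels = {"CpG_islands": 0.1, "TSS": 0.1, "enhancers": 0.9}
    class_regions: dict[str, list[GenomicInterval]] = {}
    class_positions: dict[str, list[tuple[int, ...]]] = {}
    for cls in class_levels:
        ivs = []
        pos_list = []
        for _ in range(cfg.n_class_regions):
            positions = next_positions()
            ivs.append(GenomicInterval(cfg.chrom, positions[0], positions[-1] + 2))
            pos_list.append(positions)
        class_regions[cls] = ivs
        class_positions[cls] = pos_list

    def block_level(row, tissue: str) -> float:
        if row.label == "pan-tissue" or row.tissue == tissue:
            return 0.5
        return 0.9 if row.direction == "meth" else 0.1

    def sample_track(sample_id: str, levels: dict[tuple[int, ...], float]
                     ) -> MethylationTrack:
        chroms, pos, meth, unmeth = [], [], [], []
        for positions, level in levels.items():
            depth = rng.poisson(cfg.mean_coverage, size=len(positions))
            m = rng.binomial(depth, level)
            chroms.extend([cfg.chrom] * len(positions))
            pos.extend(positions)
            meth.extend(m.tolist())
            unmeth.extend((depth - m).tolist())
        df = pd.DataFrame({"chrom": chroms, "pos": pos, "haplotype": "combined",
                           "meth": meth, "unmeth": unmeth})
        return MethylationTrack(sample_id, df.reindex(columns=TRACK_COLUMNS))

    # per-sample block interval sets (jittered; inconsistent blocks dropped
    # from all but the first sample of their tissue)
    block_sets: dict[str, list[IntervalSet]] = {}
    normal_tracks: dict[str, list[MethylationTrack]] = {}
    tumor_tracks: dict[str, list[MethylationTrack]] = {}
    planted: dict[str, set[str]] = {}

    for tissue in tissues:
        sets = []
        tracks = []
        for s in range(cfg.samples_per_tissue):
            ivs = []
            for row in blocks.itertuples(index=False):
                present = (
                    row.label == "pan-tissue"
                    or (row.label == "tissue-specific" and row.tissue == tissue)
                    or (row.label == "inconsistent" and row.tissue == tissue and s == 0)
                )
                if not present:
                    continue
                j1 = int(rng.integers(-10, 11))
                j2 = int(rng.integers(-10, 11))
                start = max(0, row.start + j1)
                end = max(start + 1, row.end + j2)
                ivs.append(GenomicInterval(cfg.chrom, start, end))
            sets.append(IntervalSet(ivs, label=f"{tissue}_s{s + 1}"))

            levels: dict[tuple[int, ...], float] = {}
            for row in blocks.itertuples(index=False):
                levels[row.positions] = block_level(row, tissue)
            for cls, level in class_levels.items():
                for positions in class_positions[cls]:
                    levels[positions] = level
            tracks.append(sample_track(f"{tissue}_normal{s + 1}", levels))
        block_sets[tissue] = sets
        normal_tracks[tissue] = tracks

        # tumors for this tissue
        tumors = []
        for t in range(1):
            sample_id = f"{tissue}_tumor{t + 1}"
            hit: set[str] = set()
            levels = {}
            for row in blocks.itertuples(index=False):
                base = block_level(row, tissue)
                level = base
                is_matched_block = (row.label == "tissue-specific"
                                    and row.tissue == tissue)
                if is_matched_block and rng.random() < cfg.tumor_diff_fraction:
                    level = 0.95 if rng.random() < 0.5 else 0.05
                    hit.add(GenomicInterval(cfg.chrom, row.start, row.end).key())
                levels[row.positions] = level
            for cls, base in class_levels.items():
                for positions in class_positions[cls]:
                    level = base
                    if rng.random() < cfg.class_diff_fraction:
                        level = min(0.95, base + 0.5) if base < 0.5 else max(0.05, base - 0.5)
                        hit.add(GenomicInterval(cfg.chrom, positions[0],
                                                positions[-1] + 2).key())
                    levels[positions] = level
            tumors.append(sample_track(sample_id, levels))
            planted[sample_id] = hit
        tumor_tracks[tissue] = tumors

    return TissueSim(cfg, tissues, block_sets, blocks, normal_tracks,
                     tumor_tracks, class_regions, planted)


# ---------------------------------------------------------------------------
# file emission for the CLI / analysis drivers


def write_truth_bed(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        for b in sorted(truth.blocks, key=lambda b: b.interval):
            fh.write(f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}"
                     f"\t{b.label}\t{b.block_id}\n")


def write_point_bed(points: Sequence[tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in sorted(points):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
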