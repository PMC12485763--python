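import numpy as np
import pandas as pd
import pytest

from epimosaic.intervals import GenomicInterval
from epimosaic.io import MethylationTrack, ReadRecord, TRACK_COLUMNS
from epimosaic.simulate import SimulationConfig, simulate_clone_set


def make_track(sample_id, rows):
    """rows: (chrom, pos, haplotype, meth, unmeth) tuples."""
    return MethylationTrack(sample_id, pd.DataFrame(rows, columns=TRACK_COLUMNS))


def make_reads(chrom, patterns, positions, allele_tags=None, hap_tags=None,
               prefix="r"):
    """One read per pattern string ('M'/'U' per position, '.' = not covered)."""
    reads = []
    for i, pat in enumerate(patterns):
        calls = tuple(
            (pos, ch) for pos, ch in zip(positions, pat) if ch != "."
        )
        reads.append(
            ReadRecord(
                f"{prefix}{i}", chrom, calls,
                allele_tags[i] if allele_tags else "none",
                hap_tags[i] if hap_tags else "none",
            )
        )
    return reads


@pytest.fixture(scope="session")
def small_clone_sim():
    """A modest clone-set simulation shared by read-only tests."""
    cfg = SimulationConfig(seed=20, n_asm_blocks=40, n_clones=6,
                           n_meth_blocks=6, n_unmeth_blocks=6,
                           n_epimutated_blocks=8, n_imprinted_blocks=4,
                           n_sv_blocks=4, n_snp_dense_blocks=4, n_chrx_blocks=4)
    return simulate_clone_set(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)
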