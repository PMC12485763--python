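"""Cross-sample clonal analyses: haplotype switching, timepoint concordance
and the per-sample fraction of allelic blocks.

All comparisons assume a common haplotype frame: phasing assigns "hap1" and
"hap2" arbitrarily per run, so cross-sample state matrices must be built from
haplotype-synchronized calls (or corrected with an explicit per-sample flip
mapping) before switching or concordance is interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .hapcalls import ASM_HAP1, ASM_HAP2, HYPER, HYPO

ASM_STATES = (ASM_HAP1, ASM_HAP2)
ALLELIC_STATES = (ASM_HAP1, ASM_HAP2, HYPER, HYPO)
EPIMUTATION_STATES = (HYPER, HYPO)


class CloneBlockMatrix:
    """Blocks x samples matrix of block-state labels in one haplotype frame.

    ``states`` is a DataFrame indexed by block key with one column per
    sample/clone; cells hold state labels (ASM_hap1_meth, ASM_hap2_meth,
    hyper, hypo, intermediate, indeterminate) or NA for inevaluable blocks.
    """

    def __init__(self, states: pd.DataFrame, synchronized: bool = True,
                 flips: Mapping[str, bool] | None = None):
        if flips:
            states = states.copy()
            swap = {ASM_HAP1: ASM_HAP2, ASM_HAP2: ASM_HAP1}
            for col, flip in flips.items():
                if flip:
                    states[col] = states[col].map(lambda s: swap.get(s, s))
            synchronized = True
        self.states = states
        self.synchronized = synchronized

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)


@dataclass(frozen=True)
class SwitchingSummary:
    n_informative_blocks: int
    n_concordant: int
    n_switched: int

    @property
    def switched_fraction(self) -> float:
        if self.n_informative_blocks == 0:
            return float("nan")
        return self.n_switched / self.n_informative_blocks


def switching_summary(
    matrix: CloneBlockMatrix, min_asm_samples: int = 4
) -> SwitchingSummary:
    """Concordant vs switched methylated haplotype across clones.

    Blocks with ASM in at least ``min_asm_samples`` clones are informative; a
    block is concordant iff every ASM clone methylates the same haplotype.
    """
    if not matrix.synchronized:
        raise ValueError("clone matrix is not haplotype-synchronized")
    n_inf = n_conc = n_switch = 0
    for _, row in matrix.states.iterrows():
        asm = [s for s in row if s in ASM_STATES]
        if len(asm) < min_asm_samples:
            continue
        n_inf += 1
        if len(set(asm)) == 1:
            n_conc += 1
        else:
            n_switch += 1
    return SwitchingSummary(n_inf, n_conc, n_switch)


def timepoint_concordance(
    states_t1: Mapping[str, str],
    states_t2: Mapping[str, str],
    category: str,
) -> tuple[float, int]:
    """Fraction of blocks with the same significant call at both timepoints.

    ``category`` is "ASM" or "epimutation". The denominator is blocks with a
    significant call of that category at both timepoints; an ASM block is
    concordant iff the methylated haplotype matches, an epimutation block iff
    the direction (hyper/hypo) matches. Returns (fraction, denominator);
    fraction is NaN for an empty denominator.
    """
    if category == "ASM":
        members = ASM_STATES
    elif category == "epimutation":
        members = EPIMUTATION_STATES
    else:
        raise ValueError(f"unknown category {category!r}")
    denom = 0
    concordant = 0
    for block, s1 in states_t1.items():
        s2 = states_t2.get(block)
        if s1 in members and s2 in members:
            denom += 1
            concordant += s1 == s2
    return (concordant / denom if denom else float("nan")), denom


@dataclass(frozen=True)
class AllelicFraction:
    n_universe: int
    n_evaluable: int
    n_allelic: int

    @property
    def fraction_of_universe(self) -> float:
        return self.n_allelic / self.n_universe

    @property
    def fraction_of_evaluable(self) -> float:
        if self.n_evaluable == 0:
            return float("nan")
        return self.n_allelic / self.n_evaluable


def allelic_block_fraction(
    sample_states: Mapping[str, str],
    block_universe: Sequence[str],
) -> AllelicFraction:
    """Fraction of the fixed block universe that is ASM or hyper/hypo.

    Blocks absent from ``sample_states`` (or with NA state) are inevaluable;
    fractions over both the full universe and the evaluable subset are
    reported.
    """
    if not block_universe:
        raise ValueError("empty block universe")
    n_eval = 0
    n_allelic = 0
    for block in block_universe:
        state = sample_states.get(block)
        if state is None or (isinstance(state, float) and pd.isna(state)):
            continue
        n_eval += 1
        if state in ALLELIC_STATES:
            n_allelic += 1
    return AllelicFraction(len(block_universe), n_eval, n_allelic)
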