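"""Phase-switch-error detection from patterns of adjacent IBD fragments.

A phase switch error in an individual moves every downstream allele to the
complementary haplotype, so every IBD segment spanning the switch is broken
into two fragments: on the *same* haplotype in the unaffected individual and
on *complementary* haplotypes in the affected one.  When a newly found
fragment between individuals P and Q begins near the end of an open fragment
between the same two individuals, the haplotype arrangement of the two
fragments identifies which individual (if any) switched:

==================  ==========================  =========================
haplotype in P      haplotype in Q              inferred scenario
==================  ==========================  =========================
same                same                        fragments of one segment
complementary       complementary               switch in both P and Q
same                complementary               switch in Q
complementary       same                        switch in P
==================  ==========================  =========================

Fragments that do not begin near the end of the open fragment are unrelated.

When a switch is inferred, the affected individual's haplotypes are swapped
for all future sites in *all* templates (a single global orientation per
individual), so the correction is consistent across every pair that
individual shares IBD with, and segment triangulation within a cohort is
preserved.  For haploid data the heuristic is disabled
(:attr:`tpbwt.tpbwt_core.TPBWTParams.haploid`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class AdjacencyScenario(enum.Enum):
    MERGE_SAME = "merge_same"
    SWITCH_BOTH = "switch_both"
    SWITCH_P = "switch_P"
    SWITCH_Q = "switch_Q"
    UNRELATED = "unrelated"


def classify_adjacent_segments(
    existing: tuple[int, int, int, int],
    new: tuple[int, int, int, int],
    tolerance_sites: int,
) -> AdjacencyScenario:
    """Classify a new match fragment against an existing one.

    Each match is ``(hap_p, hap_q, start_site, end_site)`` where ``hap_p``
    belongs to individual P and ``hap_q`` to individual Q; both matches must
    involve the same two individuals.  The new fragment is "adjacent" when its
    start lies within ``tolerance_sites`` of the existing fragment's end
    (small overlap or small gap); everything else is unrelated.
    """
    hp, hq, _, e_end = existing
    np_, nq, n_start, _ = new
    if hp >> 1 != np_ >> 1 or hq >> 1 != nq >> 1:
        raise ValueError("matches involve different individual pairs")
    if n_start - e_end > tolerance_sites:  # gap too large; overlap is adjacent
        return AdjacencyScenario.UNRELATED
    same_p = hp == np_
    same_q = hq == nq
    if same_p and same_q:
        return AdjacencyScenario.MERGE_SAME
    if not same_p and not same_q:
        return AdjacencyScenario.SWITCH_BOTH
    if same_p:
        return AdjacencyScenario.SWITCH_Q
    return AdjacencyScenario.SWITCH_P


@dataclass
class SwapState:
    """Per-individual haplotype orientation during a sweep.

    ``swapped[i]`` is True while individual ``i``'s haplotype rows are
    logically exchanged; toggling twice restores the original orientation.
    ``last_switch_site[i]`` records where the most recent switch was inferred,
    used to suppress duplicate evidence of the same switch arriving from
    other pairs.
    """

    swapped: dict[int, bool] = field(default_factory=dict)
    last_switch_site: dict[int, int] = field(default_factory=dict)

    def is_swapped(self, individual: int) -> bool:
        return self.swapped.get(individual, False)

    def toggle(self, individual: int, site: int) -> None:
        self.swapped[individual] = not self.swapped.get(individual, False)
        self.last_switch_site[individual] = site


def apply_phase_switch(state: SwapState, individual: int, site: int) -> SwapState:
    """Swap the individual's haplotypes from ``site`` forward (an involution)."""
    state.toggle(individual, site)
    return state
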