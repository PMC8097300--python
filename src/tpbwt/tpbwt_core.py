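"""Templated PBWT sweep: error-robust haplotype matching and IBD reporting.

The positional Burrows-Wheeler transform (PBWT) keeps, at every site ``k``, the
haplotypes sorted by their reversed prefixes (the positional prefix array,
``ppa``) together with the site at which each adjacent pair of haplotypes
began matching (the divergence array, ``div``).  Exact identical-by-state runs
can then be enumerated in a single left-to-right pass.

The templated PBWT adds a third dimension: ``t`` repeating binary masks
("templates") over sites.  Each template maintains its own ``ppa``/``div``
columns and skips its masked sites, so a genotyping error can break a match in
at most some of the templates while the others carry it through.  Candidate
match fragments emitted by all templates are merged in shared current-match
arrays (``Ps``/``Pe`` keyed by haplotype pair), gaps shorter than ``L_m``
sites are bridged, and a phase-correction heuristic (see
:mod:`tpbwt.phase_correction`) stitches fragments that were separated by
phase switch errors.  Only merged segments at least ``L_f`` cM long are
reported.

With one all-ones template, no missing data and phase correction disabled,
the machinery collapses to the plain PBWT and reports exactly the maximal
exact matches of at least ``L_m`` sites (merged across sub-``L_m`` gaps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .haplotype_io import MISSING, HaplotypeAlignment

__all__ = [
    "TemplateSet",
    "TPBWTParams",
    "IBDSegment",
    "MatchTracker",
    "SweepDebug",
    "default_templates",
    "pbwt_template",
    "template_count",
    "binomial_error_probability",
    "compute_ibd_in_sample",
]

_SENTINEL = 1 << 60


@dataclass(frozen=True)
class TemplateSet:
    """A set of ``t`` repeating site masks with a common period.

    ``masks[j][k % period] == 1`` means template ``j`` processes site ``k``;
    0 means the site is skipped (masked) by that template.  Every residue
    class must be processed by at least one template, otherwise some sites
    would never be compared.
    """

    masks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("template set needs at least one mask")
        period = len(self.masks[0])
        if any(len(m) != period for m in self.masks):
            raise ValueError("all masks must share one period")
        if any(v not in (0, 1) for m in self.masks for v in m):
            raise ValueError("masks must be binary")
        for r in range(period):
            if not any(m[r] for m in self.masks):
                raise ValueError(f"site residue {r} is masked by every template")

    @property
    def t(self) -> int:
        return len(self.masks)

    @property
    def period(self) -> int:
        return len(self.masks[0])

    def processes(self, j: int, k: int) -> bool:
        """The indicator T(j, k): does template ``j`` process site ``k``?"""
        return bool(self.masks[j][k % self.period])

    def __eq__(self, other) -> bool:  # frozen dataclass on tuples
        return isinstance(other, TemplateSet) and self.masks == other.masks

    def __hash__(self) -> int:
        return hash(self.masks)


def default_templates() -> TemplateSet:
    """The six period-4 masks processing every 2-of-4 site combination.

    Any arrangement of two errors within a four-site window falls entirely in
    the masked half of at least one template, so such errors can never break a
    match in all templates at once.
    """
    return TemplateSet(
        masks=(
            (0, 1, 0, 1),
            (1, 0, 1, 0),
            (0, 0, 1, 1),
            (1, 1, 0, 0),
            (0, 1, 1, 0),
            (1, 0, 0, 1),
        )
    )


def pbwt_template() -> TemplateSet:
    """Single all-ones template: the sweep collapses to the plain PBWT."""
    return TemplateSet(masks=((1,),))


def template_count(window_n: int, max_errors_k: int) -> int:
    """Number of templates needed to guarantee matches across any window of
    ``window_n`` sites containing at most ``max_errors_k`` errors: C(n, k)."""
    if max_errors_k < 0 or window_n < 0:
        raise ValueError("window size and error count must be non-negative")
    if max_errors_k > window_n:
        raise ValueError("cannot have more errors than sites in the window")
    return math.comb(window_n, max_errors_k)


def binomial_error_probability(n: int, j: int, p: float) -> float:
    """Probability of exactly ``j`` independent errors among ``n`` sites with
    per-site error rate ``p``: C(n, j) p^j (1-p)^(n-j)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("error rate must be a probability in [0, 1]")
    if not 0 <= j <= n:
        raise ValueError("need 0 <= j <= n")
    from scipy.stats import binom

    return float(binom.pmf(j, n, p))


@dataclass
class TPBWTParams:
    """Tuning parameters of the sweep.

    L_m
        Minimum span, in alignment sites, for a match fragment to be emitted
        and to extend/merge other fragments; also the gap (in sites) bridged
        when merging fragments and the adjacency tolerance of the
        phase-correction classifier.
    L_f
        Minimum genetic length (cM) for a merged segment to be reported.
    M_t
        Maximum run of consecutive missing sites a match is extended through;
        longer runs terminate the match.
    """

    L_m: int = 200
    L_f: float = 3.0
    M_t: int = 10
    phase_correction: bool = True
    haploid: bool = False
    include_self_pairs: bool = False

    def __post_init__(self) -> None:
        if self.L_m < 1:
            raise ValueError("L_m must be >= 1 site")
        if self.L_f < 0:
            raise ValueError("L_f must be >= 0 cM")
        if self.M_t < 0:
            raise ValueError("M_t must be >= 0")

    @property
    def correction_active(self) -> bool:
        return self.phase_correction and not self.haploid


@dataclass(frozen=True)
class IBDSegment:
    """A reported match between two haplotypes, with site/bp/cM extents."""

    hap_a: int
    hap_b: int
    start_site: int
    end_site: int
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    id1: str = ""
    id2: str = ""
    chromosome: str = "1"

    def __post_init__(self) -> None:
        if self.hap_a >= self.hap_b:
            raise ValueError("segments require hap_a < hap_b")
        if self.start_site > self.end_site:
            raise ValueError("segment start after end")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def interval_cm(self) -> tuple[float, float]:
        return (self.start_cm, self.end_cm)


class SweepDebug:
    """Optional instrumentation: inner-loop op counts, order hooks, checks."""

    def __init__(
        self,
        check_permutations: bool = False,
        on_order: Callable[[int, int, list[int]], None] | None = None,
    ) -> None:
        self.inner_ops = 0
        self.check_permutations = check_permutations
        self.on_order = on_order

    def observe(self, j: int, k: int, ppa: list[int]) -> None:
        self.inner_ops += len(ppa)
        if self.check_permutations:
            if sorted(ppa) != list(range(len(ppa))):
                raise AssertionError(f"ppa column {j} at site {k} is not a permutation")
        if self.on_order is not None:
            self.on_order(j, k, ppa)


class MatchTracker:
    """The current-match arrays Ps/Pe plus merge and phase-switch logic.

    Open matches are kept sparsely, keyed by the (ordered) haplotype pair.
    ``add_fragment`` implements the merge rules: overlapping fragments and
    fragments separated by fewer than ``L_m`` sites extend the open match;
    fragments adjacent to an open match on complementary haplotypes trigger
    the phase-correction classifier; a displaced open match is reported iff
    its genetic length reaches ``L_f``.
    """

    def __init__(
        self,
        params: TPBWTParams,
        cm: np.ndarray,
        on_switch: Callable[[int, int], None] | None = None,
        pair_filter: Callable[[int, int], bool] | None = None,
    ) -> None:
        self.params = params
        self.cm = cm
        self.on_switch = on_switch
        self.pair_filter = pair_filter
        self.open: dict[tuple[int, int], list[int]] = {}
        self.reported: list[tuple[int, int, int, int]] = []
        # per individual: positions of applied switches plus the sweep
        # positions where they took effect (both are places from which
        # duplicate evidence keeps arriving and must not re-toggle)
        self.switch_sites: dict[int, list[int]] = {}
        self.current_site = 0

    # -- helpers ---------------------------------------------------------
    def _report_if_long(self, a: int, b: int, s: int, e: int) -> None:
        if self.cm[e] - self.cm[s] >= self.params.L_f:
            self.reported.append((a, b, s, e))

    def _request_switch(self, individual: int, at_site: int) -> None:
        # Suppress duplicate evidence: after a switch is corrected, the
        # individual's other pairs re-deliver fragments starting at the same
        # inferred position (and at the sweep position where the relabelling
        # cut their open matches); acting on those again would ping-pong the
        # orientation.  Distinct switches further apart than L_m sites are
        # always applied.
        sites = self.switch_sites.setdefault(individual, [])
        if any(abs(at_site - s) <= self.params.L_m for s in sites):
            return
        sites.append(at_site)
        if self.current_site - at_site > self.params.L_m:
            sites.append(self.current_site)
        if self.on_switch is not None:
            self.on_switch(individual, at_site)

    # -- main entry ------------------------------------------------------
    def add_fragment(self, a: int, b: int, start: int, end: int) -> None:
        if a > b:
            a, b = b, a
        if self.pair_filter is not None and not self.pair_filter(a, b):
            return
        ind_a, ind_b = a >> 1, b >> 1
        if ind_a == ind_b and not self.params.include_self_pairs:
            return
        L_m = self.params.L_m
        key = (a, b)
        cur = self.open.get(key)
        # Fig 12B: same haplotypes, overlapping or separated by a short gap.
        if cur is not None and start - cur[1] - 1 < L_m:
            if start < cur[0]:
                cur[0] = start
            if end > cur[1]:
                cur[1] = end
            return
        if self.params.correction_active and ind_a != ind_b:
            if self._try_switch_merge(a, b, start, end):
                return
        if cur is not None:
            self._report_if_long(a, b, cur[0], cur[1])
        self.open[key] = [start, end]

    def _try_switch_merge(self, a: int, b: int, start: int, end: int) -> bool:
        """The fragment begins near the end of an open match between the same
        two individuals but on complementary haplotypes: a phase switch."""
        from .phase_correction import AdjacencyScenario, classify_adjacent_segments

        L_m = self.params.L_m
        switch_for = {
            AdjacencyScenario.SWITCH_P: (a >> 1,),
            AdjacencyScenario.SWITCH_Q: (b >> 1,),
            AdjacencyScenario.SWITCH_BOTH: (a >> 1, b >> 1),
        }
        candidates: list[tuple[int, tuple[int, int], tuple[int, ...]]] = []
        for ka, kb in ((a ^ 1, b ^ 1), (a, b ^ 1), (a ^ 1, b)):
            okey = (ka, kb) if ka < kb else (kb, ka)
            ocur = self.open.get(okey)
            if ocur is None:
                continue
            scenario = classify_adjacent_segments(
                (ka, kb, ocur[0], ocur[1]), (a, b, start, end), L_m
            )
            if scenario in switch_for:
                candidates.append((abs(start - ocur[1]), okey, switch_for[scenario]))
        if not candidates:
            return False
        candidates.sort(key=lambda c: c[0])
        _, okey, switch_inds = candidates[0]
        ocur = self.open[okey]
        if start < ocur[0]:
            ocur[0] = start
        if end > ocur[1]:
            ocur[1] = end
        for ind in switch_inds:
            self._request_switch(ind, start)
        return True

    def finalize(self) -> list[tuple[int, int, int, int]]:
        for (a, b), (s, e) in self.open.items():
            self._report_if_long(a, b, s, e)
        self.open.clear()
        return self.reported


def resolve_missing_column(raw: list[int], div: list[int]) -> list[int]:
    """Impute missing alleles (in ppa order) by the neighbouring haplotype
    that carries the longer current match (smaller divergence value); ties go
    to the predecessor.  Non-missing alleles pass through unchanged."""
    m = len(raw)
    resolved = list(raw)
    for pos in range(m):
        if raw[pos] >= 0:
            continue
        succ_raw = raw[pos + 1] if pos < m - 1 else MISSING
        if pos > 0 and (pos == m - 1 or succ_raw < 0 or div[pos] <= div[pos + 1]):
            resolved[pos] = resolved[pos - 1]
        elif succ_raw >= 0:
            resolved[pos] = succ_raw
        elif pos > 0:
            resolved[pos] = resolved[pos - 1]
        else:
            resolved[pos] = 0
    return resolved


def advance_order(
    ppa: list[int], div: list[int], resolved: list[int], next_k: int
) -> tuple[list[int], list[int]]:
    """One stable counting-sort step of the PBWT: partition haplotypes by
    allele while carrying divergence (match-start) bookkeeping to ``next_k``."""
    s0 = s1 = next_k
    p0: list[int] = []
    p1: list[int] = []
    d0: list[int] = []
    d1: list[int] = []
    for pos in range(len(ppa)):
        d = div[pos]
        if d > s0:
            s0 = d
        if d > s1:
            s1 = d
        if resolved[pos] == 0:
            p0.append(ppa[pos])
            d0.append(s0)
            s0 = 0
        else:
            p1.append(ppa[pos])
            d1.append(s1)
            s1 = 0
    p0.extend(p1)
    d0.extend(d1)
    return p0, d0


class _TemplateState:
    __slots__ = ("ppa", "div", "prev_k", "last_k")

    def __init__(self, m: int) -> None:
        self.ppa = list(range(m))
        self.div = [0] * m
        self.prev_k: int | None = None
        self.last_k: int | None = None


class SweepEngine:
    """One left-to-right pass of the templated PBWT over an allele source.

    ``column(k)`` of the source returns the raw alleles of all *physical*
    haplotype rows at site ``k``; the engine applies the current per-individual
    phase-swap orientation on top, so a phase switch corrected in one template
    immediately affects every template.
    """

    def __init__(
        self,
        column: Callable[[int], Sequence[int]],
        n_haplotypes: int,
        n_sites: int,
        cm: np.ndarray,
        templates: TemplateSet,
        params: TPBWTParams,
        pair_filter: Callable[[int, int], bool] | None = None,
        debug: SweepDebug | None = None,
    ) -> None:
        self.column = column
        self.M = n_haplotypes
        self.N = n_sites
        self.cm = cm
        self.templates = templates
        self.params = params
        self.debug = debug
        if self.M % 2 != 0:
            raise ValueError("engine expects an even number of haplotype rows")
        self.row_of = list(range(self.M))  # logical hap -> physical row
        self.tracker = MatchTracker(
            params,
            cm,
            on_switch=self._toggle_individual if params.correction_active else None,
            pair_filter=pair_filter,
        )
        # per-template state
        self.states = [_TemplateState(self.M) for _ in range(templates.t)]
        self.miss_run = [[0] * self.M for _ in range(templates.t)]
        self.valid_from = [[0] * self.M for _ in range(templates.t)]
        self.last_real = [[-1] * self.M for _ in range(templates.t)]
        # schedule: for each template and residue, offset to next processed site
        per = templates.period
        self._next_offset = []
        for mask in templates.masks:
            offs = []
            for r in range(per):
                delta = next(
                    (d for d in range(1, per + 1) if mask[(r + d) % per]), per
                )
                offs.append(delta)
            self._next_offset.append(offs)

    # -- phase switching -------------------------------------------------
    def _toggle_individual(self, individual: int, at_site: int) -> None:
        a, b = 2 * individual, 2 * individual + 1
        self.row_of[a], self.row_of[b] = self.row_of[b], self.row_of[a]

    # -- sweep -----------------------------------------------------------
    def run(self) -> list[tuple[int, int, int, int]]:
        masks = self.templates.masks
        per = self.templates.period
        for k in range(self.N):
            r = k % per
            col = self.column(k)
            for j in range(self.templates.t):
                if masks[j][r]:
                    self._process(j, k, col)
        self._trailing()
        return self.tracker.finalize()

    def _process(self, j: int, k: int, col: Sequence[int]) -> None:
        self.tracker.current_site = k
        st = self.states[j]
        ppa = st.ppa
        div = st.div
        M = self.M
        row_of = self.row_of
        miss_run = self.miss_run[j]
        valid_from = self.valid_from[j]
        last_real = self.last_real[j]
        params = self.params
        L_m = params.L_m
        M_t = params.M_t
        next_k = k + self._next_offset[j][k % self.templates.period]

        # 1. read raw alleles in ppa order; track missing runs (M_t barriers)
        raw = [col[row_of[h]] for h in ppa]
        barriers: list[int] = []
        for pos in range(M):
            h = ppa[pos]
            if raw[pos] >= 0:
                miss_run[h] = 0
                last_real[h] = k
            else:
                mr = miss_run[h] + 1
                miss_run[h] = mr
                if mr > M_t:
                    if mr == M_t + 1:
                        barriers.append(pos)
                    else:
                        valid_from[h] = k + 1
        resolved = resolve_missing_column(raw, div)

        # 2. emit fragments that terminate at k (allele mismatch within a
        #    block of haplotypes matching >= L_m sites through prev_k)
        if st.prev_k is not None:
            self._emit_blocks(j, k, resolved)
        for pos in barriers:
            # report the haplotype's matches up to its last observed site
            # *before* invalidating them
            self._emit_barrier(j, k, pos)
            valid_from[ppa[pos]] = k + 1

        # 3. stable counting sort into the next ppa/div columns
        st.ppa, st.div = advance_order(ppa, div, resolved, next_k)
        st.prev_k = k
        st.last_k = k
        if self.debug is not None:
            self.debug.observe(j, k, st.ppa)

    def _emit_blocks(self, j: int, k: int, resolved: list[int]) -> None:
        st = self.states[j]
        ppa, div = st.ppa, st.div
        end = st.prev_k
        L_m = self.params.L_m
        valid_from = self.valid_from[j]
        thresh = k - L_m
        M = self.M
        tracker = self.tracker
        bstart = 0
        for pos in range(1, M + 1):
            if pos == M or div[pos] > thresh:
                if pos - bstart >= 2:
                    m0 = [q for q in range(bstart, pos) if resolved[q] == 0]
                    m1 = [q for q in range(bstart, pos) if resolved[q] == 1]
                    if m0 and m1:
                        for qa in m0:
                            for qb in m1:
                                lo, hi = (qa, qb) if qa < qb else (qb, qa)
                                s = max(div[lo + 1 : hi + 1])
                                ha, hb = ppa[qa], ppa[qb]
                                if valid_from[ha] > s:
                                    s = valid_from[ha]
                                if valid_from[hb] > s:
                                    s = valid_from[hb]
                                if end - s + 1 >= L_m:
                                    tracker.add_fragment(ha, hb, s, end)
                bstart = pos

    def _emit_barrier(self, j: int, k: int, pos: int) -> None:
        """A missing run exceeded M_t: report the haplotype's matches up to
        its last observed site, then (via valid_from) terminate them."""
        st = self.states[j]
        ppa, div = st.ppa, st.div
        h = ppa[pos]
        end = self.last_real[j][h]
        if end < 0:
            return
        L_m = self.params.L_m
        valid_from = self.valid_from[j]
        limit = end - L_m + 1  # max usable start
        run = -_SENTINEL
        for q in range(pos - 1, -1, -1):
            if div[q + 1] > run:
                run = div[q + 1]
            if run > limit:
                break
            s = max(run, valid_from[h], valid_from[ppa[q]], 0)
            if end - s + 1 >= L_m:
                self.tracker.add_fragment(h, ppa[q], s, end)
        run = -_SENTINEL
        for q in range(pos + 1, self.M):
            if div[q] > run:
                run = div[q]
            if run > limit:
                break
            s = max(run, valid_from[h], valid_from[ppa[q]], 0)
            if end - s + 1 >= L_m:
                self.tracker.add_fragment(h, ppa[q], s, end)

    def _trailing(self) -> None:
        """Report matches extending through the final site of each template."""
        L_m = self.params.L_m
        for j, st in enumerate(self.states):
            if st.last_k is None:
                continue
            last_k = st.last_k
            ppa, div = st.ppa, st.div
            valid_from = self.valid_from[j]
            limit = last_k - L_m + 1
            M = self.M
            bstart = 0
            for pos in range(1, M + 1):
                if pos == M or div[pos] > limit:
                    for qa in range(bstart, pos):
                        run = -_SENTINEL
                        for qb in range(qa + 1, pos):
                            if div[qb] > run:
                                run = div[qb]
                            if run > limit:
                                break
                            s = max(run, valid_from[ppa[qa]], valid_from[ppa[qb]], 0)
                            if last_k - s + 1 >= L_m:
                                self.tracker.add_fragment(ppa[qa], ppa[qb], s, last_k)
                    bstart = pos


def _segments_from_raw(
    raw: Iterable[tuple[int, int, int, int]],
    bp: np.ndarray,
    cm: np.ndarray,
    hap_ids: Sequence[str],
    chromosome: str,
) -> list[IBDSegment]:
    segs = [
        IBDSegment(
            hap_a=a,
            hap_b=b,
            start_site=s,
            end_site=e,
            start_bp=int(bp[s]),
            end_bp=int(bp[e]),
            start_cm=float(cm[s]),
            end_cm=float(cm[e]),
            id1=hap_ids[a],
            id2=hap_ids[b],
            chromosome=chromosome,
        )
        for a, b, s, e in raw
    ]
    segs.sort(key=lambda s: (s.hap_a, s.hap_b, s.start_site))
    return segs


def compute_ibd_in_sample(
    alignment: HaplotypeAlignment,
    templates: TemplateSet | None = None,
    params: TPBWTParams | None = None,
    debug: SweepDebug | None = None,
) -> list[IBDSegment]:
    """All merged IBD segments of genetic length >= L_f between haplotypes of
    distinct individuals, from a single left-to-right pass.

    Output is deterministic: sorted by (hap_a, hap_b, start_site).
    """
    if templates is None:
        templates = default_templates()
    if params is None:
        params = TPBWTParams()
    cols = alignment.alleles.T.tolist()
    engine = SweepEngine(
        column=cols.__getitem__,
        n_haplotypes=alignment.n_haplotypes,
        n_sites=alignment.n_sites,
        cm=alignment.cm,
        templates=templates,
        params=params,
        debug=debug,
    )
    raw = engine.run()
    hap_ids = [alignment.sample_ids[h // 2] for h in range(alignment.n_haplotypes)]
    return _segments_from_raw(
        raw, alignment.bp, alignment.cm, hap_ids, alignment.chromosome
    )
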