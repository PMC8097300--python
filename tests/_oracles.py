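"""Independent reference implementations used to check the sweep machinery.

Everything here is deliberately naive (quadratic scans, explicit interval
algebra, exhaustive enumeration) and shares no code with the package's
single-pass engine.
"""

from __future__ import annotations

import itertools

import numpy as np


def maximal_exact_runs(row_a, row_b, min_sites: int) -> list[tuple[int, int]]:
    """All maximal runs of per-site equality of at least ``min_sites`` sites."""
    eq = np.asarray(row_a) == np.asarray(row_b)
    runs = []
    start = None
    for k, same in enumerate(eq):
        if same and start is None:
            start = k
        elif not same and start is not None:
            if k - start >= min_sites:
                runs.append((start, k - 1))
            start = None
    if start is not None and len(eq) - start >= min_sites:
        runs.append((start, len(eq) - 1))
    return runs


def merge_runs(runs: list[tuple[int, int]], max_gap_sites: int) -> list[tuple[int, int]]:
    """Merge site-interval runs separated by gaps strictly below the bound."""
    merged: list[list[int]] = []
    for s, e in sorted(runs):
        if merged and s - merged[-1][1] - 1 < max_gap_sites:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def brute_force_ibd(alignment, L_m: int, L_f: float) -> list[tuple[int, int, int, int]]:
    """Quadratic reference for the PBWT-collapse case: maximal exact IBS runs
    of >= L_m sites per haplotype pair (individual pairs only), merged across
    sub-L_m gaps, filtered at L_f cM.  Returns sorted (a, b, start, end)."""
    out = []
    m = alignment.n_haplotypes
    for a in range(m):
        for b in range(a + 1, m):
            if a // 2 == b // 2:
                continue
            runs = maximal_exact_runs(alignment.alleles[a], alignment.alleles[b], L_m)
            for s, e in merge_runs(runs, L_m):
                if alignment.cm[e] - alignment.cm[s] >= L_f:
                    out.append((a, b, s, e))
    return sorted(out)


def enumerate_binomial(n: int, j: int, p: float) -> float:
    """P(exactly j successes) by exhaustive enumeration of all 2^n outcomes."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=n):
        if sum(outcome) == j:
            prob = 1.0
            for o in outcome:
                prob *= p if o else (1.0 - p)
            total += prob
    return total


def interval_intersection_truth(track_a, track_b) -> list[tuple[float, float]]:
    """Equal-founder-label intervals of two ancestry tracks, by rasterising
    the breakpoint grid (independent of the package's two-pointer sweep)."""
    points = sorted({p for s, e, _ in track_a + track_b for p in (s, e)})
    out: list[tuple[float, float, int]] = []
    for lo, hi in zip(points, points[1:]):
        mid = (lo + hi) / 2
        la = next((lab for s, e, lab in track_a if s <= mid < e), None)
        lb = next((lab for s, e, lab in track_b if s <= mid < e), None)
        if la is not None and la == lb:
            if out and out[-1][1] == lo and out[-1][2] == la:
                out[-1] = (out[-1][0], hi, la)
            else:
                out.append((lo, hi, la))
    return [(s, e) for s, e, _ in out]
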