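"""Accuracy metrics for IBD callers: pairwise error statistics, binned
false-negative/false-positive rates, and trio validation.

Two pairwise summary statistics drive the headline comparisons: the error in
the number of IBD segments shared by a pair, (eta_hat - eta), and the error
in the amount of genome shared, (lambda_hat - lambda) / gamma, where gamma is
the genome length in cM.  Segment counts and totals are computed on the
haplotype-agnostic union of a pair's segment intervals (cM), for truth and
estimates alike: truth is defined on the diploid pair ("shares a founder
label on either haplotype"), and phase-corrected callers legitimately stitch
fragments across haplotype alternations, so haplotype-resolved counting
would misattribute correct stitching as error.

Binned rates use the segment-length bins 3-4, 4-5, 5-6, 7-8, 9-10, 10-11,
12-15, 15-18 and >18 cM (half-open; note the deliberate 6-7, 8-9 and 11-12
gaps — segments falling in a gap are excluded).  A contiguous alternative is
available.  Overlap between truth and estimate is judged on the pair's cM
intervals regardless of haplotype, and any positive overlap counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LengthBins",
    "PairSummary",
    "default_bins",
    "contiguous_bins",
    "genome_fraction_error",
    "segment_count_error",
    "union_intervals",
    "pair_summary",
    "fn_fp_rates",
    "trio_validation",
    "pedigree_accuracy_study",
]


@dataclass(frozen=True)
class LengthBins:
    """Half-open segment-length bins [lo, hi) in cM; the last may be open."""

    edges: tuple[tuple[float, float], ...]

    def labels(self) -> list[str]:
        return [
            f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}" for lo, hi in self.edges
        ]

    def bin_of(self, length_cm: float) -> int | None:
        for i, (lo, hi) in enumerate(self.edges):
            if lo <= length_cm < hi:
                return i
        return None


def default_bins() -> LengthBins:
    return LengthBins(
        edges=(
            (3.0, 4.0),
            (4.0, 5.0),
            (5.0, 6.0),
            (7.0, 8.0),
            (9.0, 10.0),
            (10.0, 11.0),
            (12.0, 15.0),
            (15.0, 18.0),
            (18.0, np.inf),
        )
    )


def contiguous_bins() -> LengthBins:
    return LengthBins(
        edges=(
            (3.0, 4.0),
            (4.0, 5.0),
            (5.0, 6.0),
            (6.0, 7.0),
            (7.0, 8.0),
            (8.0, 9.0),
            (9.0, 10.0),
            (10.0, 11.0),
            (11.0, 12.0),
            (12.0, 15.0),
            (15.0, 18.0),
            (18.0, np.inf),
        )
    )


@dataclass(frozen=True)
class PairSummary:
    """Per-pair truth/estimate totals: segment counts and shared cM."""

    lam: float  # true total IBD length (cM)
    lam_hat: float  # estimated total IBD length (cM)
    gamma: float  # genome length (cM)
    eta: int  # true segment count
    eta_hat: int  # estimated segment count

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("genome length gamma must be positive")
        if self.eta < 0 or self.eta_hat < 0:
            raise ValueError("segment counts must be non-negative")


def genome_fraction_error(summary: PairSummary) -> float:
    """(lambda_hat - lambda) / gamma: signed error in the genome fraction IBD."""
    return (summary.lam_hat - summary.lam) / summary.gamma


def segment_count_error(summary: PairSummary) -> int:
    """eta_hat - eta: signed error in the number of IBD segments."""
    return summary.eta_hat - summary.eta


def union_intervals(
    intervals, merge_gap_cm: float = 0.0
) -> list[tuple[float, float]]:
    """Merge possibly overlapping (start_cm, end_cm) intervals, bridging gaps
    up to ``merge_gap_cm`` (site-anchored adjacent intervals have sub-site
    gaps that must not count as distinct segments)."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    out: list[list[float]] = []
    for a, b in ivs:
        if out and a - out[-1][1] <= merge_gap_cm:
            if b > out[-1][1]:
                out[-1][1] = b
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def pair_summary(
    truth_intervals,
    estimated_intervals,
    gamma: float,
    min_length_cm: float = 0.0,
    merge_gap_cm: float = 0.1,
) -> PairSummary:
    """Summarise one pair from raw (start_cm, end_cm) interval collections.

    Both sides are merged haplotype-agnostically; union intervals shorter
    than ``min_length_cm`` are discarded (apply the caller's reporting floor
    to the truth so that detectable truth is compared)."""
    tu = [
        iv
        for iv in union_intervals(truth_intervals, merge_gap_cm)
        if iv[1] - iv[0] >= min_length_cm
    ]
    eu = [
        iv
        for iv in union_intervals(estimated_intervals, merge_gap_cm)
        if iv[1] - iv[0] >= min_length_cm
    ]
    return PairSummary(
        lam=sum(b - a for a, b in tu),
        lam_hat=sum(b - a for a, b in eu),
        gamma=gamma,
        eta=len(tu),
        eta_hat=len(eu),
    )


def _norm_segments(segments) -> pd.DataFrame:
    """Normalise segments to a frame of (pair, start_cm, end_cm)."""
    rows = []
    for s in segments:
        if isinstance(s, tuple):
            pair, a, b = s[0], float(s[1]), float(s[2])
            if not isinstance(pair, tuple):
                raise TypeError("tuple segments must be ((id1, id2), start, end)")
            pair = tuple(sorted(pair))
        else:
            pair = tuple(sorted((s.id1, s.id2)))
            a, b = float(s.start_cm), float(s.end_cm)
        rows.append((pair, a, b))
    return pd.DataFrame(rows, columns=["pair", "start_cm", "end_cm"])


def _covered_length(iv: tuple[float, float], others: list[tuple[float, float]]) -> float:
    lo, hi = iv
    merged = union_intervals(others)
    return sum(max(0.0, min(hi, b) - max(lo, a)) for a, b in merged)


def fn_fp_rates(
    truth,
    estimated,
    bins: LengthBins | None = None,
    fp_denominator: str = "true",
) -> pd.DataFrame:
    """Binned false-negative and false-positive rates, by segment and by
    segment coverage.

    For each length bin: FN-by-segment is the fraction of true segments in
    the bin overlapping no estimated segment of the same pair; FN-by-coverage
    is the fraction of true segment length in the bin not covered by any
    estimate.  FP rates mirror these with the roles of truth and estimate
    reversed; their denominators use the *true* counts/lengths in the bin
    (``fp_denominator="true"``, as conventionally printed) or the estimated
    ones (``fp_denominator="estimated"``).  Bins with an undefined
    denominator report NaN, not 0.
    """
    if bins is None:
        bins = default_bins()
    if fp_denominator not in ("true", "estimated"):
        raise ValueError("fp_denominator must be 'true' or 'estimated'")
    tdf = _norm_segments(truth)
    edf = _norm_segments(estimated)
    t_by_pair = {p: g[["start_cm", "end_cm"]].to_numpy() for p, g in tdf.groupby("pair")}
    e_by_pair = {p: g[["start_cm", "end_cm"]].to_numpy() for p, g in edf.groupby("pair")}
    nb = len(bins.edges)
    t_count = np.zeros(nb)
    t_miss = np.zeros(nb)
    t_len = np.zeros(nb)
    t_uncov = np.zeros(nb)
    e_count = np.zeros(nb)
    e_miss = np.zeros(nb)
    e_len = np.zeros(nb)
    e_uncov = np.zeros(nb)

    def _accumulate(df, other_by_pair, count, miss, length, uncov):
        for row in df.itertuples(index=False):
            b = bins.bin_of(row.end_cm - row.start_cm)
            if b is None:
                continue
            others = [tuple(x) for x in other_by_pair.get(row.pair, [])]
            cov = _covered_length((row.start_cm, row.end_cm), others)
            count[b] += 1
            length[b] += row.end_cm - row.start_cm
            uncov[b] += (row.end_cm - row.start_cm) - cov
            if cov <= 0.0:
                miss[b] += 1

    _accumulate(tdf, e_by_pair, t_count, t_miss, t_len, t_uncov)
    _accumulate(edf, t_by_pair, e_count, e_miss, e_len, e_uncov)

    with np.errstate(invalid="ignore", divide="ignore"):
        fn_seg = np.where(t_count > 0, t_miss / t_count, np.nan)
        fn_cov = np.where(t_len > 0, t_uncov / t_len, np.nan)
        if fp_denominator == "true":
            fp_seg = np.where(t_count > 0, e_miss / t_count, np.nan)
            fp_cov = np.where(t_len > 0, e_uncov / t_len, np.nan)
        else:
            fp_seg = np.where(e_count > 0, e_miss / e_count, np.nan)
            fp_cov = np.where(e_len > 0, e_uncov / e_len, np.nan)
    return pd.DataFrame(
        {
            "bin": bins.labels(),
            "n_true": t_count.astype(int),
            "n_estimated": e_count.astype(int),
            "fn_by_segment": fn_seg,
            "fn_by_coverage": fn_cov,
            "fp_by_segment": fp_seg,
            "fp_by_coverage": fp_cov,
        }
    ).set_index("bin")


def trio_validation(
    child_vs_relative,
    parents_vs_relative,
    child_to_parents: dict[str, tuple[str, str]],
    bins: LengthBins | None = None,
) -> pd.DataFrame:
    """Trio validation of child-relative IBD segments.

    A segment between a child and a distant relative is "trio validated" when
    at least one overlapping segment exists between the same relative and one
    of the child's parents.  Returns, per length bin, the validated fraction
    ``hmean`` together with total and validated counts.  Segments whose child
    has no parents in ``child_to_parents`` are skipped with a warning.
    """
    if bins is None:
        bins = default_bins()
    cdf = _norm_segments(child_vs_relative)
    pdf = _norm_segments(parents_vs_relative)
    p_by_pair = {p: g[["start_cm", "end_cm"]].to_numpy() for p, g in pdf.groupby("pair")}
    nb = len(bins.edges)
    total = np.zeros(nb, dtype=int)
    validated = np.zeros(nb, dtype=int)
    skipped = 0
    for row in cdf.itertuples(index=False):
        id_a, id_b = row.pair
        if id_a in child_to_parents:
            child, relative = id_a, id_b
        elif id_b in child_to_parents:
            child, relative = id_b, id_a
        else:
            skipped += 1
            continue
        b = bins.bin_of(row.end_cm - row.start_cm)
        if b is None:
            continue
        total[b] += 1
        ok = False
        for parent in child_to_parents[child]:
            key = tuple(sorted((parent, relative)))
            for a, e in p_by_pair.get(key, []):
                if min(e, row.end_cm) - max(a, row.start_cm) > 0:
                    ok = True
                    break
            if ok:
                break
        if ok:
            validated[b] += 1
    if skipped:
        warnings.warn(
            f"{skipped} child-relative segments skipped: child not in trio map",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        hmean = np.where(total > 0, validated / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "bin": bins.labels(),
            "hmean": hmean,
            "n_total": total,
            "n_validated": validated,
        }
    ).set_index("bin")


def pedigree_accuracy_study(
    n_replicates: int = 20,
    seed: int = 0,
    n_sites: int = 6000,
    length_cm: float = 50.0,
    genotype_error: float = 0.001,
    switch_rate: float = 0.0025,
    phase_correction: bool = True,
    error_free: bool = False,
    params=None,
    templates=None,
) -> pd.DataFrame:
    """Simulate pedigrees, call IBD, and summarise per-pair accuracy.

    Each replicate drops founder haplotypes through the default
    three-generation pedigree over one uniform chromosome (50 cM, 6000 sites
    by default), perturbs the observed haplotypes with genotyping miscalls
    and phase switch errors (unless ``error_free``), runs the in-sample
    sweep, and records, for every labelled relative pair, the true and
    estimated segment count (eta, eta_hat) and total shared length
    (lambda, lambda_hat) on the pair-level interval union, with the caller's
    reporting floor applied to both sides.
    """
    from .pedigree_sim import (
        add_genotype_errors,
        add_switch_errors,
        default_pedigree_spec,
        simulate_founder_alignment,
        simulate_pedigree,
    )
    from .tpbwt_core import TPBWTParams, compute_ibd_in_sample

    if params is None:
        params = TPBWTParams()
    params = TPBWTParams(
        L_m=params.L_m,
        L_f=params.L_f,
        M_t=params.M_t,
        phase_correction=phase_correction,
        haploid=params.haploid,
        include_self_pairs=params.include_self_pairs,
    )
    spec = default_pedigree_spec()
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        founders = simulate_founder_alignment(
            len(spec.founders), n_sites, length_cm, rng
        )
        sim = simulate_pedigree(spec, founders, rng)
        observed = sim.alignment
        if not error_free:
            observed = add_genotype_errors(observed, genotype_error, rng)
            observed, _ = add_switch_errors(observed, switch_rate, rng)
        segments = compute_ibd_in_sample(observed, templates, params)
        est_by_pair: dict[frozenset, list] = {}
        for s in segments:
            est_by_pair.setdefault(frozenset((s.id1, s.id2)), []).append(
                s.interval_cm
            )
        gamma = float(sim.alignment.cm[-1])
        for ptype, pairs in spec.labeled_pairs.items():
            for id1, id2 in pairs:
                truth_iv = [s.interval_cm for s in sim.truth_for_pair(id1, id2)]
                est_iv = est_by_pair.get(frozenset((id1, id2)), [])
                summ = pair_summary(
                    truth_iv, est_iv, gamma=gamma, min_length_cm=params.L_f
                )
                rows.append(
                    {
                        "replicate": rep,
                        "pair_type": ptype,
                        "id1": id1,
                        "id2": id2,
                        "eta": summ.eta,
                        "eta_hat": summ.eta_hat,
                        "lam": summ.lam,
                        "lam_hat": summ.lam_hat,
                        "gamma": gamma,
                        "count_error": segment_count_error(summ),
                        "fraction_error": genome_fraction_error(summ),
                    }
                )
    return pd.DataFrame(rows)
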