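import numpy as np
import pytest

from tpbwt import (
    TPBWTParams,
    binomial_error_probability,
    compute_ibd_in_sample,
    default_templates,
    pbwt_template,
    template_count,
)
from tpbwt.tpbwt_core import MatchTracker, SweepDebug, TemplateSet

from _oracles import brute_force_ibd, enumerate_binomial
from conftest import make_alignment, random_alignment


class TestTemplates:
    def test_default_set_is_six_period_four(self):
        ts = default_templates()
        assert ts.t == 6
        assert ts.period == 4

    def test_every_residue_covered_by_exactly_three_masks(self):
        ts = default_templates()
        for r in range(4):
            assert sum(m[r] for m in ts.masks) == 3

    def test_masks_are_all_two_of_four_choices(self):
        ts = default_templates()
        assert sorted(ts.masks) == sorted(
            {m for m in ts.masks}
        )  # distinct
        assert all(sum(m) == 2 for m in ts.masks)
        assert len(set(ts.masks)) == template_count(4, 2)

    def test_uncovered_residue_rejected(self):
        with pytest.raises(ValueError, match="masked by every template"):
            TemplateSet(masks=((1, 0), (1, 0)))

    @pytest.mark.parametrize(
        "n,k,expect", [(2, 1, 2), (4, 2, 6), (7, 0, 1), (10, 3, 120)]
    )
    def test_template_count(self, n, k, expect):
        assert template_count(n, k) == expect

    def test_template_count_rejects_k_above_n(self):
        with pytest.raises(ValueError):
            template_count(3, 4)


class TestBinomialErrorProbability:
    def test_three_errors_in_four_site_window(self):
        # the motivating calculation for stopping at 2-of-4 robustness
        assert binomial_error_probability(4, 3, 0.001) == pytest.approx(
            3.996e-9, rel=1e-4
        )

    def test_zero_errors_zero_rate(self):
        assert binomial_error_probability(12, 0, 0.0) == 1.0

    def test_matches_exhaustive_enumeration(self):
        want = enumerate_binomial(10, 4, 0.3)
        assert binomial_error_probability(10, 4, 0.3) == pytest.approx(want, rel=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            binomial_error_probability(4, 2, 1.5)


def _pbwt_params(L_m=20, L_f=0.0, M_t=0):
    return TPBWTParams(L_m=L_m, L_f=L_f, M_t=M_t, phase_correction=False)


class TestExactMatching:
    def test_identical_pair_single_full_length_match(self):
        al = make_alignment(np.tile([0, 1, 1, 0, 1, 0, 0, 1, 0, 1], (4, 1)))
        segs = compute_ibd_in_sample(al, pbwt_template(), _pbwt_params(L_m=5))
        by_pair = {(s.hap_a, s.hap_b): (s.start_site, s.end_site) for s in segs}
        # all cross-individual pairings cover every site
        assert all(v == (0, 9) for v in by_pair.values())
        assert set(by_pair) == {(0, 2), (0, 3), (1, 2), (1, 3)}

    def test_complementary_haplotypes_share_nothing(self):
        n = 100
        a = np.tile([0, 1], n // 2)
        al = make_alignment(np.stack([a, a, 1 - a, 1 - a]))
        segs = compute_ibd_in_sample(al, pbwt_template(), _pbwt_params(L_m=5))
        assert segs == []

    def test_error_masked_by_templates_does_not_split(self):
        # hand-constructed 4x12 alignment: haplotypes 0 and 2 identical except
        # one miscall at site 5; templates masking residue 1 carry the match
        base = np.array([0, 1, 0, 0, 1, 1, 0, 1, 1, 0, 0, 1], dtype=np.int8)
        alleles = np.stack([base, 1 - base, base.copy(), 1 - base])
        alleles[2, 5] ^= 1
        al = make_alignment(alleles)
        segs = compute_ibd_in_sample(
            al, default_templates(), TPBWTParams(L_m=4, L_f=0.0, phase_correction=False)
        )
        spans = [(s.start_site, s.end_site) for s in segs if (s.hap_a, s.hap_b) == (0, 2)]
        assert len(spans) == 1
        s, e = spans[0]
        assert s <= 1 and e >= 10

    @pytest.mark.parametrize("m_t,expect_segments", [(1, 1), (0, 2)])
    def test_missing_site_extension_vs_termination(self, m_t, expect_segments):
        # L_m = 1 so the sub-L_m gap merge cannot bridge the terminated match
        rng = np.random.default_rng(3)
        alleles = rng.integers(0, 2, size=(4, 120)).astype(np.int8)
        alleles[2] = alleles[0]
        alleles[2, 60] = -1
        al = make_alignment(alleles)
        params = TPBWTParams(L_m=1, L_f=0.0, M_t=m_t, phase_correction=False)
        segs = [
            s
            for s in compute_ibd_in_sample(al, pbwt_template(), params)
            if (s.hap_a, s.hap_b) == (0, 2)
        ]
        assert len(segs) == expect_segments
        if expect_segments == 2:
            assert segs[0].end_site == 59 and segs[1].start_site == 61
        else:
            assert (segs[0].start_site, segs[0].end_site) == (0, 119)

    def test_long_missing_run_respects_budget(self, rng):
        # a 15-site missing run, longer than L_m, so termination is visible
        # through the merge step
        alleles = rng.integers(0, 2, size=(4, 200)).astype(np.int8)
        alleles[2] = alleles[0]
        alleles[2, 90:105] = -1
        al = make_alignment(alleles)
        for m_t, expect in [(20, 1), (5, 2)]:
            params = TPBWTParams(L_m=10, L_f=0.0, M_t=m_t, phase_correction=False)
            segs = [
                s
                for s in compute_ibd_in_sample(al, pbwt_template(), params)
                if (s.hap_a, s.hap_b) == (0, 2)
            ]
            assert len(segs) == expect, f"M_t={m_t}"


class TestPBWTCollapseOracle:
    """t=1, all-ones template, no missing data, correction off: the sweep
    must reproduce an independent quadratic maximal-match scan exactly."""

    @pytest.mark.parametrize("seed", range(25))
    def test_random_alignments_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        al = random_alignment(rng, 20, 200)
        # plant a few shared stretches so matches exist at L_m scale
        for _ in range(3):
            a, b = rng.choice(20, size=2, replace=False)
            s = int(rng.integers(0, 150))
            length = min(int(rng.integers(30, 60)), 200 - s)
            al.alleles[b, s : s + length] = al.alleles[a, s : s + length]
        params = _pbwt_params(L_m=15, L_f=0.0)
        segs = compute_ibd_in_sample(al, pbwt_template(), params)
        got = sorted((s.hap_a, s.hap_b, s.start_site, s.end_site) for s in segs)
        assert got == brute_force_ibd(al, 15, 0.0)

    def test_genetic_length_filter_applied(self, rng):
        al = random_alignment(rng, 10, 300, length_cm=6.0)  # 0.02 cM/site
        al.alleles[4, 100:160] = al.alleles[0, 100:160]  # ~1.2 cM
        al.alleles[5, 50:280] = al.alleles[1, 50:280]  # ~4.6 cM
        params = _pbwt_params(L_m=25, L_f=2.0)
        segs = compute_ibd_in_sample(al, pbwt_template(), params)
        got = sorted((s.hap_a, s.hap_b, s.start_site, s.end_site) for s in segs)
        assert got == brute_force_ibd(al, 25, 2.0)
        assert all(s.length_cm >= 2.0 for s in segs)


class TestErrorRobustnessGuarantee:
    def test_two_errors_in_window_never_split(self, rng):
        for trial in range(40):
            trial_rng = np.random.default_rng(trial)
            alleles = trial_rng.integers(0, 2, size=(6, 700)).astype(np.int8)
            alleles[4] = alleles[0]
            w = int(trial_rng.integers(250, 420))
            offsets = trial_rng.choice(4, size=int(trial_rng.integers(1, 3)), replace=False)
            for o in offsets:
                alleles[4, w + o] ^= 1
            al = make_alignment(alleles, length_cm=40.0)
            segs = [
                s
                for s in compute_ibd_in_sample(
                    al, params=TPBWTParams(L_m=200, L_f=3.0, phase_correction=False)
                )
                if (s.hap_a, s.hap_b) == (0, 4)
            ]
            assert len(segs) == 1, f"trial {trial}: segment split or lost"
            assert segs[0].start_site <= 4 and segs[0].end_site >= 695

    def test_three_errors_at_distinct_residues_break_all_templates(self):
        # Three errors spanning three residues of one window leave no clean
        # 2-of-4 mask, so every template's match breaks there.  The fragments
        # can still be re-joined by the sub-L_m gap merge (by design), so the
        # split is observed with a merge window smaller than the error gap.
        rng = np.random.default_rng(99)
        alleles = rng.integers(0, 2, size=(4, 900)).astype(np.int8)
        alleles[2] = alleles[0]
        for o in (0, 1, 2):
            alleles[2, 440 + o] ^= 1
        al = make_alignment(alleles, length_cm=40.0)
        segs = [
            s
            for s in compute_ibd_in_sample(
                al, params=TPBWTParams(L_m=3, L_f=3.0, phase_correction=False)
            )
            if (s.hap_a, s.hap_b) == (0, 2)
        ]
        assert len(segs) == 2
        # ...whereas the default L_m = 200 bridges the three-site gap
        segs = [
            s
            for s in compute_ibd_in_sample(
                al, params=TPBWTParams(L_m=200, L_f=3.0, phase_correction=False)
            )
            if (s.hap_a, s.hap_b) == (0, 2)
        ]
        assert len(segs) == 1


class TestMatchTracker:
    def _tracker(self, L_m=10, L_f=0.0, n=1000):
        cm = np.linspace(0, 50, n)
        return MatchTracker(
            TPBWTParams(L_m=L_m, L_f=L_f, phase_correction=False), cm
        )

    def test_overlapping_fragment_extends_open_match(self):
        tr = self._tracker()
        tr.add_fragment(0, 2, 0, 100)
        tr.add_fragment(0, 2, 90, 200)
        assert tr.open[(0, 2)] == [0, 200]
        assert tr.reported == []

    def test_distant_fragment_displaces_and_reports_long_match(self):
        tr = self._tracker(L_m=10, L_f=1.0)
        tr.add_fragment(0, 2, 0, 100)  # 5 cM at 0.05 cM/site
        tr.add_fragment(0, 2, 300, 400)
        assert tr.reported == [(0, 2, 0, 100)]
        assert tr.open[(0, 2)] == [300, 400]

    def test_short_open_match_silently_dropped(self):
        tr = self._tracker(L_m=5, L_f=3.0)
        tr.add_fragment(0, 2, 0, 20)  # ~1 cM < L_f
        tr.add_fragment(0, 2, 500, 600)
        assert tr.reported == []

    def test_gap_below_L_m_merges(self):
        tr = self._tracker(L_m=50)
        tr.add_fragment(0, 2, 0, 100)
        tr.add_fragment(0, 2, 149, 300)  # gap of 48 < 50 sites
        assert tr.open[(0, 2)] == [0, 300]
        tr.add_fragment(0, 2, 351, 500)  # gap of exactly 50: no merge
        assert tr.open[(0, 2)] == [351, 500]

    def test_trailing_mixture_respects_length_floor(self):
        # five open matches, two below the cM floor: exactly three reported
        tr = self._tracker(L_m=5, L_f=2.0)  # 2 cM = 40 sites at 0.05 cM/site
        spans = [(0, 2, 0, 100), (0, 4, 0, 30), (1, 3, 50, 300), (2, 4, 0, 39), (3, 5, 10, 60)]
        for frag in spans:
            tr.add_fragment(*frag)
        reported = tr.finalize()
        assert len(reported) == 3
        assert (0, 4, 0, 30) not in reported and (2, 4, 0, 39) not in reported


class TestSweepProperties:
    def test_ppa_columns_stay_permutations(self, rng):
        al = random_alignment(rng, 12, 150, missing_rate=0.02)
        debug = SweepDebug(check_permutations=True)
        compute_ibd_in_sample(al, default_templates(), TPBWTParams(L_m=10, L_f=0.0), debug)
        assert debug.inner_ops > 0

    def test_output_invariant_under_individual_permutation(self, rng):
        al = random_alignment(rng, 12, 300)
        al.alleles[4, 20:220] = al.alleles[0, 20:220]
        al.alleles[9, 100:280] = al.alleles[2, 100:280]
        params = TPBWTParams(L_m=30, L_f=0.0, phase_correction=False)
        base = compute_ibd_in_sample(al, default_templates(), params)

        perm = np.array([3, 0, 5, 1, 4, 2])  # individual permutation
        hap_perm = np.empty(12, dtype=int)
        for new_i, old_i in enumerate(perm):
            hap_perm[2 * new_i] = 2 * old_i
            hap_perm[2 * new_i + 1] = 2 * old_i + 1
        al2 = make_alignment(al.alleles[hap_perm])
        permuted = compute_ibd_in_sample(al2, default_templates(), params)

        def keyset(segs, relabel=None):
            out = set()
            for s in segs:
                a, b = s.hap_a, s.hap_b
                if relabel is not None:
                    a, b = relabel[a], relabel[b]
                    a, b = min(a, b), max(a, b)
                out.add((a, b, s.start_site, s.end_site))
            return out

        assert keyset(permuted, relabel={i: hap_perm[i] for i in range(12)}) == keyset(base)

    def test_work_scales_linearly_in_haplotypes(self, rng):
        params = TPBWTParams(L_m=20, L_f=0.0, phase_correction=False)
        ops = {}
        for m in (10, 20, 40):
            al = random_alignment(np.random.default_rng(1), m, 200)
            debug = SweepDebug()
            compute_ibd_in_sample(al, default_templates(), params, debug)
            ops[m] = debug.inner_ops
        # doubling M doubles the inner work (N * M * t/2 structure)
        assert ops[20] / ops[10] == pytest.approx(2.0, rel=0.01)
        assert ops[40] / ops[20] == pytest.approx(2.0, rel=0.01)

    def test_self_pairs_excluded_by_default_and_optional(self):
        row = np.tile([0, 1, 1, 0, 1], 40)
        al = make_alignment(np.stack([row, row, 1 - row, row]))
        params = TPBWTParams(L_m=20, L_f=0.0, phase_correction=False)
        segs = compute_ibd_in_sample(al, pbwt_template(), params)
        assert {(s.hap_a, s.hap_b) for s in segs} == {(0, 3), (1, 3)}
        params_roh = TPBWTParams(
            L_m=20, L_f=0.0, phase_correction=False, include_self_pairs=True
        )
        segs = compute_ibd_in_sample(al, pbwt_template(), params_roh)
        assert (0, 1) in {(s.hap_a, s.hap_b) for s in segs}
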