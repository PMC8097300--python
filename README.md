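# tpbwt — error-robust, phase-aware IBD inference

`tpbwt` detects identity-by-descent (IBD) segments — stretches of chromosome
that two individuals both inherited from a common ancestor — from phased,
biallelic genotype data.  It is built for the people who need IBD calls that
survive real data: researchers doing relationship and pedigree inference,
demographic analysis, or haplotype-sharing studies on array-scale cohorts,
where genotyping miscalls and statistical phase switch errors shred true
long IBD segments into short fragments spread across complementary
haplotypes.

## The algorithm

The positional Burrows–Wheeler transform (PBWT) keeps, at each site *k*, the
*M* haplotypes sorted by reversed prefix (the positional prefix array
**ppa**) together with the site where each adjacent pair began matching (the
divergence array **div**), which yields all maximal identical-by-state runs
in a single *O(NM)* pass over *N* sites.  The PBWT requires exact matches,
so a single miscall ends a match.

The *templated* PBWT (TPBWT) adds a third dimension: *t* repeating binary
masks over sites ("templates"), each with its own ppa/div columns that skip
the masked sites.  The default set is the six 2-of-4 masks
`∅h∅h, h∅h∅, ∅∅hh, hh∅∅, ∅hh∅, h∅∅h` — for any placement of up to two errors
in a four-site window, at least one template masks both, so the match
survives in that template.  At a per-site error rate of 0.001, the residual
unmaskable event (three errors in one window) has probability
C(4,3)·0.001³·0.999 = 3.996×10⁻⁹.  Candidate fragments of at least `L_m`
sites emitted by all templates are merged in shared current-match arrays
(Ps/Pe); gaps shorter than `L_m` sites are bridged; merged segments of at
least `L_f` cM are reported.

On top of the templates sits a phase-correction heuristic: when a new
fragment between individuals P and Q begins near the end of an open fragment
between the same pair but on a complementary haplotype in P, Q, or both, a
phase switch error is inferred there and the affected individual's
haplotypes are swapped for all future sites in *all* templates.  The
correction is global per individual, so segments stay consistent
("triangulate") across the whole cohort.  Missing genotypes are imputed on
the fly from the haplotype that carries the longest current match, for up to
`M_t` consecutive missing sites.

The package also provides a run-length compressed panel format (`.tpbwt`),
out-of-sample comparison of new samples against a compressed cohort with
match storage proportional to *M_X × M_Y*, a pedigree gene-dropping
simulator with exact IBD truth tracking and realistic error injectors, and
the standard caller-evaluation metrics (segment-count and genome-fraction
errors, binned FN/FP rates, trio validation).

## Worked example

Simulate one three-generation pedigree over a 50 cM chromosome with 6000
SNPs, perturb the observed haplotypes with genotyping miscalls (rate 0.001)
and phase switch errors (0.25% of heterozygous sites), then call IBD with
and without phase correction and compare against the simulated truth:

```python
import numpy as np
from tpbwt import TPBWTParams, compute_ibd_in_sample
from tpbwt.evaluation import pair_summary
from tpbwt.pedigree_sim import (
    add_genotype_errors, add_switch_errors,
    default_pedigree_spec, simulate_founder_alignment, simulate_pedigree,
)

rng = np.random.default_rng(11)
spec = default_pedigree_spec()
founders = simulate_founder_alignment(len(spec.founders), 6000, 50.0, rng)
sim = simulate_pedigree(spec, founders, rng)
observed = add_genotype_errors(sim.alignment, 0.001, rng)
observed, _ = add_switch_errors(observed, 0.0025, rng)

for corrected in (True, False):
    segments = compute_ibd_in_sample(
        observed, params=TPBWTParams(phase_correction=corrected)
    )
    print(f"phase correction {'on' if corrected else 'off'}:")
    for ptype, pairs in spec.labeled_pairs.items():
        id1, id2 = pairs[0]
        truth = [s.interval_cm for s in sim.truth_for_pair(id1, id2)]
        est = [s.interval_cm for s in segments if {s.id1, s.id2} == {id1, id2}]
        m = pair_summary(truth, est, gamma=50.0, min_length_cm=3.0)
        print(f"  {ptype:24s} true {m.lam:5.1f} cM / {m.eta} seg   "
              f"estimated {m.lam_hat:5.1f} cM / {m.eta_hat} seg")
```

prints

```
phase correction on:
  parent_child             true  50.0 cM / 1 seg   estimated  47.6 cM / 2 seg
  grandparent_grandchild   true  50.0 cM / 1 seg   estimated  45.8 cM / 3 seg
  aunt_niece               true  37.3 cM / 1 seg   estimated  35.5 cM / 2 seg
  first_cousins            true  30.5 cM / 1 seg   estimated  29.3 cM / 1 seg
  siblings                 true  19.6 cM / 2 seg   estimated  17.2 cM / 3 seg
phase correction off:
  parent_child             true  50.0 cM / 1 seg   estimated  44.9 cM / 3 seg
  grandparent_grandchild   true  50.0 cM / 1 seg   estimated  43.2 cM / 4 seg
  aunt_niece               true  37.3 cM / 1 seg   estimated  34.2 cM / 3 seg
  first_cousins            true  30.5 cM / 1 seg   estimated  26.6 cM / 1 seg
  siblings                 true  19.6 cM / 2 seg   estimated  16.5 cM / 3 seg
```

Each line compares the true IBD a relative pair shares (total cM and number
of segments, on the haplotype-agnostic union of intervals, counting only
segments detectable at the 3 cM reporting floor) with what the caller
estimated from the error-laden haplotypes.  With correction on, the caller
recovers more of the shared genome in fewer, longer segments — e.g. the
grandparent–grandchild pair improves from 43.2 cM in 4 fragments to 45.8 cM
in 3 — because fragments split by phase switch errors are stitched back
together during the sweep.

## Command line

```sh
tpbwt compute  --vcf cohort.vcf --map chr1.map --out segments.tsv
tpbwt compress --vcf cohort.vcf --map chr1.map --out cohort.tpbwt
tpbwt compare  new.tpbwt cohort.tpbwt --out cross.tsv
tpbwt batch    --vcf b1.vcf --vcf b2.vcf --map chr1.map --out merged.tsv
tpbwt simulate --out-dir sim/ --replicates 5
tpbwt evaluate --truth sim/rep0.truth.tsv --estimated segments.tsv --out rates.tsv
tpbwt subset-sites a.tpbwt b.tpbwt --out-x a_shared.tpbwt --out-y b_shared.tpbwt
```

Defaults follow the standard settings `--Lm 200 --Lf 3.0 --Mt 10` with the
six default templates and phase correction enabled (`--no-phase-correction`
and `--haploid` disable it).  The genetic map is 3-column whitespace text
(chromosome, bp, cM); segment output is a TSV with site, bp and cM
coordinates per haplotype pair.

## Documentation

* `docs/methods.md` — models, parameters, design decisions, limitations.
* `docs/panel_format.md` — the `.tpbwt` binary layout, field by field.
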