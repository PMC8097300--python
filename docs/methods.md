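# Methods

## Matching model

The sweep maintains, per template *j*, the classic PBWT state: a positional
prefix array `ppa[j]` (haplotypes sorted by reversed prefix over the sites
that template processes) and a divergence array `div[j]` (global site index
where the match between adjacent sorted haplotypes began).  Templates are
repeating binary masks applied cyclically, `T(j,k) = masks[j][k mod period]`;
a masked site is simply skipped by that template, so an error there cannot
break that template's matches.  Every residue class must be covered by at
least one template (validated at construction).  With the six default
2-of-4 masks, each site is processed by exactly three templates and each
template sees half the sites, so the work is about `N·M·t/2` inner steps —
the op-count test verifies the linear growth in *M* directly, independent of
wall-clock noise.

At a processed site *k*, haplotypes are partitioned by allele with a stable
counting sort (stability is what preserves reversed-prefix order within an
allele class).  Match fragments are emitted when they terminate: within each
maximal block of sorted haplotypes whose pairwise matches span at least
`L_m` sites through the previous processed site, every opposite-allele pair
ends its match at *k*.  Per-pair match starts are the running maximum of the
divergence values between the two sort positions.  A final pass reports
trailing matches that reach the end of the chromosome.  Fragment endpoints
are the first and last *verified* (processed, non-missing) sites of the
match for that template; union merging across templates fills the masked
positions in between.

Boundary conventions the pseudocode tradition leaves open, fixed here: `div`
is initialised to 0 with `ppa` the identity; the first element of each new
allele class receives the next processed site as its divergence value (the
"no predecessor match" sentinel); fragments are gated on spanning at least
`L_m` sites, so nothing is reportable before site `L_m − 1`.

## Fragment merging and reporting

Current matches live in sparse arrays keyed by haplotype pair (`Ps`/`Pe` in
matrix form; a dictionary here, which is also what bounds out-of-sample
memory by the cross-product).  A new fragment extends an open match for the
same pair if it overlaps or if the gap is strictly smaller than `L_m` sites
— gaps arise when the stretch between two phase switch errors is too short
to be emitted as a fragment, and such stretches are by construction shorter
than `L_m`.  A non-adjacent fragment displaces the open match, which is
reported only if its genetic length reaches `L_f`; sub-`L_f` leftovers are
dropped silently, which is what keeps short identical-by-state runs from
becoming false positive IBD.

Parameters, with defaults:

| parameter | unit  | default | role |
|-----------|-------|---------|------|
| `L_m`     | sites | 200     | minimum fragment span; merge gap bound; phase-correction adjacency tolerance |
| `L_f`     | cM    | 3.0     | minimum reported segment length |
| `M_t`     | sites | 10      | longest missing run a match extends through |

`L_m = 200` and `L_f = 3.0` are the standard settings for array-density
data; `M_t` has no canonical published value, and 10 consecutive missing
sites is far beyond what passes array QC, so it only matters for degraded
data.  At 100+ sites/cM, 200 sites ≈ 1–2 cM, comfortably below `L_f`.

## Missing data

A missing allele is imputed, per template, from whichever sorted neighbour
carries the longer current match (the smaller divergence value; ties go to
the predecessor, and a missing successor defers to the predecessor too).
This is deliberately local: different templates may impute differently.
Runs of missing sites longer than `M_t` terminate the match: the
haplotype's matches up to its last observed site are emitted, and a
per-haplotype validity barrier truncates any later fragment so it cannot
claim the invalid stretch.  The *ordering* update always imputes — so the
sorted order is a pure function of the raw alleles, independent of `M_t` —
which is what lets a compressed-panel reader rebuild the orderings exactly
without knowing the analysis parameters.

## Phase correction

A switch error in individual Q moves every downstream allele to the
complementary haplotype: each segment spanning it splits into an
(same-haplotype-in-P, complementary-in-Q) fragment pair.  When a fragment is
stored and an open match exists between the same two individuals on a
complementary haplotype combination, the arrangement is classified
(same/same → plain merge; comp/comp → switch in both; same/comp → switch in
the complementary individual).  Adjacency means the new fragment starts no
more than `L_m` sites after the open match's end; any overlap counts as
adjacent, because once corrections modify the label streams, the divergence
array legitimately backdates a continuation's start well before the open
match's end.  On a switch verdict the fragment is merged into the open
match (stitching) and the inferred individual toggles orientation: all its
future allele reads, in every template, come from the other physical row.

Two bookkeeping rules make the heuristic stable.  First, every applied
switch position is remembered per individual, along with the sweep position
where the toggle took effect, and any further switch evidence within `L_m`
sites of a remembered position is merged without re-toggling: after a
correction, the individual's other pairs necessarily re-deliver fragments
that start at the same positions, and acting on them again would ping-pong
the orientation through the whole cohort.  Distinct switches farther apart
than `L_m` sites are always applied; no other minimum spacing is imposed.
Second, corrections are global per individual — never per pair — so if A–B
evidence fixes a switch in A, the A–C segment spanning the same position is
stitched too (cohort consistency / triangulation, exercised directly in the
tests).

The heuristic fires on real transmission crossovers as well (a parent–child
segment genuinely alternates between the parent's haplotypes), merging
truth-contiguous sharing into one reported segment; evaluation therefore
counts segments on the pair-level interval union (below).  For haploid data
(`haploid=True`) the heuristic is disabled outright.  Corrected phase is
internal state only; no re-phased output is emitted.

Known limitation: overlapping complementary-haplotype segments that are
*not* switch artifacts — sibling IBD2 — can satisfy the adjacency test and
trigger a spurious toggle.  Toggles are self-healing (the relabelled
continuations re-merge into the same union intervals), and pair-level union
counting is invariant to them, but haplotype labels in the reported table
are only meaningful up to these orientation flips downstream of a switch.

## Compressed panels and out-of-sample sweeps

`compress_panel` runs the ordering half of the sweep and records, at every
(site, template) cell, the allele run-lengths in that template's current
order (`docs/panel_format.md` has the byte layout).  Encoding never applies
phase corrections, so decompression is bit-exact and the stored runs
determine the orderings.  An out-of-sample sweep treats panels X and Y as
one alignment: because the counting sort is stable, the combined ordering
is the linear sum of the two panel orderings (each panel's relative order is
preserved — asserted against independently decoded panels in the tests),
and each panel's alleles are read once per encoded run.  Match arrays are
restricted to cross pairs, so memory scales as `M_X · M_Y`.  With phase
correction on, out-of-sample corrections see only cross-panel evidence and
may differ from an in-sample run on the union; the equivalence test
therefore runs with correction off.  Panels are immutable; corrections
never propagate into stored files.

The batch driver mirrors the large-cohort scheme: *b* within-batch
in-sample computes (writing panels) plus C(*b*, 2) cross comparisons, all
independent, merged at the end; with correction off this equals the direct
run on the concatenation.

## Synthetic data

The simulator gene-drops founder haplotypes through a three-generation
pedigree: three grandparent couples produce two sibling parents and two
married-in spouses, who produce three grandchildren — one labelled pair of
each type (parent–child, grandparent–grandchild, aunt–niece, first cousins,
siblings) per pedigree.  Transmissions draw crossover counts from
Poisson(length/100 cM) with i.i.d. uniform positions (no interference, no
sex-specific maps) and splice parental haplotypes, carrying founder-label
ancestry tracks; true IBD for a pair is wherever they share a founder
label.  Truth is stored per haplotype combination and unfiltered — length
floors are applied at evaluation time.

Observation errors mimic the measured properties of real pipelines rather
than their mechanisms: genotype calls are hit at rate 0.001 with one of the
two alleles flipped evenly, and at each heterozygous site the downstream
phase toggles with probability 0.0025 (the 0.25% switch error rate typical
of large-panel statistical phasing).  Direct injection reproduces the rate
but not the spatial clustering a real phaser produces, and the built-in
founders draw independent sites at frequencies U(0.05, 0.95) — no linkage
disequilibrium.  Passing tests therefore demonstrate correct segment
recovery under calibrated error *rates*, not performance under real LD
structure or real phaser error geometry, where background IBS is longer and
short-segment false positives are harder.

Study conditions for the recovery tests: one uniform 50 cM chromosome with
6000 sites (120 sites/cM, the same order as array data after QC), 20
replicate pedigrees, seeds fixed in the tests.  At these sizes a full
corrected sweep of one pedigree (26 haplotypes) takes well under a second,
keeping the whole suite fast.

## Evaluation conventions

Pair summaries (λ, λ̂, η, η̂) are computed on the haplotype-agnostic union
of the pair's segment intervals in cM, identically for truth and estimate,
with union intervals closer than 0.1 cM merged (site-anchored endpoints of
truth pieces that abut at a crossover differ by one inter-site gap, which
must not count as a real break; genuine fragmentation gaps are an order of
magnitude larger).  The union is what makes "error-free calls recover the
truth exactly" a meaningful statement: a phase-aware caller with correction
on legitimately reports a parent–child pair's haplotype-alternating sharing
as one segment.  Error statistics are the printed forms (η̂ − η) and
(λ̂ − λ)/γ.

Binned FN/FP rates use the half-open length bins 3–4, 4–5, 5–6, 7–8, 9–10,
10–11, 12–15, 15–18, >18 cM, including the deliberate 6–7, 8–9 and 11–12
gaps (segments in a gap are excluded); a contiguous variant exists.
Overlap is judged on the pair's cM intervals regardless of haplotype, any
positive overlap counting.  FP denominators default to the true-segment
counts/lengths in the bin as conventionally printed; the estimated-side
denominator is available (`fp_denominator="estimated"`), and only under it
does the FN↔FP role-swap symmetry hold exactly.  Empty bins yield NaN, not
zero.  Trio validation labels a child–relative segment validated when any
overlapping segment links the relative to either parent, and reports the
per-bin validated fraction (hmean) with counts.

## Degenerate inputs and errors

Single-site alignments, empty segment lists, and maps with one knot are
accepted (interpolation clamps outside the mapped range).  Rejected with
errors: unphased or multiallelic VCF records, odd haplotype counts,
non-monotone coordinates, mask sets leaving a residue uncovered, panels
with mismatched sites or template sets, corrupt or truncated panel files
(with byte offset).

## Out of scope

Statistical phasing and reference panels; running competitor callers;
set-maximal match queries against an indexed panel; crossover interference;
emitting corrected haplotypes; multi-chromosome files (run per chromosome).
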