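"""Gene-dropping simulation over three-generation pedigrees.

Founder haplotypes are dropped through a pedigree with Poisson recombination
(1 expected crossover per 100 cM, no interference), tracking for every
transmitted haplotype which founder haplotype each interval descends from.
True IBD segments between a pair of individuals are then read off as the
maximal intervals over which they carry the same founder haplotype label,
giving simulated data sets with perfectly known IBD.

Two observation-error injectors mimic real pipelines: genotyping miscalls
(each genotype call is hit with probability 0.001, and one of its two
alleles, chosen evenly, is flipped) and statistical phasing errors (at each
heterozygous site the downstream phase toggles with probability 0.0025, the
0.25% switch error rate typical of large-panel phasing).  Neither injector
touches the ancestry, so truth tracks are invariant under both.

Built-in founders draw independent sites with allele frequencies uniform on
(0.05, 0.95); real linkage disequilibrium is absent, which is irrelevant for
correctness of segment recovery but understates background identity by
state (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import HaplotypeAlignment

__all__ = [
    "PedigreeSpec",
    "AncestryTrack",
    "TrueIBDSegment",
    "PedigreeSimResult",
    "default_pedigree_spec",
    "simulate_founder_alignment",
    "sample_crossovers",
    "simulate_pedigree",
    "add_genotype_errors",
    "add_switch_errors",
]

PAIR_TYPES = (
    "parent_child",
    "grandparent_grandchild",
    "aunt_niece",
    "first_cousins",
    "siblings",
)


@dataclass(frozen=True)
class PedigreeSpec:
    """An acyclic three-generation pedigree with labelled pairs of interest.

    ``parents`` maps each non-founder to its (father, mother); members
    without an entry are founders and consume haplotypes from the supplied
    founder alignment in ``members`` order.
    """

    members: tuple[str, ...]
    parents: dict[str, tuple[str, str]]
    labeled_pairs: dict[str, tuple[tuple[str, str], ...]]

    def __post_init__(self) -> None:
        known = set(self.members)
        for child, (f, m) in self.parents.items():
            if child not in known or f not in known or m not in known:
                raise ValueError(f"unknown member in edge {child} <- ({f}, {m})")
        # acyclicity + generation depth via longest ancestor chain
        depth: dict[str, int] = {}

        def _depth(x: str, seen: frozenset) -> int:
            if x in seen:
                raise ValueError(f"pedigree cycle through {x}")
            if x not in depth:
                if x not in self.parents:
                    depth[x] = 0
                else:
                    f, m = self.parents[x]
                    s = seen | {x}
                    depth[x] = 1 + max(_depth(f, s), _depth(m, s))
            return depth[x]

        for x in self.members:
            _depth(x, frozenset())
        for ptype in PAIR_TYPES:
            if not self.labeled_pairs.get(ptype):
                raise ValueError(f"pedigree lacks a labelled {ptype} pair")

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(m for m in self.members if m not in self.parents)


def default_pedigree_spec() -> PedigreeSpec:
    """Three grandparent couples -> two sibling parents plus two married-in
    spouses -> three grandchildren; contains one labelled pair of each type."""
    members = (
        "g1", "g2", "g3", "g4", "g5", "g6",
        "p1", "p2", "q1", "q2",
        "c1", "c2", "d1",
    )
    parents = {
        "p1": ("g1", "g2"),
        "p2": ("g1", "g2"),
        "q1": ("g3", "g4"),
        "q2": ("g5", "g6"),
        "c1": ("p1", "q1"),
        "c2": ("p1", "q1"),
        "d1": ("p2", "q2"),
    }
    labeled = {
        "parent_child": (("p1", "c1"),),
        "grandparent_grandchild": (("g1", "c1"),),
        "aunt_niece": (("p2", "c1"),),
        "first_cousins": (("c1", "d1"),),
        "siblings": (("c1", "c2"),),
    }
    return PedigreeSpec(members=members, parents=parents, labeled_pairs=labeled)


def simulate_founder_alignment(
    n_individuals: int,
    n_sites: int,
    length_cm: float,
    rng: np.random.Generator,
    chromosome: str = "1",
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> HaplotypeAlignment:
    """Independent-site founder haplotypes with per-site allele frequencies
    drawn uniformly from ``maf_range``; uniform genetic map over ``length_cm``."""
    freqs = rng.uniform(*maf_range, size=n_sites)
    alleles = (rng.random((2 * n_individuals, n_sites)) < freqs).astype(np.int8)
    bp = np.linspace(1, 1_000_000 * max(length_cm, 1.0) / 100, n_sites).astype(np.int64)
    bp = np.maximum.accumulate(bp)
    bp += np.arange(n_sites)  # ensure strictly increasing
    cm = np.linspace(0.0, length_cm, n_sites)
    return HaplotypeAlignment(
        alleles=alleles,
        bp=bp,
        cm=cm,
        sample_ids=[f"f{i}" for i in range(n_individuals)],
        chromosome=chromosome,
    )


def sample_crossovers(length_cm: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions for one meiosis: count ~ Poisson(length/100 cM),
    positions i.i.d. uniform over the chromosome, returned sorted."""
    if length_cm < 0:
        raise ValueError("chromosome length must be non-negative")
    n = rng.poisson(length_cm / 100.0)
    return np.sort(rng.uniform(0.0, length_cm, size=n))


# An ancestry track is a list of (start_cm, end_cm, founder_haplotype_label)
# half-open intervals tiling [0, length_cm).
AncestryTrack = list[tuple[float, float, int]]


@dataclass(frozen=True)
class TrueIBDSegment:
    """A maximal interval over which two individuals share a founder label."""

    id1: str
    id2: str
    hap_a: int
    hap_b: int
    start_site: int
    end_site: int
    start_cm: float
    end_cm: float
    founder_label: int

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def interval_cm(self) -> tuple[float, float]:
        return (self.start_cm, self.end_cm)


@dataclass
class PedigreeSimResult:
    alignment: HaplotypeAlignment
    spec: PedigreeSpec
    tracks: dict[str, tuple[AncestryTrack, AncestryTrack]]
    truth: list[TrueIBDSegment]

    def truth_for_pair(self, id1: str, id2: str) -> list[TrueIBDSegment]:
        key = frozenset((id1, id2))
        return [s for s in self.truth if frozenset((s.id1, s.id2)) == key]


def _splice(
    tracks: tuple[AncestryTrack, AncestryTrack],
    rows: np.ndarray,
    cm: np.ndarray,
    xovers: np.ndarray,
    start_hap: int,
    length_cm: float,
) -> tuple[AncestryTrack, np.ndarray]:
    """One gamete: alternate parental haplotypes at the crossover positions."""
    bounds = np.concatenate(([0.0], xovers, [length_cm]))
    # allele row: site -> which parental hap transmitted
    seg_of_site = np.searchsorted(xovers, cm, side="right")
    hap_of_site = (start_hap + seg_of_site) % 2
    row = np.where(hap_of_site == 0, rows[0], rows[1]).astype(np.int8)
    track: AncestryTrack = []
    for i in range(len(bounds) - 1):
        a, b = float(bounds[i]), float(bounds[i + 1])
        if b <= a:
            continue
        src = tracks[(start_hap + i) % 2]
        for s, e, lab in src:
            lo, hi = max(s, a), min(e, b)
            if hi > lo:
                if track and track[-1][2] == lab and track[-1][1] == lo:
                    track[-1] = (track[-1][0], hi, lab)
                else:
                    track.append((lo, hi, lab))
    return track, row


def _equal_label_intervals(
    ta: AncestryTrack, tb: AncestryTrack
) -> list[tuple[float, float, int]]:
    """Intervals where two tracks carry the same founder label."""
    out: list[tuple[float, float, int]] = []
    ia = ib = 0
    while ia < len(ta) and ib < len(tb):
        sa, ea, la = ta[ia]
        sb, eb, lb = tb[ib]
        lo, hi = max(sa, sb), min(ea, eb)
        if hi > lo and la == lb:
            if out and out[-1][2] == la and out[-1][1] == lo:
                out[-1] = (out[-1][0], hi, la)
            else:
                out.append((lo, hi, la))
        if ea <= eb:
            ia += 1
        else:
            ib += 1
    return out


def simulate_pedigree(
    spec: PedigreeSpec,
    founder_alignment: HaplotypeAlignment,
    rng: np.random.Generator,
) -> PedigreeSimResult:
    """Drop founder haplotypes through the pedigree and record the truth.

    Founders consume the founder alignment's individuals in order; raises if
    there are too few.  Truth segments are computed for the labelled pairs,
    one per haplotype combination sharing a founder label, with cM endpoints
    anchored to the sites they span.
    """
    founders = spec.founders
    if founder_alignment.n_individuals < len(founders):
        raise ValueError(
            f"pedigree needs {len(founders)} founders, alignment has "
            f"{founder_alignment.n_individuals}"
        )
    cm = founder_alignment.cm
    length_cm = float(cm[-1])
    n_sites = founder_alignment.n_sites
    rows: dict[str, np.ndarray] = {}
    tracks: dict[str, tuple[AncestryTrack, AncestryTrack]] = {}
    for idx, fid in enumerate(founders):
        rows[fid] = founder_alignment.alleles[2 * idx : 2 * idx + 2].copy()
        tracks[fid] = (
            [(0.0, length_cm, 2 * idx)],
            [(0.0, length_cm, 2 * idx + 1)],
        )
    # process non-founders in dependency order
    pending = [m for m in spec.members if m in spec.parents]
    while pending:
        progressed = False
        for m in list(pending):
            f, mo = spec.parents[m]
            if f in rows and mo in rows:
                gametes = []
                gtracks = []
                for parent in (f, mo):
                    xo = sample_crossovers(length_cm, rng)
                    start = int(rng.integers(0, 2))
                    tr, row = _splice(
                        tracks[parent], rows[parent], cm, xo, start, length_cm
                    )
                    gametes.append(row)
                    gtracks.append(tr)
                rows[m] = np.stack(gametes)
                tracks[m] = (gtracks[0], gtracks[1])
                pending.remove(m)
                progressed = True
        if not progressed:
            raise ValueError("unresolvable pedigree ordering")
    alleles = np.concatenate([rows[m] for m in spec.members], axis=0)
    alignment = HaplotypeAlignment(
        alleles=alleles,
        bp=founder_alignment.bp.copy(),
        cm=cm.copy(),
        sample_ids=list(spec.members),
        chromosome=founder_alignment.chromosome,
    )
    member_index = {m: i for i, m in enumerate(spec.members)}
    truth: list[TrueIBDSegment] = []
    seen_pairs = set()
    for pairs in spec.labeled_pairs.values():
        for id1, id2 in pairs:
            key = frozenset((id1, id2))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            for ha in (0, 1):
                for hb in (0, 1):
                    for s, e, lab in _equal_label_intervals(
                        tracks[id1][ha], tracks[id2][hb]
                    ):
                        start_site = int(np.searchsorted(cm, s, side="left"))
                        end_site = int(np.searchsorted(cm, e, side="left")) - 1
                        if end_site < start_site:
                            continue
                        truth.append(
                            TrueIBDSegment(
                                id1=id1,
                                id2=id2,
                                hap_a=2 * member_index[id1] + ha,
                                hap_b=2 * member_index[id2] + hb,
                                start_site=start_site,
                                end_site=end_site,
                                start_cm=float(cm[start_site]),
                                end_cm=float(cm[end_site]),
                                founder_label=lab,
                            )
                        )
    return PedigreeSimResult(alignment=alignment, spec=spec, tracks=tracks, truth=truth)


def add_genotype_errors(
    alignment: HaplotypeAlignment,
    rate: float = 0.001,
    rng: np.random.Generator | None = None,
) -> HaplotypeAlignment:
    """Genotype miscalls: each genotype call is selected with probability
    ``rate``; one of its two alleles (chosen with probability 1/2 each) is
    flipped 0 <-> 1.  Missing alleles are never flipped."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("error rate must be a probability")
    if rng is None:
        rng = np.random.default_rng()
    out = alignment.copy()
    n_ind, n = alignment.n_individuals, alignment.n_sites
    hit = rng.random((n_ind, n)) < rate
    which = rng.integers(0, 2, size=(n_ind, n))
    rows = 2 * np.arange(n_ind)[:, None] + which
    ind_idx, site_idx = np.nonzero(hit)
    row_idx = rows[ind_idx, site_idx]
    vals = out.alleles[row_idx, site_idx]
    ok = vals >= 0
    out.alleles[row_idx[ok], site_idx[ok]] = 1 - vals[ok]
    return out


def add_switch_errors(
    alignment: HaplotypeAlignment,
    switch_rate: float = 0.0025,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeAlignment, dict[str, list[int]]]:
    """Phase switch errors: at each heterozygous site of each individual the
    downstream phase toggles (suffixes of the two haplotypes exchanged, from
    that site on) with probability ``switch_rate``.

    Returns the perturbed alignment and the realised switch sites per
    individual.  Unordered genotypes are unchanged.
    """
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError("switch rate must be a probability")
    if rng is None:
        rng = np.random.default_rng()
    out = alignment.copy()
    switches: dict[str, list[int]] = {}
    for i, sid in enumerate(alignment.sample_ids):
        a0 = out.alleles[2 * i]
        a1 = out.alleles[2 * i + 1]
        het = (a0 >= 0) & (a1 >= 0) & (a0 != a1)
        draw = rng.random(alignment.n_sites) < switch_rate
        sw_sites = np.nonzero(het & draw)[0]
        switches[sid] = [int(s) for s in sw_sites]
        if len(sw_sites):
            parity = np.zeros(alignment.n_sites, dtype=np.int64)
            parity[sw_sites] = 1
            odd = np.cumsum(parity) % 2 == 1
            tmp = a0[odd].copy()
            a0[odd] = a1[odd]
            a1[odd] = tmp
    return out, switches
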