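"""Phased-haplotype input/output and genetic-map interpolation.

The in-memory representation used throughout the package is a
:class:`HaplotypeAlignment`: ``M`` haplotypes by ``N`` biallelic sites, with
physical (bp) and genetic (cM) coordinates attached to every site.  Haplotype
rows ``2i`` and ``2i + 1`` always belong to diploid individual ``i``.

Coordinates are 0-based site indices internally; reported bp positions are the
VCF ``POS`` values (1-based, inclusive at both segment ends).  The genetic
length of a segment is ``cm[end_site] - cm[start_site]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SEGMENT_COLUMNS = [
    "id1",
    "id2",
    "hap1",
    "hap2",
    "chromosome",
    "start_site",
    "end_site",
    "start_bp",
    "end_bp",
    "start_cm",
    "end_cm",
    "length_cm",
]


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear map from physical (bp) to genetic (cM) position.

    ``bp_positions`` must be strictly increasing and ``cm_positions``
    non-decreasing; positions outside the mapped range clamp to the end values.
    """

    chromosome: str
    bp_positions: np.ndarray
    cm_positions: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp_positions, dtype=np.int64)
        cm = np.asarray(self.cm_positions, dtype=np.float64)
        if bp.size == 0:
            raise ValueError("genetic map is empty")
        if bp.size != cm.size:
            raise ValueError("bp and cM arrays differ in length")
        if bp.size >= 2 and not np.all(np.diff(bp) > 0):
            raise ValueError("map bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("map cM positions must be non-decreasing")
        object.__setattr__(self, "bp_positions", bp)
        object.__setattr__(self, "cm_positions", cm)

    def interpolate(self, bp: int | Sequence[int] | np.ndarray) -> np.ndarray | float:
        return interpolate_genetic_position(self, bp)


def interpolate_genetic_position(
    genetic_map: GeneticMap, bp: int | Sequence[int] | np.ndarray
) -> float | np.ndarray:
    """Linearly interpolate genetic position (cM) at physical position(s) ``bp``.

    Positions below the first or above the last map knot clamp to the end cM
    values.  Scalar input returns a float.
    """
    out = np.interp(bp, genetic_map.bp_positions, genetic_map.cm_positions)
    if np.isscalar(bp) or np.ndim(bp) == 0:
        return float(out)
    return out


def read_genetic_map(path) -> GeneticMap:
    """Read a 3-column whitespace-separated genetic map: chrom, bp, cM."""
    tbl = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "bp", "cm"],
        comment="#",
        dtype={"chromosome": str},
    )
    chroms = tbl["chromosome"].unique()
    if len(chroms) != 1:
        raise ValueError(f"genetic map must cover one chromosome, found {list(chroms)}")
    return GeneticMap(
        chromosome=str(chroms[0]),
        bp_positions=tbl["bp"].to_numpy(np.int64),
        cm_positions=tbl["cm"].to_numpy(np.float64),
    )


@dataclass
class HaplotypeAlignment:
    """``M`` phased haplotypes over ``N`` biallelic sites on one chromosome.

    ``alleles`` is an ``M x N`` int8 array with values 0, 1, or ``MISSING``
    (-1).  Rows ``2i`` and ``2i + 1`` are the two haplotypes of
    ``sample_ids[i]``.
    """

    alleles: np.ndarray
    bp: np.ndarray
    cm: np.ndarray
    sample_ids: list[str]
    chromosome: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        m, n = self.alleles.shape
        if n < 1:
            raise ValueError("alignment needs at least one site")
        if m != 2 * len(self.sample_ids):
            raise ValueError(
                f"{m} haplotype rows but {len(self.sample_ids)} sample ids "
                "(expected two rows per individual)"
            )
        if self.bp.shape != (n,) or self.cm.shape != (n,):
            raise ValueError("bp/cm length must equal the number of sites")
        if n >= 2 and not np.all(np.diff(self.bp) > 0):
            raise ValueError("bp positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cM positions must be non-decreasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "HaplotypeAlignment":
        return HaplotypeAlignment(
            self.alleles.copy(),
            self.bp.copy(),
            self.cm.copy(),
            list(self.sample_ids),
            self.chromosome,
        )

    def subset_sites(self, site_index: np.ndarray) -> "HaplotypeAlignment":
        """Restrict the alignment to the given (sorted) site indices."""
        idx = np.asarray(site_index)
        return HaplotypeAlignment(
            self.alleles[:, idx],
            self.bp[idx],
            self.cm[idx],
            list(self.sample_ids),
            self.chromosome,
        )


def read_phased_vcf(path, genetic_map: GeneticMap) -> HaplotypeAlignment:
    """Read a phased single-chromosome biallelic-SNP VCF into an alignment.

    Haplotype row ``2i`` takes the first GT allele of sample ``i`` and row
    ``2i + 1`` the second; ``.`` alleles become :data:`MISSING`.  Genetic
    positions come from ``genetic_map`` interpolation.

    Raises ``ValueError`` for unphased genotypes (``/`` separator),
    multiallelic records, or records on a different chromosome than the map.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    bps: list[int] = []
    chrom: str | None = None
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in VCF: {chrom} and {var.CHROM}"
            )
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; "
                "only biallelic SNPs are supported"
            )
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if not phased and a0 != a1:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            col[2 * i] = MISSING if a0 < 0 else a0
            col[2 * i + 1] = MISSING if a1 < 0 else a1
        cols.append(col)
        bps.append(var.POS)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    if chrom != genetic_map.chromosome:
        raise ValueError(
            f"VCF chromosome {chrom!r} does not match map chromosome "
            f"{genetic_map.chromosome!r}"
        )
    bp = np.asarray(bps, dtype=np.int64)
    cm = interpolate_genetic_position(genetic_map, bp)
    return HaplotypeAlignment(
        alleles=np.stack(cols, axis=1),
        bp=bp,
        cm=np.asarray(cm, dtype=np.float64),
        sample_ids=samples,
        chromosome=str(chrom),
    )


def write_phased_vcf(alignment: HaplotypeAlignment, path) -> None:
    """Write the alignment as a minimal phased VCF (REF=A, ALT=G placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={alignment.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(alignment.sample_ids)
            + "\n"
        )
        sym = {0: "0", 1: "1", MISSING: "."}
        for k in range(alignment.n_sites):
            col = alignment.alleles[:, k]
            gts = "\t".join(
                f"{sym[int(col[2 * i])]}|{sym[int(col[2 * i + 1])]}"
                for i in range(alignment.n_individuals)
            )
            fh.write(
                f"{alignment.chromosome}\t{int(alignment.bp[k])}\t.\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def write_genetic_map(genetic_map: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for bp, cm in zip(genetic_map.bp_positions, genetic_map.cm_positions):
            fh.write(f"{genetic_map.chromosome}\t{int(bp)}\t{cm:.8g}\n")


def segments_to_dataframe(segments: Iterable) -> pd.DataFrame:
    """Tabulate IBD segments (one row per segment) in the output column order."""
    rows = [
        {
            "id1": s.id1,
            "id2": s.id2,
            "hap1": s.hap_a % 2,
            "hap2": s.hap_b % 2,
            "chromosome": s.chromosome,
            "start_site": s.start_site,
            "end_site": s.end_site,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "start_cm": s.start_cm,
            "end_cm": s.end_cm,
            "length_cm": s.length_cm,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments(segments: Iterable, sink) -> None:
    """Write IBD segments as a tab-separated table with a header line.

    Floating-point columns are rendered with ``repr`` round-trip precision so
    that write -> read -> write is byte-identical.
    """
    df = segments if isinstance(segments, pd.DataFrame) else segments_to_dataframe(segments)
    buf = io.StringIO()
    buf.write("\t".join(SEGMENT_COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        vals = []
        for col, v in zip(SEGMENT_COLUMNS, row):
            if col in ("start_cm", "end_cm", "length_cm"):
                vals.append(repr(float(v)))
            elif col in ("hap1", "hap2", "start_site", "end_site", "start_bp", "end_bp"):
                vals.append(str(int(v)))
            else:
                vals.append(str(v))
        buf.write("\t".join(vals) + "\n")
    if hasattr(sink, "write"):
        sink.write(buf.getvalue())
    else:
        with open(sink, "w") as fh:
            fh.write(buf.getvalue())


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"id1": str, "id2": str, "chromosome": str}
    )
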