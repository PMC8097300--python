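"""Run-length-compressed haplotype panels in templated-PBWT order.

At every site each template keeps the haplotypes sorted so that those with
matching recent history are adjacent (the positional prefix array).  Linkage
disequilibrium makes adjacent haplotypes tend to carry the same allele, so
the allele column in that order collapses into a few long runs.  A site
processed by ``c`` templates is encoded ``c`` times, once per ordering.

Because the orderings are maintained by the same deterministic sort used in
the IBD sweep, a reader can rebuild them incrementally from the decoded
alleles alone, so the format stores only the runs plus coordinates and ids.
The encoding sweep never applies phase corrections: stored runs are a pure
function of the raw alleles, and decompression is bit-exact (missing alleles
are stored explicitly as a third symbol).

Binary layout (documented field-by-field in ``docs/panel_format.md``):
little-endian, magic ``TPBW1``, header (version, M, N, template masks,
chromosome, sample ids, bp/cM coordinates), then for each site and each
template processing it, a varint run count followed by varint-encoded runs
``(length << 2) | symbol`` with symbols 0, 1, 2=missing.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .haplotype_io import MISSING, HaplotypeAlignment
from .tpbwt_core import (
    TemplateSet,
    TPBWTParams,
    advance_order,
    default_templates,
    resolve_missing_column,
)

MAGIC = b"TPBW1"
VERSION = 1

_SYM_TO_STORE = {0: 0, 1: 1, MISSING: 2}
_STORE_TO_SYM = {0: 0, 1: 1, 2: MISSING}


class PanelFormatError(ValueError):
    pass


@dataclass
class CompressedPanel:
    """A haplotype panel stored as per-template allele runs in ppa order."""

    templates: TemplateSet
    sample_ids: list[str]
    chromosome: str
    bp: np.ndarray
    cm: np.ndarray
    runs: dict[tuple[int, int], list[tuple[int, int]]]  # (site, template) -> [(sym, len)]

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.bp)

    def covering_templates(self, site: int) -> list[int]:
        return [
            j for j in range(self.templates.t) if self.templates.processes(j, site)
        ]


def _rle(values: list[int]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    prev = None
    count = 0
    for v in values:
        if v == prev:
            count += 1
        else:
            if prev is not None:
                out.append((prev, count))
            prev, count = v, 1
    if prev is not None:
        out.append((prev, count))
    return out


def compress_panel(
    alignment: HaplotypeAlignment,
    templates: TemplateSet | None = None,
    params: TPBWTParams | None = None,
) -> CompressedPanel:
    """Run the ordering sweep over the alignment, recording allele runs.

    The sweep is the same pass that computes in-sample IBD (and costs the
    same); only the ordering side of it matters here, so no match arrays are
    kept and no phase corrections are applied.
    """
    if templates is None:
        templates = default_templates()
    del params  # accepted for interface symmetry; ordering needs none of it
    t = templates.t
    per = templates.period
    m = alignment.n_haplotypes
    cols = alignment.alleles.T.tolist()
    ppa = [list(range(m)) for _ in range(t)]
    div = [[0] * m for _ in range(t)]
    next_off = _next_offsets(templates)
    runs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for k in range(alignment.n_sites):
        col = cols[k]
        r = k % per
        for j in range(t):
            if not templates.masks[j][r]:
                continue
            raw = [col[h] for h in ppa[j]]
            runs[(k, j)] = _rle([_SYM_TO_STORE[v] for v in raw])
            resolved = resolve_missing_column(raw, div[j])
            ppa[j], div[j] = advance_order(ppa[j], div[j], resolved, k + next_off[j][r])
    return CompressedPanel(
        templates=templates,
        sample_ids=list(alignment.sample_ids),
        chromosome=alignment.chromosome,
        bp=alignment.bp.copy(),
        cm=alignment.cm.copy(),
        runs=runs,
    )


def _next_offsets(templates: TemplateSet) -> list[list[int]]:
    per = templates.period
    out = []
    for mask in templates.masks:
        offs = []
        for r in range(per):
            offs.append(
                next((d for d in range(1, per + 1) if mask[(r + d) % per]), per)
            )
        out.append(offs)
    return out


def iterate_runs(panel: CompressedPanel, site: int, template: int):
    """The ordered (allele, run_length) runs of one (site, template) cell.

    Alleles are 0, 1 or :data:`MISSING`; run lengths sum to the number of
    haplotypes.  Raises if the template masks this site.
    """
    if not panel.templates.processes(template, site):
        raise ValueError(f"template {template} does not process site {site}")
    for sym, length in panel.runs[(site, template)]:
        yield _STORE_TO_SYM[sym], length


class PanelDecoder:
    """Sequential reader that rebuilds per-template orderings while decoding.

    ``peek(k)`` exposes the runs and current ordering of the first template
    covering site ``k`` (for merged-order traversal); ``column(k)`` returns
    the raw alleles of all haplotypes at ``k`` and advances the orderings.
    Sites must be visited left to right.
    """

    def __init__(self, panel: CompressedPanel) -> None:
        self.panel = panel
        t = panel.templates.t
        m = panel.n_haplotypes
        self._ppa = [list(range(m)) for _ in range(t)]
        self._div = [[0] * m for _ in range(t)]
        self._next_off = _next_offsets(panel.templates)
        self._k = 0

    def order(self, template: int) -> list[int]:
        return list(self._ppa[template])

    def peek(self, k: int) -> tuple[list[tuple[int, int]], list[int]]:
        if k != self._k:
            raise ValueError(f"decoder is at site {self._k}, not {k}")
        j = self.panel.covering_templates(k)[0]
        return self.panel.runs[(k, j)], self._ppa[j]

    def column(self, k: int) -> list[int]:
        runs, order = self.peek(k)
        col = expand_runs(runs, order)
        self._advance(k, col)
        return col

    def _advance(self, k: int, col: list[int]) -> None:
        per = self.panel.templates.period
        r = k % per
        for j in self.panel.covering_templates(k):
            raw = [col[h] for h in self._ppa[j]]
            resolved = resolve_missing_column(raw, self._div[j])
            self._ppa[j], self._div[j] = advance_order(
                self._ppa[j], self._div[j], resolved, k + self._next_off[j][r]
            )
        self._k = k + 1


def expand_runs(runs: list[tuple[int, int]], order: list[int]) -> list[int]:
    """Expand (symbol, length) runs laid out in ``order`` into a
    haplotype-indexed allele column, touching each run once."""
    col = [0] * len(order)
    pos = 0
    for sym, length in runs:
        v = _STORE_TO_SYM[sym]
        for _ in range(length):
            col[order[pos]] = v
            pos += 1
    if pos != len(order):
        raise PanelFormatError(
            f"run lengths sum to {pos}, expected {len(order)} haplotypes"
        )
    return col


def decompress_panel(panel: CompressedPanel) -> HaplotypeAlignment:
    """Exact inverse of :func:`compress_panel`."""
    decoder = PanelDecoder(panel)
    m, n = panel.n_haplotypes, panel.n_sites
    alleles = np.empty((m, n), dtype=np.int8)
    for k in range(n):
        alleles[:, k] = decoder.column(k)
    return HaplotypeAlignment(
        alleles=alleles,
        bp=panel.bp.copy(),
        cm=panel.cm.copy(),
        sample_ids=list(panel.sample_ids),
        chromosome=panel.chromosome,
    )


# ---------------------------------------------------------------------------
# binary I/O
# ---------------------------------------------------------------------------


def _write_varint(out: bytearray, value: int) -> None:
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            out.append(b | 0x80)
        else:
            out.append(b)
            return


class _Reader:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise PanelFormatError(
                f"truncated panel file at byte offset {self.pos} "
                f"(needed {n} more bytes)"
            )
        chunk = self.data[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def varint(self) -> int:
        shift = 0
        value = 0
        while True:
            if self.pos >= len(self.data):
                raise PanelFormatError(
                    f"truncated varint at byte offset {self.pos}"
                )
            b = self.data[self.pos]
            self.pos += 1
            value |= (b & 0x7F) << shift
            if not b & 0x80:
                return value
            shift += 7


def write_panel(panel: CompressedPanel, path) -> None:
    out = bytearray()
    out += MAGIC
    out.append(VERSION)
    t, per = panel.templates.t, panel.templates.period
    out += struct.pack("<IIHH", panel.n_haplotypes, panel.n_sites, t, per)
    for mask in panel.templates.masks:
        out += bytes(mask)
    chrom = panel.chromosome.encode()
    out += struct.pack("<H", len(chrom)) + chrom
    out += struct.pack("<I", len(panel.sample_ids))
    for sid in panel.sample_ids:
        raw = sid.encode()
        out += struct.pack("<H", len(raw)) + raw
    out += np.asarray(panel.bp, dtype="<i8").tobytes()
    out += np.asarray(panel.cm, dtype="<f8").tobytes()
    for k in range(panel.n_sites):
        for j in panel.covering_templates(k):
            runs = panel.runs[(k, j)]
            _write_varint(out, len(runs))
            for sym, length in runs:
                _write_varint(out, (length << 2) | sym)
    with open(path, "wb") as fh:
        fh.write(out)


def read_panel(path) -> CompressedPanel:
    with open(path, "rb") as fh:
        rd = _Reader(fh.read())
    if rd.take(len(MAGIC)) != MAGIC:
        raise PanelFormatError(f"not a TPBWT panel: {path}")
    version = rd.take(1)[0]
    if version != VERSION:
        raise PanelFormatError(f"unsupported panel version {version}")
    m, n, t, per = struct.unpack("<IIHH", rd.take(12))
    masks = tuple(tuple(rd.take(per)) for _ in range(t))
    templates = TemplateSet(masks=masks)
    (clen,) = struct.unpack("<H", rd.take(2))
    chromosome = rd.take(clen).decode()
    (nsamp,) = struct.unpack("<I", rd.take(4))
    if 2 * nsamp != m:
        raise PanelFormatError("sample count inconsistent with haplotype count")
    sample_ids = []
    for _ in range(nsamp):
        (slen,) = struct.unpack("<H", rd.take(2))
        sample_ids.append(rd.take(slen).decode())
    bp = np.frombuffer(rd.take(8 * n), dtype="<i8").copy()
    cm = np.frombuffer(rd.take(8 * n), dtype="<f8").copy()
    runs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for k in range(n):
        for j in range(t):
            if not templates.processes(j, k):
                continue
            nruns = rd.varint()
            cell = []
            total = 0
            for _ in range(nruns):
                v = rd.varint()
                sym, length = v & 0x3, v >> 2
                cell.append((sym, length))
                total += length
            if total != m:
                raise PanelFormatError(
                    f"runs at site {k}, template {j} sum to {total}, expected {m}"
                )
            runs[(k, j)] = cell
    if rd.pos != len(rd.data):
        raise PanelFormatError(f"{len(rd.data) - rd.pos} trailing bytes in panel")
    return CompressedPanel(
        templates=templates,
        sample_ids=sample_ids,
        chromosome=chromosome,
        bp=bp,
        cm=cm,
        runs=runs,
    )
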