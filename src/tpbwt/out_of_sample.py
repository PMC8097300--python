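"""IBD between two panels, reporting only cross-panel segments.

When new samples X are compared against an existing cohort Y, the sweep
passes through both sets simultaneously — the combined haplotype ordering is
the linear sum of the two panels' orderings, so each panel's alleles are
queried only at the starts of its encoded runs — while the current-match
arrays are restricted to (x, y) pairs.  Memory for match bookkeeping then
grows as M_X x M_Y instead of (M_X + M_Y)^2, and within-panel matches are
traversed for ordering but never stored or reported.

With phase correction enabled, corrections are inferred from cross-panel
evidence only (the within-panel matches an in-sample run would see are not
tracked), so out-of-sample output may legitimately differ from an in-sample
run on the union; equivalence with the concatenation holds with correction
off.  Panels are immutable: corrections never alter stored panels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .compressed_panel import CompressedPanel, PanelDecoder, expand_runs
from .haplotype_io import HaplotypeAlignment
from .tpbwt_core import (
    IBDSegment,
    SweepDebug,
    SweepEngine,
    TemplateSet,
    TPBWTParams,
    _segments_from_raw,
    default_templates,
)

__all__ = ["compute_ibd_out_of_sample", "merge_orderings"]


def merge_orderings(
    runs_x: list[tuple[int, int]],
    order_x: Sequence[int],
    runs_y: list[tuple[int, int]],
    order_y: Sequence[int],
) -> list[int]:
    """Decode one (site, template) cell of two panels into the combined
    haplotype space (Y haplotypes offset by M_X).

    Within the combined traversal the X haplotypes keep their ppa(X) relative
    order and the Y haplotypes their ppa(Y) relative order (the combined
    ordering is the linear sum of the two totally ordered sets); alleles are
    queried once per encoded run of either panel, never per haplotype.
    """
    col_x = expand_runs(runs_x, list(order_x))
    col_y = expand_runs(runs_y, list(order_y))
    return col_x + col_y


def _as_source(obj, templates: TemplateSet | None):
    """Normalise an alignment or panel into (column_fn, M, bp, cm, ids, chrom,
    templates)."""
    if isinstance(obj, CompressedPanel):
        dec = PanelDecoder(obj)
        return dec.column, obj.n_haplotypes, obj.bp, obj.cm, list(
            obj.sample_ids
        ), obj.chromosome, obj.templates
    if isinstance(obj, HaplotypeAlignment):
        cols = obj.alleles.T.tolist()
        return cols.__getitem__, obj.n_haplotypes, obj.bp, obj.cm, list(
            obj.sample_ids
        ), obj.chromosome, templates
    raise TypeError(f"expected HaplotypeAlignment or CompressedPanel, got {type(obj)}")


def compute_ibd_out_of_sample(
    panel_x,
    panel_y,
    params: TPBWTParams | None = None,
    templates: TemplateSet | None = None,
    debug: SweepDebug | None = None,
) -> list[IBDSegment]:
    """Cross-panel IBD segments between every x in X and y in Y.

    Both inputs may be alignments or compressed panels; they must agree on
    chromosome, site positions and template set.  Returned segments index
    haplotypes in the concatenated (X then Y) space, with sample ids resolved
    from the respective panels.
    """
    if params is None:
        params = TPBWTParams()
    col_x, m_x, bp_x, cm_x, ids_x, chrom_x, tmpl_x = _as_source(panel_x, templates)
    col_y, m_y, bp_y, cm_y, ids_y, chrom_y, tmpl_y = _as_source(panel_y, templates)
    if tmpl_x is None and tmpl_y is None:
        tmpl_x = tmpl_y = default_templates()
    elif tmpl_x is None:
        tmpl_x = tmpl_y
    elif tmpl_y is None:
        tmpl_y = tmpl_x
    if tmpl_x != tmpl_y:
        raise ValueError("panels were built with different template sets")
    if chrom_x != chrom_y:
        raise ValueError(f"chromosome mismatch: {chrom_x!r} vs {chrom_y!r}")
    if len(bp_x) != len(bp_y) or not np.array_equal(bp_x, bp_y):
        raise ValueError("panels cover different sites; subset to shared sites first")

    def column(k: int) -> list[int]:
        return col_x(k) + col_y(k)

    def cross_only(a: int, b: int) -> bool:
        return (a < m_x) != (b < m_x)

    engine = SweepEngine(
        column=column,
        n_haplotypes=m_x + m_y,
        n_sites=len(bp_x),
        cm=cm_x,
        templates=tmpl_x,
        params=params,
        pair_filter=cross_only,
        debug=debug,
    )
    raw = engine.run()
    ids = ids_x + ids_y
    hap_ids = [ids[h // 2] for h in range(m_x + m_y)]
    return _segments_from_raw(raw, bp_x, cm_x, hap_ids, chrom_x)
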