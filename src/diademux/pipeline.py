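"""Convenience pipeline: dilution-series quantification with and without
demultiplexing.

Glue around :mod:`simulate`, :mod:`demux`, :mod:`chrom` and :mod:`metrics`
used by the bundled benchmark scripts and tests: for each simulated
replicate run, a peptide's fragment chromatograms are extracted either
directly (precursor-filtered, no demultiplexing) or demultiplexed into the
peptide's precursor region, integrated over fixed peak boundaries, and
summed over the top-N fragments.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .chrom import PeakBoundaries, extract_xic, integrate_peak, \
    peptide_area_topN
from .demux import TransitionQuery, demultiplex_run
from .simulate import DilutionRun, SimPeptide

__all__ = ["series_areas"]


def series_areas(
    runs: Sequence[DilutionRun],
    peptide: SimPeptide,
    boundaries: PeakBoundaries,
    demultiplexed: bool,
    top_n: int = 5,
    rt_margin: float = 0.4,
) -> dict[float, list[float]]:
    """Per-concentration replicate top-N peak areas for one peptide.

    ``demultiplexed=False`` integrates precursor-filtered chromatograms as
    acquired; ``demultiplexed=True`` demultiplexes scans within
    ``boundaries +/- rt_margin`` minutes and integrates the trace of the
    peptide's own precursor region.  Fragments are ranked by their true
    relative intensity (library order).
    """
    ranks = [mz for mz, _ in sorted(peptide.fragments, key=lambda f: -f[1])]
    frag_mzs = tuple(mz for mz, _ in peptide.fragments)
    query = TransitionQuery(peptide.peptide_id, peptide.precursor_mz,
                            frag_mzs)
    out: dict[float, list[float]] = {}
    for rec in runs:
        if demultiplexed:
            chroms = demultiplex_run(
                rec.run, [query],
                rt_range=(boundaries.start_rt - rt_margin,
                          boundaries.end_rt + rt_margin),
            )[peptide.peptide_id]
        else:
            chroms = {
                mz: extract_xic(rec.run, mz,
                                precursor_filter=peptide.precursor_mz)
                for mz in frag_mzs
            }
        area = peptide_area_topN(chroms, boundaries, ranks, top_n)
        out.setdefault(rec.concentration, []).append(area)
    return out
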