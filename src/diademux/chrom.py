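"""Extracted ion chromatograms, peak integration, and retention-time alignment.

Selectivity is summarized by the total extracted ion current: the
trapezoidal integral of every fragment chromatogram over the whole run,
summed over fragments, with no background subtraction.  Lower totals mean
less co-isolated interference and chemical noise — more precursor
selectivity.

Peak boundaries are seeded (e.g. from ground truth or a detection run in a
reference condition) and refined by a fixed-width local search: candidate
centers are the actual scan retention times within +/- 0.1 min of the seed,
and the chosen center is the one whose unit-sum fragment-intensity vector
best matches a unit-sum reference spectrum in least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.interpolate

from .scheme import DemuxRegion, IsolationWindow
from .spectra_io import Run

__all__ = [
    "Chromatogram",
    "PeakBoundaries",
    "RtAlignment",
    "extract_xic",
    "total_xic_area",
    "integrate_peak",
    "fit_rt_alignment",
    "refine_boundaries_fixed_width",
    "peptide_area_topN",
    "ms1_area",
]

NEUTRON_MASS = 1.00335  # Da, C13 - C12 isotope spacing


@dataclass
class Chromatogram:
    """Per-transition (retention time, intensity) trace, RT in minutes."""

    rt: np.ndarray
    intensity: np.ndarray
    label: tuple = ("", "")
    demuxed: bool = False

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity lengths differ")
        if self.rt.size and np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("chromatogram intensities must be >= 0")


@dataclass(frozen=True)
class PeakBoundaries:
    start_rt: float
    end_rt: float

    def __post_init__(self) -> None:
        if not self.start_rt < self.end_rt:
            raise ValueError(
                f"peak boundaries require start < end, got "
                f"[{self.start_rt}, {self.end_rt}]"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.start_rt + self.end_rt)

    @property
    def width(self) -> float:
        return self.end_rt - self.start_rt


def extract_xic(
    run: Run,
    mz: float,
    tolerance: float = 0.02,
    precursor_filter: float | tuple[float, float] | IsolationWindow
    | DemuxRegion | None = None,
    rt_range: Optional[tuple[float, float]] = None,
    ms_level: int = 2,
) -> Chromatogram:
    """Extract one fragment (or MS1) chromatogram.

    ``precursor_filter`` selects which MS2 scans contribute: a single m/z
    keeps scans whose isolation window contains it; an interval (tuple,
    window, or region) keeps scans whose isolation window fully covers the
    interval.  Intensity at each kept scan is the summed intensity of peaks
    within ``mz +/- tolerance`` (0 when none match).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if precursor_filter is not None and not isinstance(precursor_filter, float):
        if isinstance(precursor_filter, (IsolationWindow, DemuxRegion)):
            precursor_filter = (precursor_filter.low, precursor_filter.high)

    rts, intens = [], []
    for s in run.spectra:
        if s.ms_level != ms_level:
            continue
        if rt_range is not None and not (rt_range[0] <= s.rt <= rt_range[1]):
            continue
        if ms_level == 2 and precursor_filter is not None:
            if isinstance(precursor_filter, tuple):
                lo, hi = precursor_filter
                if not (s.isolation.low <= lo and hi <= s.isolation.high):
                    continue
            elif not s.isolation.contains(float(precursor_filter)):
                continue
        rts.append(s.rt)
        intens.append(s.intensity_near(mz, tolerance))
    return Chromatogram(np.array(rts), np.array(intens), label=("", mz))


def total_xic_area(chromatograms: Sequence[Chromatogram]) -> float:
    """Summed trapezoidal integral (intensity x min) over all fragments,
    across the full RT range, no background subtraction — the precursor
    selectivity metric (lower = more selective)."""
    if not chromatograms:
        raise ValueError("need at least one chromatogram")
    total = 0.0
    for c in chromatograms:
        if c.rt.size >= 2:
            total += float(np.trapezoid(c.intensity, c.rt))
    return total


def integrate_peak(chrom: Chromatogram, boundaries: PeakBoundaries) -> float:
    """Trapezoidal area (intensity x min) between boundaries, no background
    subtraction.  Out-of-range boundaries are clipped with a warning."""
    if chrom.rt.size < 2:
        return 0.0
    lo, hi = boundaries.start_rt, boundaries.end_rt
    if lo < chrom.rt[0] or hi > chrom.rt[-1]:
        warnings.warn(
            f"peak boundaries [{lo:.3f}, {hi:.3f}] clipped to chromatogram "
            f"range [{chrom.rt[0]:.3f}, {chrom.rt[-1]:.3f}]",
            stacklevel=2,
        )
        lo, hi = max(lo, chrom.rt[0]), min(hi, chrom.rt[-1])
        if lo >= hi:
            return 0.0
    inside = (chrom.rt > lo) & (chrom.rt < hi)
    grid = np.concatenate([[lo], chrom.rt[inside], [hi]])
    vals = np.interp(grid, chrom.rt, chrom.intensity)
    return float(np.trapezoid(vals, grid))


@dataclass
class RtAlignment:
    """Monotone RT mapping source -> target fitted on anchor pairs."""

    anchors_source: np.ndarray
    anchors_target: np.ndarray
    weights: np.ndarray
    _forward: object
    linear_fallback: bool = False

    def __call__(self, rt):
        return np.asarray(self._forward(np.asarray(rt, dtype=float)), dtype=float)

    def map_boundaries(self, b: PeakBoundaries) -> PeakBoundaries:
        lo, hi = self(np.array([b.start_rt, b.end_rt]))
        return PeakBoundaries(float(lo), float(hi))

    def inverse(self) -> "RtAlignment":
        return fit_rt_alignment(
            list(zip(self.anchors_target, self.anchors_source)), self.weights
        )


def fit_rt_alignment(
    anchors: Sequence[tuple[float, float]],
    weights: Optional[Sequence[float]] = None,
    smoothing: Optional[float] = None,
) -> RtAlignment:
    """Weighted smoothing-spline RT alignment from (source, target) anchors.

    Falls back to a weighted linear fit (with a warning) if the spline is
    not monotone non-decreasing over the anchor range.  Weights default to
    1; the smoothing factor defaults to the scipy heuristic of the anchor
    count.
    """
    anchors = sorted(anchors)
    if len(anchors) < 2:
        raise ValueError("RT alignment needs at least 2 anchors")
    src = np.array([a[0] for a in anchors], dtype=float)
    tgt = np.array([a[1] for a in anchors], dtype=float)
    w = (np.ones_like(src) if weights is None
         else np.asarray(weights, dtype=float))
    # collapse duplicate source RTs (spline requires strictly increasing x)
    if np.any(np.diff(src) <= 0):
        uniq, inv = np.unique(src, return_inverse=True)
        tgt = np.bincount(inv, weights=w * tgt) / np.bincount(inv, weights=w)
        w = np.bincount(inv, weights=w)
        src = uniq

    fallback = False
    forward = None
    if src.size >= 4:
        spline = scipy.interpolate.UnivariateSpline(
            src, tgt, w=w, k=3, s=smoothing if smoothing is not None else len(src)
        )
        grid = np.linspace(src[0], src[-1], max(200, 4 * src.size))
        if np.all(np.diff(spline(grid)) >= -1e-9):
            forward = spline
    if forward is None:
        if src.size >= 4:
            warnings.warn(
                "spline alignment not monotone; falling back to weighted "
                "linear fit", stacklevel=2,
            )
            fallback = True
        coeffs = np.polyfit(src, tgt, 1, w=np.sqrt(w))
        forward = np.poly1d(coeffs)
    return RtAlignment(src, tgt, w, forward, linear_fallback=fallback)


def refine_boundaries_fixed_width(
    chroms: Sequence[Chromatogram],
    seed_boundaries: PeakBoundaries,
    reference_spectrum: Sequence[float],
    width: float,
    search_halfwidth: float = 0.1,
) -> PeakBoundaries:
    """Fixed-width boundary refinement by local reference-spectrum matching.

    Candidate centers are the actual scan RTs within ``+/- search_halfwidth``
    min of the seed center.  For each candidate, the per-fragment intensity
    vector at that RT is scaled to unit sum and compared with the unit-sum
    reference spectrum; the center minimizing the sum of squared differences
    wins, ties broken toward the seed center.  The returned boundaries have
    exactly the requested width.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    ref = np.asarray(reference_spectrum, dtype=float)
    if ref.size != len(chroms):
        raise ValueError("reference spectrum length must match fragment count")
    seed_center = seed_boundaries.center
    grid = chroms[0].rt
    candidates = grid[np.abs(grid - seed_center) <= search_halfwidth]
    if candidates.size == 0:
        warnings.warn("no scans within the search window; keeping seed "
                      "boundaries", stacklevel=2)
        return seed_boundaries
    ref_n = ref / ref.sum() if ref.sum() > 0 else ref

    def cost(center: float) -> float:
        vec = np.array(
            [np.interp(center, c.rt, c.intensity) for c in chroms]
        )
        total = vec.sum()
        if total <= 0:
            return np.inf
        vec = vec / total
        return float(np.sum((vec - ref_n) ** 2))

    costs = np.array([cost(c) for c in candidates])
    best = np.min(costs)
    if not np.isfinite(best):
        center = seed_center  # all-zero observations: keep the seed
    else:
        tied = candidates[np.isclose(costs, best, rtol=0, atol=1e-12)]
        center = float(tied[np.argmin(np.abs(tied - seed_center))])
    return PeakBoundaries(center - width / 2, center + width / 2)


def peptide_area_topN(
    chroms: dict[float, Chromatogram],
    boundaries: PeakBoundaries,
    library_ranks: Sequence[float],
    n: int = 5,
) -> float:
    """Peptide-level area: sum of integrated areas of the top *n* fragments
    by library rank (``library_ranks`` lists fragment m/z from most to least
    intense in the reference spectrum).  Fewer than *n* fragments: use all.
    """
    chosen = [mz for mz in library_ranks if mz in chroms][:n]
    return sum(integrate_peak(chroms[mz], boundaries) for mz in chosen)


def ms1_area(
    run: Run,
    precursor_mz: float,
    charge: int,
    boundaries: PeakBoundaries,
    tolerance: float = 0.02,
) -> float:
    """Precursor-level area: summed integrated XIC areas of the M, M+1 and
    M+2 isotope peaks (spacing ``1.00335/charge`` Th) from MS1 survey scans.
    """
    if not any(s.ms_level == 1 for s in run.spectra):
        raise ValueError("run contains no MS1 scans")
    total = 0.0
    for k in range(3):
        chrom = extract_xic(
            run, precursor_mz + k * NEUTRON_MASS / charge, tolerance,
            ms_level=1,
        )
        total += integrate_peak(chrom, boundaries)
    return total
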