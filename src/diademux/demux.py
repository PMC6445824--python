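"""Demultiplexing of overlapped DIA scans by non-negative least squares.

For a center MS2 scan *s*, the surrounding MS2 scans (one full pass of every
cycle variant, ``s - 2W .. s + 2W - 1`` MS2 scans for a W-window two-variant
scheme) form a linear system ``X A = Y``:

* ``X`` — scans x regions design matrix; each scan row holds a 1 at every
  demultiplexing region its isolation window covers, plus one final
  regularization row of constant ``lambda``;
* ``Y`` — observed fragment intensities per scan (optionally interpolated
  to the retention time of the center scan so that every row describes the
  same instant of the elution profile), regularization target 0;
* ``A`` — non-negative region x fragment intensities, solved per fragment
  column with the Lawson–Hanson active-set algorithm.

The solved shares are then reallocated proportionally: the observed center
scan intensity of each fragment is split over the regions of its window in
the ratio of the solved region intensities, so per-scan ion counts are
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.signal

from .scheme import (DemuxRegion, IsolationScheme, IsolationWindow,
                     SchemeError, region_of, regions_in_window)
from .spectra_io import Run, Spectrum

__all__ = [
    "TransitionQuery",
    "DesignSystem",
    "DemuxError",
    "build_design_matrix",
    "assemble_observed",
    "build_system",
    "nnls_solve",
    "nnls_solve_banded",
    "demultiplex_scan",
    "demultiplex_run",
]

DEFAULT_MZ_TOLERANCE = 0.02  # Th
DEFAULT_LAMBDA_SCALE = 1e-3  # lambda = scale x median nonzero |Y|


class DemuxError(ValueError):
    """Demultiplexing cannot proceed on the given inputs."""


@dataclass(frozen=True)
class TransitionQuery:
    """Fragments to demultiplex for one peptide precursor."""

    peptide_id: str
    precursor_mz: float
    fragment_mzs: tuple[float, ...]
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE

    def __post_init__(self) -> None:
        if not self.fragment_mzs:
            raise DemuxError(f"{self.peptide_id}: empty fragment list")
        if self.mz_tolerance <= 0:
            raise DemuxError(f"{self.peptide_id}: tolerance must be positive")
        object.__setattr__(self, "fragment_mzs", tuple(self.fragment_mzs))


@dataclass
class DesignSystem:
    """One assembled and (optionally) solved demultiplexing system."""

    X: np.ndarray                    # (n_scans + 1) x n_regions
    Y: np.ndarray                    # (n_scans + 1) x m
    scan_indices: list[int]          # run scan indices of the scan rows
    region_indices: list[int]        # global region index per column of X
    center_scan: int
    lam: float
    truncated: bool = False          # system clipped at a run edge
    A: Optional[np.ndarray] = None   # n_regions x m, solved

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _default_lambda(Y: np.ndarray) -> float:
    nz = np.abs(Y[Y != 0])
    return DEFAULT_LAMBDA_SCALE * float(np.median(nz)) if nz.size else DEFAULT_LAMBDA_SCALE


def build_design_matrix(
    scheme: IsolationScheme,
    scan_windows: Sequence[tuple[int, IsolationWindow]],
    lam: float,
    regions: Optional[Sequence[DemuxRegion]] = None,
) -> np.ndarray:
    """Scans x regions 0/1 design matrix with a final constant-``lam`` row.

    For the default two-variant scheme and 40 scans this is the square
    41 x 41 system with exactly two 1s in every scan row.
    """
    if regions is None:
        regions = scheme.regions()
    X = np.zeros((len(scan_windows) + 1, len(regions)))
    for i, (_, window) in enumerate(scan_windows):
        if not scheme.find_window(window):
            raise DemuxError(
                f"scan window [{window.low},{window.high}) is not part of the scheme"
            )
        for r in regions_in_window(window, regions):
            X[i, r] = 1.0
    X[-1, :] = lam
    return X


def _system_scan_range(run: Run, center_scan: int,
                       scheme: IsolationScheme) -> tuple[list[int], bool]:
    """MS2 scan indices forming the system window around *center_scan*.

    Counts MS2 scans only (interleaved MS1 survey scans are skipped).  The
    window spans one full pass of every variant (2W scans for the default
    scheme), half before and half after the center; at run edges it is
    truncated to the available scans.
    """
    ms2 = run.ms2_indices()
    try:
        pos = ms2.index(center_scan)
    except ValueError:
        raise DemuxError(f"scan {center_scan} is not an MS2 scan")
    total = scheme.n_variants * scheme.windows_per_variant
    lo = pos - total // 2
    hi = lo + total
    truncated = lo < 0 or hi > len(ms2)
    lo_c, hi_c = max(lo, 0), min(hi, len(ms2))
    if hi_c - lo_c < scheme.windows_per_variant:
        raise DemuxError(
            f"scan {center_scan}: fewer than one full cycle of scans available"
        )
    return ms2[lo_c:hi_c], truncated


def _window_key(w: IsolationWindow) -> tuple[float, float]:
    return (round(w.low, 4), round(w.high, 4))


def assemble_observed(
    run: Run,
    center_scan: int,
    query: TransitionQuery,
    scheme: Optional[IsolationScheme] = None,
    interpolate: bool = True,
    smooth: bool = False,
) -> DesignSystem:
    """Assemble the observed-intensity matrix ``Y`` (and matching ``X``).

    ``Y[i, j]`` is the summed intensity of peaks within tolerance of
    fragment *j* in system scan *i*.  With ``interpolate=True`` each entry
    is linearly interpolated between occurrences of that scan's isolation
    window in adjacent cycles, estimating the intensity the window would
    have read at the center scan's retention time — the correction for
    elution-profile shape.  ``smooth=True`` applies a 5-point
    Savitzky–Golay filter to each window's time series first.
    """
    scheme = scheme or run.scheme
    if scheme is None:
        raise DemuxError("run has no isolation scheme attached")
    scan_ids, truncated = _system_scan_range(run, center_scan, scheme)
    spectra = [run.by_index(i) for i in scan_ids]
    center = run.by_index(center_scan)
    frags = query.fragment_mzs
    tol = query.mz_tolerance

    raw = np.array(
        [[s.intensity_near(mz, tol) for mz in frags] for s in spectra]
    )
    if interpolate:
        # Time series of each distinct isolation window across the whole run,
        # so edge systems still see both bracketing occurrences.
        occurrences: dict[tuple[float, float], list[Spectrum]] = {}
        for s in run.spectra:
            if s.ms_level == 2:
                occurrences.setdefault(_window_key(s.isolation), []).append(s)
        rt_c = center.rt
        Yrows = np.empty_like(raw)
        cache: dict[tuple[float, float], np.ndarray] = {}
        for i, s in enumerate(spectra):
            key = _window_key(s.isolation)
            occ = occurrences[key]
            if key not in cache:
                vals = np.array(
                    [[o.intensity_near(mz, tol) for mz in frags] for o in occ]
                )
                if smooth and len(occ) >= 5:
                    vals = scipy.signal.savgol_filter(
                        vals, 5, 2, axis=0
                    ).clip(min=0.0)
                cache[key] = vals
            vals = cache[key]
            rts = np.array([o.rt for o in occ])
            row = np.empty(len(frags))
            for j in range(len(frags)):
                row[j] = np.interp(rt_c, rts, vals[:, j])
            Yrows[i] = row
        Y = Yrows
    else:
        Y = raw
    Y = np.vstack([Y, np.zeros(len(frags))])  # regularization target
    lam = _default_lambda(Y)
    regions = scheme.regions()
    X = build_design_matrix(
        scheme, [(s.scan_index, s.isolation) for s in spectra], lam, regions
    )
    return DesignSystem(
        X=X, Y=Y, scan_indices=list(scan_ids),
        region_indices=[r.index for r in regions],
        center_scan=center_scan, lam=lam, truncated=truncated,
    )


build_system = assemble_observed  # convenience alias


def nnls_solve(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise Lawson–Hanson NNLS: each column of A minimizes
    ``||X a - y||_2`` subject to ``a >= 0``."""
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise DemuxError("non-finite values in NNLS inputs")
    A = np.empty((X.shape[1], Y.shape[1]))
    for j in range(Y.shape[1]):
        A[:, j], _ = scipy.optimize.nnls(X, Y[:, j])
    return A


def nnls_solve_banded(
    X: np.ndarray, Y: np.ndarray, block_halfwidth: int = 2
) -> np.ndarray:
    """Approximate NNLS exploiting the near-diagonal structure of ``X``.

    For each region *r*, a small sub-problem over regions
    ``r - block_halfwidth .. r + block_halfwidth`` is solved using only the
    scan rows touching the block, and the center region's solution is kept.
    Scan rows and the regularization row couple each block to the rest of
    the system, so the solve iterates Gauss–Seidel style: an initial sweep
    uses only rows whose coverage lies wholly inside each block (with a
    zero regularization target); subsequent sweeps use every row touching
    the block, subtracting the freshest estimate of the out-of-block
    regions from the observations, until the solution stabilizes.  Exact in
    the full-matrix limit ``block_halfwidth >= n_regions``.
    """
    if block_halfwidth < 1:
        raise DemuxError(f"block_halfwidth must be >= 1, got {block_halfwidth}")
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    n_regions = X.shape[1]
    if block_halfwidth >= n_regions:
        return nnls_solve(X, Y)
    scan_rows = X[:-1]
    reg_row = X[-1]
    support = [np.flatnonzero(scan_rows[i]) for i in range(scan_rows.shape[0])]

    blocks = []
    for r in range(n_regions):
        lo = max(0, r - block_halfwidth)
        hi = min(n_regions, r + block_halfwidth + 1)
        inside = np.array(
            [i for i, sup in enumerate(support)
             if sup.size and sup[0] >= lo and sup[-1] < hi],
            dtype=int,
        )
        touching = np.array(
            [i for i, sup in enumerate(support)
             if sup.size and sup[0] < hi and sup[-1] >= lo],
            dtype=int,
        )
        blocks.append((lo, hi, inside, touching))

    A = np.zeros((n_regions, Y.shape[1]))
    for r, (lo, hi, inside, _) in enumerate(blocks):
        cols = np.arange(lo, hi)
        Xb = np.vstack([scan_rows[inside][:, cols], reg_row[cols]])
        Yb = np.vstack([Y[inside], np.zeros(Y.shape[1])])
        A[r] = nnls_solve(Xb, Yb)[r - lo]

    max_sweeps, tol = 60, 1e-10
    for _ in range(max_sweeps):
        delta = 0.0
        for r, (lo, hi, _, touching) in enumerate(blocks):
            cols = np.arange(lo, hi)
            outside = A.copy()
            outside[lo:hi] = 0.0
            Yrows = Y[touching] - scan_rows[touching] @ outside
            reg_target = Y[-1] - reg_row @ outside
            Xb = np.vstack([scan_rows[touching][:, cols], reg_row[cols]])
            Yb = np.vstack([Yrows, reg_target])
            new = nnls_solve(Xb, Yb)[r - lo]
            delta = max(delta, float(np.abs(new - A[r]).max()))
            A[r] = new
        if delta <= tol * max(1.0, float(np.abs(A).max())):
            break
    return A


@dataclass
class ScanDemuxResult:
    """Per-region fragment intensities for one demultiplexed MS2 scan."""

    scan_index: int
    rt: float
    window: IsolationWindow
    region_indices: list[int]            # regions covered by the window
    intensities: np.ndarray              # len(region_indices) x m, conserved
    observed: np.ndarray                 # m raw center-scan intensities
    truncated: bool


def demultiplex_scan(
    run: Run,
    scan_index: int,
    query: TransitionQuery,
    scheme: Optional[IsolationScheme] = None,
    interpolate: bool = True,
    smooth: bool = False,
    solver: str = "full",
    block_halfwidth: int = 2,
    lam: Optional[float] = None,
) -> ScanDemuxResult:
    """Assign each fragment's observed intensity in one scan to the regions
    of its isolation window, proportionally to the solved region shares.

    Conservation holds by construction: over the window's regions, the
    demultiplexed intensities of a fragment sum to the raw observed
    intensity whenever any solved share exists (zero shares yield zeros).
    """
    scheme = scheme or run.scheme
    system = assemble_observed(run, scan_index, query, scheme,
                               interpolate=interpolate, smooth=smooth)
    if lam is not None:
        system.X[-1, :] = lam
        system.lam = lam
    if solver == "full":
        A = nnls_solve(system.X, system.Y)
    elif solver == "banded":
        A = nnls_solve_banded(system.X, system.Y, block_halfwidth)
    else:
        raise DemuxError(f"unknown solver {solver!r}")
    system.A = A

    center = run.by_index(scan_index)
    regions = scheme.regions()
    covered = sorted(regions_in_window(center.isolation, regions))
    observed = np.array(
        [center.intensity_near(mz, query.mz_tolerance)
         for mz in query.fragment_mzs]
    )
    shares = A[np.array(covered, dtype=int), :]        # k x m
    totals = shares.sum(axis=0)
    out = np.zeros_like(shares)
    nz = totals > 0
    out[:, nz] = shares[:, nz] / totals[nz] * observed[nz]
    return ScanDemuxResult(
        scan_index=scan_index, rt=center.rt, window=center.isolation,
        region_indices=covered, intensities=out, observed=observed,
        truncated=system.truncated,
    )


def demultiplex_run(
    run: Run,
    queries: Optional[Sequence[TransitionQuery]] = None,
    scheme: Optional[IsolationScheme] = None,
    interpolate: bool = True,
    smooth: bool = False,
    solver: str = "full",
    block_halfwidth: int = 2,
    rt_range: Optional[tuple[float, float]] = None,
):
    """Demultiplex a whole run.

    Transition mode (``queries`` given) returns, per query, per-fragment
    demultiplexed chromatograms restricted to the query's precursor region
    (optionally limited to ``rt_range`` minutes).
    Full-spectrum mode (``queries=None``) replaces each MS2 scan by one
    pseudo-scan per covered region, whose isolation metadata equals the
    region bounds — suitable for :func:`diademux.spectra_io.write_run`.
    """
    from .chrom import Chromatogram  # local import: chrom is downstream

    scheme = scheme or run.scheme
    if scheme is None:
        raise DemuxError("run has no isolation scheme attached")
    regions = scheme.regions()

    if queries is not None:
        results: dict[str, dict[float, Chromatogram]] = {}
        for q in queries:
            target = region_of(q.precursor_mz, regions)
            rts: list[float] = []
            traces: list[np.ndarray] = []
            for s in run.spectra:
                if s.ms_level != 2 or not s.isolation.contains(q.precursor_mz):
                    continue
                if rt_range is not None and not (
                    rt_range[0] <= s.rt <= rt_range[1]
                ):
                    continue
                try:
                    res = demultiplex_scan(
                        run, s.scan_index, q, scheme, interpolate=interpolate,
                        smooth=smooth, solver=solver,
                        block_halfwidth=block_halfwidth,
                    )
                except DemuxError:
                    continue  # run edge: not even one full cycle available
                k = res.region_indices.index(target.index)
                rts.append(s.rt)
                traces.append(res.intensities[k])
            arr = (np.array(traces) if traces
                   else np.zeros((0, len(q.fragment_mzs))))
            results[q.peptide_id] = {
                mz: Chromatogram(
                    rt=np.array(rts), intensity=arr[:, j],
                    label=(q.peptide_id, mz), demuxed=True,
                )
                for j, mz in enumerate(q.fragment_mzs)
            }
        return results

    # Full-spectrum mode: every center-scan peak is its own fragment column.
    out_spectra: list[Spectrum] = []
    next_index = 0
    for s in run.spectra:
        if s.ms_level != 2:
            out_spectra.append(
                Spectrum(next_index, s.rt, s.ms_level, None,
                         s.mz.copy(), s.intensity.copy())
            )
            next_index += 1
            continue
        if s.mz.size == 0:
            continue
        q = TransitionQuery("__full__", s.isolation.center,
                            tuple(s.mz.tolist()),
                            mz_tolerance=DEFAULT_MZ_TOLERANCE / 2)
        try:
            res = demultiplex_scan(
                run, s.scan_index, q, scheme, interpolate=interpolate,
                smooth=smooth, solver=solver, block_halfwidth=block_halfwidth,
            )
        except DemuxError:
            continue  # truncated edge scan without a full cycle
        for k, r_idx in enumerate(res.region_indices):
            region = regions[r_idx]
            keep = res.intensities[k] > 0
            out_spectra.append(
                Spectrum(next_index, s.rt, 2,
                         IsolationWindow(region.low, region.high),
                         s.mz[keep], res.intensities[k][keep])
            )
            next_index += 1
    return Run(out_spectra, scheme)
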