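# Methods

## The demultiplexing model

Overlapped DIA acquires a repeating pair of cycle variants: a pass of
non-overlapping isolation windows (by default twenty 20 Th windows covering
500–900 Th) followed by the same pass shifted by −10 Th (490–890 Th).  The
shifted edges cut the covered range into *demultiplexing regions* — the
smallest intervals to which fragment signal can be assigned from the window
pattern.  The default scheme induces 41 regions of 10 Th from 490 to
900 Th; every window is the union of exactly two regions.  All intervals
are half-open `[low, high)` so a boundary m/z belongs to exactly one
window and one region.

For a center MS2 scan *s*, the surrounding MS2 scans — one full pass of
every variant, i.e. scans *s*−20 … *s*+19 for the default scheme, counting
MS2 scans only — define the linear system `X A = Y`:

* `X` (scans+1 × regions): scan row *i* holds a 1 at every region covered
  by that scan's isolation window, 0 elsewhere; the final row is a
  regularization row of constant λ.  For the default scheme `X` is the
  square 41 × 41 system with two 1s per scan row.
* `Y` (scans+1 × fragments): observed fragment intensities per scan
  (summed peak intensity within the m/z tolerance, default 0.02 Th); the
  regularization target is 0.
* `A` (regions × fragments): non-negative region intensities, solved per
  fragment column by the Lawson–Hanson active-set algorithm
  (`scipy.optimize.nnls`).

Solved region shares are **reallocated proportionally**: the observed
center-scan intensity of each fragment is split over its window's regions
in the ratio of the solved `A` entries.  This conserves per-scan ion
counts exactly (the conservation invariant) and reduces sensitivity of the
output to the absolute scale of the solve.  When all shares of a fragment
are zero the output is zero, never NaN.

### Regularization

The 40 scan rows of the default scheme span only a 40-dimensional space:
they are the consecutive-pair indicators `e_r + e_{r+1}`, whose null space
is the alternating-sign vector.  The constant-λ row with a zero target
resolves this by shrinking the solution along that direction until a
region hits the non-negativity bound.  With realistic occupancy — a
fragment originates from one region, most regions carry ~zero — the shrink
is nil.  λ defaults to `1e-3 ×` the median nonzero observed intensity:
large enough to pick a unique solution, ~six orders below the signal so it
does not bias large components.  Both λ and the target convention are
configurable.

### Elution-shape interpolation

The system assumes every scan row reads the *same* region intensity, but
adjacent-cycle scans sample different points of the elution profile.  Each
`Y` entry is therefore linearly interpolated between occurrences of that
scan's window in neighbouring cycles to the retention time of the center
scan (optionally after 5-point Savitzky–Golay smoothing of each window's
time series; off by default).  Interpolation is exact for locally linear
profiles — a constant signal is a fixed point, and a linear ramp
interpolates to the ramp value at the center RT.  The residual error is
the curvature term `~(Δt/σ)²/8` per same-window sampling interval Δt,
which for the default cadence (Δt = 5 s) and σ ≥ 0.15 min is a few
percent at the apex.  Disabling interpolation demonstrably increases the
reconstruction error on Gaussian peaks (regression-tested).

### Banded approximate solver

`X` is near-diagonal, so the full solve can be approximated with sliding
blocks: for each region *r* the sub-problem over regions
`r ± block_halfwidth` (default 2, i.e. 5-region blocks) is solved and the
center region kept.  Both the scan rows crossing a block boundary and the
regularization row couple blocks together, so the solver iterates
Gauss–Seidel style: an initial sweep uses only scan rows wholly inside
each block with a zero regularization target; subsequent sweeps use all
rows touching the block with the freshest out-of-block estimates
subtracted, until the largest change falls below 1e-10 of the solution
scale (usually 3–5 sweeps, capped at 60).  On noiseless sparse systems the
result agrees with the full solver to better than 1e-4 relative; with
`block_halfwidth ≥ n_regions` the two are identical by construction.

### Run edges

Where fewer than two full cycles surround the center scan the system is
truncated to the available scans (matching rows removed from `X`) and the
result flagged; scans without at least one full cycle are skipped.
Zero-padding is deliberately avoided — a missing scan is absence of
evidence, not evidence of zero intensity.

## Chromatograms and quantification

Extracted ion chromatograms carry one point per MS2 scan whose isolation
covers the precursor filter; intensity is the summed peak intensity within
±0.02 Th (configurable, ppm mode available; the extraction tolerance is an
implementation choice).  The selectivity metric is the trapezoidal
integral over the full run summed over fragments, with no background
subtraction — lower totals mean less co-isolated signal.

Peak integration is trapezoidal between fixed boundaries.  Boundary
refinement follows the fixed-width local-search rule: candidate centers
are the actual scan RTs within ±0.1 min of the seed; the winner minimizes
the sum of squared differences between the unit-sum fragment-intensity
vector at that RT and a unit-sum reference spectrum (unit-sum scaling
makes the fit scale-free as abundance falls; ties break toward the seed).
The returned boundaries have exactly the requested width.  RT alignment
across runs is a weighted smoothing spline over anchor pairs (weights
default to 1 and are user-suppliable — the weighting scheme is an open
design choice), with a monotonicity check and a weighted-linear fallback.

Peptide-level areas sum the top-N (default 5) library-ranked fragments.
MS1 quantification sums the integrated M, M+1, M+2 isotope chromatograms
with spacing 1.00335/charge Th.

Normalization and calibration statistics follow the printed formulas:
`N_i = Σ_k Area_{i,k}`, `TNI_a = max N_i` within a workflow,
`NF_i = TNI_a / N_i`; `D = ½(96/mean(I₉₆) + 32/mean(I₃₂))` (the
concentration pair is configurable for synthetic series);
`bias = |log2(D·I/C)|`; CV is the sample standard deviation over the mean.
The LLoQ rule is deliberately simple and deterministic: the lowest
concentration at which CV ≤ 0.2 and bias ≤ 1 log2 hold there and at every
higher concentration, aggregated across peptides by geometric mean.  This
replaces curve-shape mixed-model estimators (e.g. MSStats' LoQ) with a
transparent rule; no numerical equivalence with such estimators is
claimed, only the same qualitative ordering between workflows.  Bias and
CV comparisons across workflows are made only above each peptide's
largest per-workflow LLoQ.  Manual curation of normalization peptides is
replaced by an automatic filter (top-K by summed intensity, drop
cross-run CV > 0.5).

## The simulator

`simulate` generates the test bed for every claim above: peptides elute as
area-normalized Gaussians (`total_abundance × N(apex, σ)`, so true peak
area equals total abundance), fragments carry fixed relative shares, and
scans follow the scheme's cadence — 2.5 s per 20-scan cycle, an MS1 survey
scan every 10 MS2 scans, variants alternating per cycle.  Interference
studies place a second species in the opposite 10 Th half of a shared
20 Th window; its non-demultiplexed signature is the characteristic
every-other-cycle "spiky" trace.  Noise is additive Gaussian per tracked
fragment peak (chemical-noise floor, clipped at zero) plus a mean-one
log-normal factor per scan; the dilution series adds an optional per-run
global intensity factor to exercise normalization.  The truth ledger
(per scan × region × fragment, noise-free, plus true areas) is emitted
alongside every run.

Default study conditions used by the tests and benchmark script: target
at 505 Th and interferent at 512 Th (shared [500,520) window, opposite
halves), σ = 0.15–0.2 min (≥ 3 cycle durations), apexes 1.2–2.2 min,
3–3.5 min runs; the dilution series spans 16…0.5 fmol in 2× steps with 2
replicates, 100 intensity units/fmol, and a constant co-eluting 200-unit
interferent.  These short runs keep the full suite desk-scale while
preserving ≥ 40 scans per elution peak.  The interferent offset makes the
non-demultiplexed bias rule cross 1 log2 between 0.5 and 1 fmol — a
closed-form designed LLoQ of 1 fmol — while the demultiplexed series
qualifies at the lowest simulated amount.

What the simulator does *not* model: realistic fragmentation or retention
time prediction, profile-mode peaks (spectra are centroided), detector
saturation/AGC, quadrupole isolation-efficiency non-uniformity across a
window, and chemical backgrounds at m/z other than the tracked fragments.
Passing tests therefore demonstrate the mathematical correctness of the
demultiplexing and quantification machinery under the stated model, not
instrument-level performance.

## Numerical choices and edge cases

* Window edges are compared after rounding to 1e-6 Th; isolation metadata
  matches scheme windows within 0.01 Th.
* Cycle-variant assignment is a pure function of isolation metadata,
  never scan parity, so dropped scans cannot shift labels.
* Degenerate inputs: empty m/z range, non-divisor offsets, |offset| ≥
  width, MS2 spectra without isolation metadata, decreasing RT, negative
  intensities and n < 2 replicates are all rejected with specific errors;
  unsorted peak lists are sorted with a warning.
* The optional window-edge adjustment hook (shifting edges toward
  user-defined sparse m/z points) is off by default and its placement rule
  is a placeholder, not a reproduction of any published optimizer.

## Known limitations

* The banded solver is an iterative approximation; pathological region
  patterns (several active regions of equal parity packed within one
  block) converge more slowly and are only guaranteed to the 1e-3
  tolerance verified in tests.
* Full-spectrum demultiplexing treats every center-scan peak as its own
  fragment column and is quadratic-ish in peak count; it is intended for
  the simulator's sparse spectra, not dense real-world runs.
* mzML support covers the common subset emitted and consumed here
  (centroided spectra, 32/64-bit zlib or uncompressed arrays, standard
  isolation-window CV terms); vendor formats, ion mobility and
  chromatogram-indexed mzML are out of scope.
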