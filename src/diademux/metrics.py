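"""Label-free quantification statistics.

Run-to-run normalization: for run *i* the total normalization intensity is
``N_i = sum_k Area_{i,k}`` over normalization peptides *k*; within each
analytical workflow *a* the top normalization intensity is
``TNI_a = max_i N_i``, the per-run factor ``NF_i = TNI_a / N_i`` and
``NormalizedArea_{i,k} = NF_i * Area_{i,k}``.

Calibration against a dilution series uses the top two spike-in amounts
(96 and 32 fmol by default):
``D = 1/2 * (96 / mean(I_96) + 32 / mean(I_32))`` (fmol per intensity
unit), ``bias at C = |log2(D * I / C)|`` and the coefficient of variation
is the sample standard deviation over the mean across replicates.

The lower limit of quantification (LLoQ) is the lowest spike-in
concentration at which CV <= ``cv_max`` and bias <= ``bias_max`` hold there
and at every higher concentration (a simple deterministic rule standing in
for curve-shape models); the aggregate across peptides is the geometric
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationSet",
    "CalibrationSeries",
    "normalization_factors",
    "select_normalization_peptides",
    "calibration_factor",
    "bias",
    "cv_of_replicates",
    "estimate_lloq",
    "aggregate_lloq",
]


@dataclass
class NormalizationSet:
    N: pd.Series                 # per-run summed normalization area N_i
    TNI: pd.Series               # per-workflow top normalization intensity
    NF: pd.Series                # per-run factor TNI_a / N_i
    workflow: pd.Series          # workflow label a per run
    normalized_areas: pd.DataFrame


@dataclass
class CalibrationSeries:
    """Replicate intensities per concentration for one peptide."""

    concentrations: tuple[float, ...]            # fmol, descending
    intensities: Mapping[float, Sequence[float]]  # conc -> replicate I
    calibration_concentrations: tuple[float, float] = (96.0, 32.0)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if list(self.concentrations) != sorted(self.concentrations,
                                               reverse=True):
            raise ValueError("concentrations must be sorted descending")

    def factor(self) -> float:
        c_hi, c_lo = self.calibration_concentrations
        return calibration_factor(
            self.intensities[c_hi], self.intensities[c_lo], c_hi, c_lo
        )


def normalization_factors(
    areas: pd.DataFrame, workflows: Mapping[str, str] | pd.Series
) -> NormalizationSet:
    """Per-run normalization from a run x peptide area table.

    ``workflows`` labels each run (index of *areas*) with its analytical
    workflow; the maximum N_i is taken within workflows, never across.
    """
    areas = areas.astype(float)
    wf = pd.Series(workflows).reindex(areas.index)
    if wf.isna().any():
        raise ValueError(
            f"runs without workflow label: {list(areas.index[wf.isna()])}"
        )
    N = areas.sum(axis=1)
    zero = N[N == 0]
    if len(zero):
        raise ValueError(
            f"zero total normalization intensity in run(s) {list(zero.index)}"
        )
    TNI = N.groupby(wf).max()
    NF = pd.Series(TNI[wf].to_numpy(), index=N.index) / N
    normalized = areas.mul(NF, axis=0)
    return NormalizationSet(N=N, TNI=TNI, NF=NF, workflow=wf,
                            normalized_areas=normalized)


def select_normalization_peptides(
    areas: pd.DataFrame, top_k: int = 100, cv_max: float = 0.5
) -> list:
    """Automatic normalization-peptide filter: keep the *top_k* peptides by
    total intensity, then drop those whose cross-run CV exceeds *cv_max*."""
    totals = areas.sum(axis=0).sort_values(ascending=False)
    keep = list(totals.index[:top_k])
    out = []
    for pep in keep:
        col = areas[pep].to_numpy(dtype=float)
        if len(col) < 2 or col.mean() <= 0:
            continue
        if col.std(ddof=1) / col.mean() <= cv_max:
            out.append(pep)
    return out


def calibration_factor(
    I_hi: Sequence[float], I_lo: Sequence[float],
    c_hi: float = 96.0, c_lo: float = 32.0,
) -> float:
    """``D = 1/2 * (c_hi/mean(I_hi) + c_lo/mean(I_lo))`` in fmol per
    intensity unit."""
    m_hi, m_lo = float(np.mean(I_hi)), float(np.mean(I_lo))
    if m_hi <= 0 or m_lo <= 0:
        raise ValueError("calibration intensities must have positive means")
    return 0.5 * (c_hi / m_hi + c_lo / m_lo)


def bias(I: float, C: float, D: float) -> float:
    """``|log2((D * I) / C)|`` — absolute log2 fold change between measured
    (D*I) and true concentration."""
    if I <= 0 or C <= 0 or D <= 0:
        raise ValueError("bias requires positive intensity, concentration "
                         "and calibration factor")
    return abs(math.log2(D * I / C))


def cv_of_replicates(intensities: Sequence[float]) -> float:
    """Sample standard deviation over the mean across replicates."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 replicates")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(x.std(ddof=1) / mean)


def estimate_lloq(
    series: CalibrationSeries,
    cv_max: float = 0.2,
    bias_max: float = 1.0,
    D: Optional[float] = None,
) -> float:
    """Lowest concentration at which CV <= cv_max and bias <= bias_max hold
    there and at all higher concentrations; ``inf`` if none qualifies.

    Bias at each concentration is computed from the mean replicate
    intensity with the series' calibration factor (or a supplied *D*).
    """
    if len(series.concentrations) < 3:
        raise ValueError("LLoQ estimation needs >= 3 concentrations")
    if D is None:
        D = series.factor()
    lloq = math.inf
    for c in series.concentrations:  # descending
        reps = np.asarray(series.intensities[c], dtype=float)
        mean = reps.mean()
        ok = (
            mean > 0
            and cv_of_replicates(reps) <= cv_max
            and bias(mean, c, D) <= bias_max
        )
        if ok:
            lloq = c
        else:
            break  # must hold at this and all higher concentrations
    return lloq


def aggregate_lloq(lloqs: Sequence[float]) -> float:
    """Geometric-mean LLoQ across peptides (LLoQ varies over orders of
    magnitude); ``inf`` if any peptide never qualifies."""
    vals = np.asarray(lloqs, dtype=float)
    if vals.size == 0:
        raise ValueError("no LLoQ values to aggregate")
    if np.any(~np.isfinite(vals)):
        return math.inf
    return float(np.exp(np.mean(np.log(vals))))
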