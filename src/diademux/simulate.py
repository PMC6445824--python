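"""Synthetic DIA run generator with ground truth.

Emulates the spike-in study geometry: peptides elute as Gaussian profiles
at known total abundances; MS2 scans step through the isolation scheme's
windows, alternating cycle variants (default cadence: a 2.5-s cycle of 20
MS2 scans, one MS1 survey scan interleaved every 10 MS2 scans); a peptide
contributes its fragments to every MS2 scan whose window contains its
precursor m/z.  Interference studies place a second species in the
opposite half of a shared 20 Th window.  A noise-free truth ledger records
every (scan, region, fragment) intensity and per-peptide areas, so
demultiplexing and quantification claims can be checked against ground
truth.

The elution profile is ``total_abundance x NormalPDF(rt; apex, sigma)``, so
a peptide's true integrated area (intensity x min) equals its total
abundance.  Noise, both off by default magnitudes given per call:
additive Gaussian on every tracked fragment peak (chemical-noise floor,
clipped at zero) and a per-scan multiplicative log-normal factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .scheme import IsolationScheme, SchemeError, region_of
from .spectra_io import Run, Spectrum

__all__ = ["SimPeptide", "SimTruth", "simulate_run",
           "simulate_dilution_series", "DilutionRun"]

NEUTRON_MASS = 1.00335
DEFAULT_ISOTOPE_SHARES = (0.6, 0.3, 0.1)


@dataclass(frozen=True)
class SimPeptide:
    """Ground-truth peptide: Gaussian elution, fixed fragment shares."""

    peptide_id: str
    precursor_mz: float
    apex_rt: float
    elution_sigma: float
    total_abundance: float
    fragments: tuple[tuple[float, float], ...]  # (m/z, relative share)
    charge: int = 2
    isotope_shares: tuple[float, float, float] = DEFAULT_ISOTOPE_SHARES

    def __post_init__(self) -> None:
        if self.elution_sigma <= 0:
            raise ValueError(f"{self.peptide_id}: elution_sigma must be > 0")
        total = sum(f for _, f in self.fragments)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(
                f"{self.peptide_id}: fragment shares sum to {total}, not 1"
            )

    def profile(self, rt: float) -> float:
        """Noise-free total intensity at *rt* (area-normalized Gaussian)."""
        z = (rt - self.apex_rt) / self.elution_sigma
        return (self.total_abundance
                / (self.elution_sigma * math.sqrt(2 * math.pi))
                * math.exp(-0.5 * z * z))


@dataclass
class SimTruth:
    """Noise-free ledger emitted alongside a simulated run."""

    # (scan_index, region_index, fragment m/z rounded to 4 dp) -> intensity
    scan_region_fragment: dict[tuple[int, int, float], float]
    peptide_areas: dict[str, float]                   # total abundance
    fragment_areas: dict[tuple[str, float], float]    # per-fragment area
    peptide_regions: dict[str, int]                   # precursor region index

    def intensity(self, scan_index: int, region_index: int,
                  fragment_mz: float) -> float:
        key = (scan_index, region_index, round(fragment_mz, 4))
        return self.scan_region_fragment.get(key, 0.0)

    def true_trace(self, run: Run, peptide_id: str, fragment_mz: float,
                   scan_indices: Sequence[int]) -> np.ndarray:
        """True fragment intensities of a peptide at the given scans."""
        r = self.peptide_regions[peptide_id]
        return np.array(
            [self.intensity(i, r, fragment_mz) for i in scan_indices]
        )


def simulate_run(
    peptides: Sequence[SimPeptide],
    scheme: IsolationScheme,
    run_length: float = 3.5,
    cycle_time: float = 2.5,
    noise: Optional[dict] = None,
    ms1_every: int = 10,
    seed: int = 0,
) -> tuple[Run, SimTruth]:
    """Simulate one DIA run.

    ``run_length`` is in minutes, ``cycle_time`` in seconds (per variant
    pass).  ``noise`` keys: ``additive_sigma`` (Gaussian floor added to
    every tracked fragment peak in covering scans) and
    ``multiplicative_cv`` (per-scan log-normal factor); both default 0.
    An MS1 survey scan (M/M+1/M+2 isotope envelope) is inserted every
    ``ms1_every`` MS2 scans.
    """
    noise = noise or {}
    add_sigma = float(noise.get("additive_sigma", 0.0))
    mult_cv = float(noise.get("multiplicative_cv", 0.0))
    rng = np.random.default_rng(seed)
    regions = scheme.regions()
    for p in peptides:
        if not (scheme.range_low + min(0.0, scheme.offset * (scheme.n_variants - 1))
                <= p.precursor_mz):
            raise SchemeError(f"{p.peptide_id}: precursor below scheme range")
        region_of(p.precursor_mz, regions)  # raises if outside coverage

    sigma_log = math.sqrt(math.log1p(mult_cv ** 2)) if mult_cv > 0 else 0.0
    dt_min = cycle_time / scheme.windows_per_variant / 60.0

    spectra: list[Spectrum] = []
    ledger: dict[tuple[int, int, float], float] = {}
    pep_region = {p.peptide_id: region_of(p.precursor_mz, regions).index
                  for p in peptides}

    t = 0.0
    scan_index = 0
    ms2_count = 0
    cycle = 0
    while t < run_length:
        variant = scheme.variants[cycle % scheme.n_variants]
        for window in variant.windows:
            if t >= run_length:
                break
            if ms1_every and ms2_count % ms1_every == 0:
                spectra.append(_ms1_spectrum(scan_index, t, peptides, rng,
                                             sigma_log))
                scan_index += 1
                t += dt_min
            peaks: dict[float, float] = {}
            scan_factor = (math.exp(rng.normal(-0.5 * sigma_log ** 2,
                                               sigma_log))
                           if sigma_log else 1.0)
            for p in peptides:
                if not window.contains(p.precursor_mz):
                    continue
                signal = p.profile(t)
                for fmz, share in p.fragments:
                    true_val = signal * share
                    key = (scan_index, pep_region[p.peptide_id],
                           round(fmz, 4))
                    ledger[key] = ledger.get(key, 0.0) + true_val
                    observed = true_val * scan_factor
                    if add_sigma:
                        observed += rng.normal(0.0, add_sigma)
                    peaks[round(fmz, 6)] = max(
                        0.0, peaks.get(round(fmz, 6), 0.0) + observed
                    )
            mzs = np.array(sorted(peaks))
            spectra.append(
                Spectrum(scan_index, t, 2, window, mzs,
                         np.array([peaks[m] for m in mzs]))
            )
            scan_index += 1
            ms2_count += 1
            t += dt_min
        cycle += 1

    truth = SimTruth(
        scan_region_fragment=ledger,
        peptide_areas={p.peptide_id: p.total_abundance for p in peptides},
        fragment_areas={(p.peptide_id, round(fmz, 4)): p.total_abundance * s
                        for p in peptides for fmz, s in p.fragments},
        peptide_regions=pep_region,
    )
    return Run(spectra, scheme), truth


def _ms1_spectrum(scan_index: int, rt: float, peptides: Sequence[SimPeptide],
                  rng: np.random.Generator, sigma_log: float) -> Spectrum:
    peaks: dict[float, float] = {}
    factor = (math.exp(rng.normal(-0.5 * sigma_log ** 2, sigma_log))
              if sigma_log else 1.0)
    for p in peptides:
        signal = p.profile(rt) * factor
        for k, share in enumerate(p.isotope_shares):
            mz = round(p.precursor_mz + k * NEUTRON_MASS / p.charge, 6)
            peaks[mz] = peaks.get(mz, 0.0) + signal * share
    mzs = np.array(sorted(peaks))
    return Spectrum(scan_index, rt, 1, None, mzs,
                    np.array([peaks[m] for m in mzs]))


@dataclass
class DilutionRun:
    """One replicate run of a spike-in dilution series."""

    concentration: float
    replicate: int
    run_factor: float
    run: Run
    truth: SimTruth


def simulate_dilution_series(
    template_peptides: Sequence[SimPeptide],
    concentrations: Sequence[float],
    scheme: IsolationScheme,
    background_peptides: Sequence[SimPeptide] = (),
    replicates: int = 3,
    abundance_per_fmol: float = 100.0,
    run_factor_cv: float = 0.0,
    run_factors: Optional[Sequence[float]] = None,
    noise: Optional[dict] = None,
    run_length: float = 3.5,
    cycle_time: float = 2.5,
    ms1_every: int = 10,
    seed: int = 0,
) -> list[DilutionRun]:
    """Spike-in dilution series: template peptides scale linearly with
    concentration (``abundance_per_fmol`` units per fmol), background
    peptides stay constant, and an optional per-run global intensity factor
    exercises normalization: either log-normal with CV ``run_factor_cv`` or
    the explicit ``run_factors`` sequence (consumed in run order).
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("empty concentration series")
    if concentrations != sorted(concentrations, reverse=True):
        raise ValueError("concentrations must be sorted descending")
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    out: list[DilutionRun] = []
    run_no = 0
    for conc in concentrations:
        for rep in range(replicates):
            run_seed = int(rng.integers(0, 2 ** 31 - 1))
            if run_factors is not None:
                factor = float(run_factors[run_no % len(run_factors)])
            elif run_factor_cv > 0:
                s = math.sqrt(math.log1p(run_factor_cv ** 2))
                factor = float(np.exp(rng.normal(-0.5 * s * s, s)))
            else:
                factor = 1.0
            peptides = [
                SimPeptide(
                    p.peptide_id, p.precursor_mz, p.apex_rt, p.elution_sigma,
                    conc * abundance_per_fmol * factor, p.fragments,
                    p.charge, p.isotope_shares,
                )
                for p in template_peptides
            ] + [
                SimPeptide(
                    b.peptide_id, b.precursor_mz, b.apex_rt, b.elution_sigma,
                    b.total_abundance * factor, b.fragments, b.charge,
                    b.isotope_shares,
                )
                for b in background_peptides
            ]
            run, truth = simulate_run(
                peptides, scheme, run_length=run_length,
                cycle_time=cycle_time, noise=noise, ms1_every=ms1_every,
                seed=run_seed,
            )
            out.append(DilutionRun(conc, rep, factor, run, truth))
            run_no += 1
    return out
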