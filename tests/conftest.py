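"""Shared fixtures: schemes and small simulated runs (built once per session)."""

from __future__ import annotations

import numpy as np
import pytest

import diademux as dx
from diademux.demux import TransitionQuery

FRAGMENTS = ((600.1, 0.5), (700.2, 0.3), (800.3, 0.2))
FRAGMENT_MZS = tuple(mz for mz, _ in FRAGMENTS)


@pytest.fixture(scope="session")
def default_scheme():
    """Two alternating cycles of twenty 20 Th windows, 500-900 / 490-890."""
    return dx.build_overlap_scheme(500, 900, 20, -10)


@pytest.fixture(scope="session")
def no_overlap_scheme():
    return dx.build_overlap_scheme(500, 900, 20, 0)


@pytest.fixture(scope="session")
def target_query():
    return TransitionQuery("T", 505.0, FRAGMENT_MZS)


@pytest.fixture(scope="session")
def interference_sim(default_scheme):
    """Target at 505 Th and a 2x-abundant interferent at 512 Th sharing the
    [500,520) window but sitting in opposite 10 Th halves; shared fragment
    m/z values, shifted elution apexes, noiseless."""
    target = dx.SimPeptide("T", 505.0, 1.2, 0.2, 1000.0, FRAGMENTS)
    interf = dx.SimPeptide("I", 512.0, 2.2, 0.2, 2000.0, FRAGMENTS)
    run, truth = dx.simulate_run(
        [target, interf], default_scheme, run_length=3.5, seed=1
    )
    return run, truth


@pytest.fixture(scope="session")
def single_peptide_sim(default_scheme):
    """One noiseless peptide in the overlapped scheme."""
    pep = dx.SimPeptide("T", 505.0, 1.2, 0.2, 1000.0, FRAGMENTS)
    run, truth = dx.simulate_run([pep], default_scheme, run_length=2.4,
                                 seed=7)
    return run, truth


def scan_lookup(run):
    """Map retention time -> scan index (unique in simulated runs)."""
    return {s.rt: s.scan_index for s in run.spectra}
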