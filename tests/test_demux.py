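"""The XA=Y demultiplexing system: design matrix, NNLS solvers, reallocation."""

import itertools

import numpy as np
import pytest

import diademux as dx
from diademux.demux import (DemuxError, TransitionQuery, assemble_observed,
                            build_design_matrix, demultiplex_run,
                            demultiplex_scan, nnls_solve, nnls_solve_banded)
from diademux.scheme import build_overlap_scheme
from diademux.spectra_io import Run, Spectrum

from conftest import FRAGMENT_MZS, FRAGMENTS, scan_lookup


def brute_force_nnls(X, y):
    """Exhaustive active-set oracle: at the NNLS optimum the positive
    variables solve the unconstrained least-squares problem on their
    support, so enumerating all supports and keeping the best feasible
    candidate finds the global optimum (tractable for <= 4 columns)."""
    n = X.shape[1]
    best, best_res = np.zeros(n), float(np.linalg.norm(y))
    for k in range(1, n + 1):
        for supp in itertools.combinations(range(n), k):
            sol, *_ = np.linalg.lstsq(X[:, supp], y, rcond=None)
            if np.any(sol < -1e-10):
                continue
            a = np.zeros(n)
            a[list(supp)] = np.clip(sol, 0, None)
            res = float(np.linalg.norm(X @ a - y))
            if res < best_res - 1e-12:
                best, best_res = a, res
    return best


def default_system_matrix(scheme, lam=1e-3):
    wins = [(i, w) for i, w in
            enumerate(scheme.variants[0].windows + scheme.variants[1].windows)]
    return build_design_matrix(scheme, wins, lam, scheme.regions())


class TestDesignMatrix:
    def test_default_scheme_gives_square_41_system(self, default_scheme):
        X = default_system_matrix(default_scheme)
        assert X.shape == (41, 41)
        np.testing.assert_array_equal(X[:-1].sum(axis=1), np.full(40, 2.0))
        assert set(np.unique(X[:-1])) == {0.0, 1.0}
        np.testing.assert_allclose(X[-1], 1e-3)

    def test_toy_two_window_rows(self):
        s = build_overlap_scheme(0, 2, 2, -1)
        X = build_design_matrix(
            s, [(0, dx.IsolationWindow(0, 2)), (1, dx.IsolationWindow(-1, 1))],
            0.5,
        )
        # regions [-1,0),[0,1),[1,2): window [0,2) covers the upper two,
        # window [-1,1) the lower two
        np.testing.assert_array_equal(X[0], [0, 1, 1])
        np.testing.assert_array_equal(X[1], [1, 1, 0])
        np.testing.assert_allclose(X[2], 0.5)

    def test_no_overlap_rows_are_unit(self, no_overlap_scheme):
        wins = [(i, w) for i, w in
                enumerate(no_overlap_scheme.variants[0].windows)]
        X = build_design_matrix(no_overlap_scheme, wins, 1e-3)
        scan_part = X[:-1]
        assert (scan_part.sum(axis=1) == 1).all()
        # dropping the regularization row leaves a permutation of identity
        assert (np.sort(scan_part, axis=0)[-1] == 1).all()

    def test_foreign_window_rejected(self, default_scheme):
        with pytest.raises(DemuxError, match="not part of the scheme"):
            build_design_matrix(default_scheme,
                                [(0, dx.IsolationWindow(501, 521))], 1e-3)


class TestNnlsSolve:
    def test_identity_system_returns_observations(self):
        Y = np.array([[3.0, 0.0], [1.0, 2.0]])
        A = nnls_solve(np.eye(2), Y)
        np.testing.assert_allclose(A, Y)

    def test_two_variable_textbook_case(self):
        X = np.array([[1.0, 1.0], [1.0, 0.0]])
        A = nnls_solve(X, np.array([1.0, 1.0]))
        np.testing.assert_allclose(A[:, 0], [1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("n_cols", [2, 3, 4])
    def test_matches_exhaustive_active_set_oracle(self, n_cols):
        rng = np.random.default_rng(42 + n_cols)
        for _ in range(25):
            X = np.abs(rng.normal(size=(n_cols + 2, n_cols)))
            y = rng.normal(size=n_cols + 2)  # may be infeasible -> clipping
            a = nnls_solve(X, y)[:, 0]
            oracle = brute_force_nnls(X, y)
            np.testing.assert_allclose(a, oracle, atol=1e-8)

    def test_recovers_truth_on_consistent_default_system(self, default_scheme):
        X = default_system_matrix(default_scheme)
        rng = np.random.default_rng(0)
        A_true = np.zeros((41, 2))
        for j in range(2):
            A_true[rng.choice(41, 4, replace=False), j] = rng.uniform(
                1, 100, 4)
        A = nnls_solve(X, X @ A_true)
        np.testing.assert_allclose(A, A_true, atol=1e-8 * A_true.max())

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(DemuxError, match="finite"):
            nnls_solve(np.array([[np.nan]]), np.array([1.0]))


class TestNnlsBanded:
    def test_full_matrix_limit_equals_full_solver(self, default_scheme):
        X = default_system_matrix(default_scheme)
        rng = np.random.default_rng(3)
        Y = X @ np.abs(rng.normal(size=(41, 2)))
        np.testing.assert_allclose(nnls_solve_banded(X, Y, 100),
                                   nnls_solve(X, Y))

    def test_matches_full_solver_on_sparse_noiseless_systems(
            self, default_scheme):
        X = default_system_matrix(default_scheme)
        rng = np.random.default_rng(0)
        for _ in range(20):
            A_true = np.zeros((41, 2))
            for j in range(2):
                A_true[rng.choice(41, 3, replace=False), j] = rng.uniform(
                    10, 1000, 3)
            Y = X @ A_true
            Af = nnls_solve(X, Y)
            Ab = nnls_solve_banded(X, Y, 2)
            scale = np.abs(Af).max(axis=0)
            rel = np.abs(Ab - Af) / np.maximum(np.abs(Af), 1e-6 * scale)
            assert rel.max() <= 1e-3

    def test_single_region_system_projects_to_nonnegative(self):
        X = np.array([[1.0], [1.0], [1e-3]])
        y = np.array([2.0, 4.0, 0.0])
        expected = nnls_solve(X, y)
        np.testing.assert_allclose(nnls_solve_banded(X, y, 1), expected)

    def test_invalid_halfwidth_rejected(self):
        with pytest.raises(DemuxError, match="block_halfwidth"):
            nnls_solve_banded(np.eye(3), np.ones(3), 0)


class TestAssembleObserved:
    def test_constant_signal_is_interpolation_fixed_point(
            self, default_scheme, target_query):
        pep = dx.SimPeptide("T", 505.0, 1.0, 1e6, 1000.0, FRAGMENTS)
        run, _ = dx.simulate_run([pep], default_scheme, run_length=1.0,
                                 seed=0)  # sigma >> run: flat profile
        center = run.ms2_indices()[45]
        raw = assemble_observed(run, center, target_query,
                                interpolate=False)
        interp = assemble_observed(run, center, target_query,
                                   interpolate=True)
        np.testing.assert_allclose(interp.Y, raw.Y, rtol=1e-9)

    def test_linear_ramp_interpolates_to_center_rt(self, default_scheme,
                                                   target_query):
        # hand-built MS2-only run with intensity a linear function of RT
        spectra, idx, rt = [], 0, 0.0
        dt = 2.5 / 20 / 60
        for cyc in range(6):
            for w in default_scheme.variants[cyc % 2].windows:
                if w.contains(505.0):
                    inten = 100.0 + 2400.0 * rt
                    spectra.append(Spectrum(idx, rt, 2, w,
                                            np.array(FRAGMENT_MZS),
                                            np.full(3, inten)))
                else:
                    spectra.append(Spectrum(idx, rt, 2, w, np.empty(0),
                                            np.empty(0)))
                idx += 1
                rt += dt
        run = Run(spectra, default_scheme)
        center = run.ms2_indices()[60]
        system = assemble_observed(run, center, target_query,
                                   interpolate=True)
        rt_c = run.by_index(center).rt
        covering = [i for i, s_i in enumerate(system.scan_indices)
                    if run.by_index(s_i).isolation.contains(505.0)]
        assert covering, "system should include scans covering the precursor"
        for i in covering:
            assert system.Y[i, 0] == pytest.approx(100.0 + 2400.0 * rt_c)

    def test_absent_fragment_gives_zero_column(self, single_peptide_sim,
                                               default_scheme):
        run, _ = single_peptide_sim
        q = TransitionQuery("T", 505.0, (999.9,))
        center = run.ms2_indices()[45]
        system = assemble_observed(run, center, q)
        np.testing.assert_array_equal(system.Y, 0.0)

    def test_run_edge_truncates_and_flags(self, single_peptide_sim,
                                          target_query):
        run, _ = single_peptide_sim
        first = run.ms2_indices()[2]
        system = assemble_observed(run, first, target_query)
        assert system.truncated
        assert system.X.shape[0] == len(system.scan_indices) + 1
        assert len(system.scan_indices) < 40


class TestDemultiplexScan:
    def test_known_split_recovered(self, default_scheme):
        """Two constant-elution peptides in opposite halves of [500,520)
        with a 70/30 shared-fragment split."""
        pa = dx.SimPeptide("A", 505.0, 1.0, 1e6, 7000.0, ((600.1, 1.0),))
        pb = dx.SimPeptide("B", 512.0, 1.0, 1e6, 3000.0, ((600.1, 1.0),))
        run, _ = dx.simulate_run([pa, pb], default_scheme, run_length=1.0,
                                 seed=0)
        q = TransitionQuery("A", 505.0, (600.1,))
        # an interior scan whose window is [500,520)
        scan = next(s.scan_index for s in run.spectra
                    if s.ms_level == 2 and s.rt > 0.45
                    and s.isolation.low == 500 and s.isolation.high == 520)
        res = demultiplex_scan(run, scan, q)
        split = res.intensities[:, 0] / res.intensities[:, 0].sum()
        np.testing.assert_allclose(split, [0.7, 0.3], atol=0.01)

    def test_all_mass_on_one_side(self, single_peptide_sim, target_query):
        run, _ = single_peptide_sim
        scan = next(s.scan_index for s in run.spectra
                    if s.ms_level == 2 and abs(s.rt - 1.2) < 0.05
                    and s.isolation.contains(505.0))
        res = demultiplex_scan(run, scan, target_query)
        region_lows = [run.scheme.regions()[i].low for i in res.region_indices]
        target_side = region_lows.index(500.0)
        other = 1 - target_side
        np.testing.assert_allclose(res.intensities[target_side],
                                   res.observed, rtol=1e-3)
        assert res.intensities[other].max() <= 1e-3 * res.observed.max()

    def test_conservation_even_with_noise(self, default_scheme, target_query):
        pep = dx.SimPeptide("T", 505.0, 1.0, 0.15, 500.0, FRAGMENTS)
        run, _ = dx.simulate_run(
            [pep], default_scheme, run_length=2.0,
            noise={"additive_sigma": 20.0, "multiplicative_cv": 0.2}, seed=9,
        )
        for scan in run.ms2_indices()[40:44]:
            if not run.by_index(scan).isolation.contains(505.0):
                continue
            res = demultiplex_scan(run, scan, target_query)
            np.testing.assert_allclose(res.intensities.sum(axis=0),
                                       res.observed, rtol=1e-9)
            assert (res.intensities >= 0).all()

    def test_zero_observations_give_zeros_not_nan(self, single_peptide_sim):
        run, _ = single_peptide_sim
        q = TransitionQuery("T", 505.0, (999.9,))
        scan = next(s.scan_index for s in run.spectra
                    if s.ms_level == 2 and s.rt > 1.0
                    and s.isolation.contains(505.0))
        res = demultiplex_scan(run, scan, q)
        assert np.isfinite(res.intensities).all()
        np.testing.assert_array_equal(res.intensities, 0.0)


class TestDemultiplexRun:
    def test_no_overlap_run_passes_through(self, no_overlap_scheme):
        pep = dx.SimPeptide("T", 505.0, 1.0, 0.15, 500.0, FRAGMENTS)
        run, _ = dx.simulate_run([pep], no_overlap_scheme, run_length=2.0,
                                 seed=4)
        q = TransitionQuery("T", 505.0, FRAGMENT_MZS)
        res = demultiplex_run(run, [q])
        raw = dx.extract_xic(run, 600.1, precursor_filter=505.0)
        c = res["T"][600.1]
        common = np.isin(raw.rt, c.rt)
        np.testing.assert_allclose(c.intensity, raw.intensity[common],
                                   rtol=1e-9)

    def test_interference_removed_from_target_region(self, interference_sim,
                                                     target_query):
        """The opposite-half interferent's every-other-cycle 'spiky'
        contribution disappears from the demultiplexed target trace."""
        run, truth = interference_sim
        res = demultiplex_run(run, [target_query])
        c = res["T"][600.1]
        lookup = scan_lookup(run)
        scans = [lookup[rt] for rt in c.rt]
        tt = truth.true_trace(run, "T", 600.1, scans)
        rms = np.sqrt(np.mean((c.intensity - tt) ** 2) / np.mean(tt ** 2))
        assert rms <= 0.05
        raw = dx.extract_xic(run, 600.1, precursor_filter=505.0)
        raw_scans = [lookup[rt] for rt in raw.rt]
        tt_raw = truth.true_trace(run, "T", 600.1, raw_scans)
        leak_raw = np.abs(raw.intensity - tt_raw).sum()
        leak_demux = np.abs(c.intensity - tt).sum()
        assert leak_demux <= 0.05 * leak_raw

    def test_full_spectrum_mode_doubles_pseudo_scans(self, default_scheme):
        pep = dx.SimPeptide("T", 505.0, 1.0, 0.3, 500.0, ((600.1, 1.0),))
        run, _ = dx.simulate_run([pep], default_scheme, run_length=2.0,
                                 ms1_every=0, seed=2)
        out = demultiplex_run(run, None)
        in_ms2 = [s for s in run.spectra
                  if s.ms_level == 2 and s.mz.size > 0]
        # interior scans (with a full system) produce 2 pseudo-scans each
        full_system = [s for s in in_ms2
                       if 20 <= run.ms2_indices().index(s.scan_index)
                       < len(run.ms2_indices()) - 20]
        out_ms2 = [s for s in out.spectra if s.ms_level == 2]
        assert len(out_ms2) >= 2 * len(full_system)
        # pseudo-scan isolation metadata equals region bounds (10 Th halves)
        widths = {round(s.isolation.width, 6) for s in out_ms2}
        assert widths == {10.0}
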