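"""Variable projection: spectra projection, sequential fits, basis changes."""

import numpy as np
import pytest

from takinetics import (
    IRFModel,
    NoiseModel,
    TADataset,
    c1c2_presets,
    dads_from_eads,
    default_wavelength_axis,
    eads_from_dads,
    fit_sequential,
    linlog_time_axis,
    project_spectra,
    simulate_dataset,
)
from takinetics.datasets import SpectraSet
from takinetics.kinetics import exp_gauss_kernel
from takinetics.varpro import (
    IdentifiabilityError,
    _chain_concentrations,
    sequential_scheme,
    sequential_to_parallel_matrix,
    standard_errors_from_jacobian,
    svd_residual_diagnostics,
)


class TestProjectSpectra:
    def test_noiseless_consistency(self, fig3b_scheme, irf150):
        from takinetics import DumpEvent, apply_dump

        # a dump event populates the GSI so all five species carry signal
        ev = DumpEvent(0.3, [("ES1", "GSI", 0.1), ("ES2", "GSI", 0.1)])
        scheme = fig3b_scheme.with_dump_events([ev])
        t = linlog_time_axis(-1, 1, 500.0, 80)
        wl = default_wavelength_axis(n=50)
        p = c1c2_presets(8)
        ds = simulate_dataset(scheme, p.target_spectra, irf150, t, wl)
        conc = apply_dump(scheme, irf150, t)
        observed = [c for c in scheme.compartments if c != "GS"]
        C = np.stack([conc[c] for c in observed], axis=1)
        spec, resid = project_spectra(ds, C, labels=observed)
        truth = p.target_spectra.matrix(observed, wl)
        # masked scatter columns carry no information; spectra are zero there
        seen = ds.weights[0] > 0
        assert spec.spectra[:, seen] == pytest.approx(truth[:, seen], abs=1e-8)
        # residuals orthogonal to the concentration columns under the weights
        assert np.abs(C.T @ (ds.weights * resid)).max() < 1e-8

    def test_duplicate_kinetics_raise_identifiability_error(self, irf150):
        t = np.linspace(-1, 10, 50)
        k = exp_gauss_kernel(0.5, t, irf150)
        C = np.stack([k, k], axis=1)
        ds = TADataset(t, np.array([500.0, 510.0]), np.zeros((50, 2)))
        with pytest.raises(IdentifiabilityError, match="c1~c2"):
            project_spectra(ds, C)


class TestSequentialParallelEquivalence:
    def test_single_component_dads_equals_eads(self):
        wl = np.linspace(400, 700, 30)
        eads = SpectraSet("EADS", wl, np.random.default_rng(0).normal(size=(1, 30)),
                          ("EADS1",))
        d = dads_from_eads(eads, [2.0])
        assert d.spectra == pytest.approx(eads.spectra)

    def test_transform_matches_pseudoinverse_oracle(self, irf150):
        """Closed-form triangular map vs brute-force basis change."""
        taus = [0.45, 2.0, 11.0, 630.0]
        t = linlog_time_axis(-1, 1, 5e3, 120)
        C = _chain_concentrations(taus, irf150, t, 4)
        Phi = np.stack([exp_gauss_kernel(1 / x, t, irf150) for x in taus], axis=1)
        B_oracle = np.linalg.lstsq(Phi, C, rcond=None)[0]
        B = sequential_to_parallel_matrix(taus)
        assert B == pytest.approx(B_oracle, abs=1e-8)

    def test_well_separated_first_dads_is_eads_difference(self):
        # tau1 << tau2: the fast parallel amplitude is ~ EADS1 - EADS2
        B = sequential_to_parallel_matrix([0.1, 1000.0])
        assert B[0] == pytest.approx([1.0, -1.0], abs=1e-3)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(5)
        wl = np.linspace(400, 700, 40)
        taus = [0.45, 2.0, 11.0, 630.0, np.inf]
        eads = SpectraSet("EADS", wl, rng.normal(size=(5, 40)),
                          tuple(f"EADS{i}" for i in range(5)))
        back = eads_from_dads(dads_from_eads(eads, taus), taus)
        assert np.abs(back.spectra - eads.spectra).max() < 1e-10

    def test_both_bases_reconstruct_identical_model(self, ph8_fit, ph8_dataset):
        taus = list(ph8_fit.lifetimes)
        t = ph8_dataset.times
        C = _chain_concentrations(taus, ph8_fit.irf, t, len(taus))
        rates = [0.0 if np.isinf(x) else 1 / x for x in taus]
        Phi = np.stack([exp_gauss_kernel(k, t, ph8_fit.irf) for k in rates], axis=1)
        eads = ph8_fit.spectra["EADS"].spectra
        dads = ph8_fit.spectra["DADS"].spectra
        assert np.abs(C @ eads - Phi @ dads).max() < 1e-10


class TestFitSequential:
    def test_single_exponential_exact_recovery(self):
        t = np.linspace(0.0, 20.0, 60)
        wl = np.array([500.0, 550.0, 600.0])
        spectra = np.array([[1.0, -0.5, 0.2]])
        D = np.exp(-t / 3.7)[:, None] * spectra
        ds = TADataset(t, wl, D)
        fit = fit_sequential(ds, [2.0], irf_init=None, n_starts=1)
        assert fit.lifetimes[0] == pytest.approx(3.7, rel=1e-6)
        assert fit.stderr["tau1"] == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_closure_recovers_all_parameters(self, preset8):
        t = linlog_time_axis()
        wl = default_wavelength_axis(n=60)
        ds = simulate_dataset(
            preset8.sequential_scheme, preset8.sequential_spectra, preset8.irf,
            t, wl, noise=None,
        )
        init = [0.6, 2.6, 8.0, 800.0, 3.6e5, np.inf]
        fit = fit_sequential(ds, init, irf_init=IRFModel(0.01, 0.08), n_starts=1)
        truth = np.array([0.45, 2.0, 11.0, 630.0, 4.9e5])
        assert fit.lifetimes[:5] == pytest.approx(truth, rel=1e-6)
        assert fit.params["irf_width"] == pytest.approx(preset8.irf.width, rel=1e-6)

    def test_noisy_recovery_median_error_within_quoted_precision(self, ph8_fit):
        """1% noise leaves the six constants within the quoted 10% errors."""
        truth = np.array([0.45, 2.0, 11.0, 630.0, 4.9e5])
        rel = np.abs(ph8_fit.lifetimes[:5] - truth) / truth
        assert np.median(rel) <= 0.10
        assert rel[0] <= 0.10  # the isomerization time is well determined

    def test_twenty_seeds_median_recovery(self, preset8):
        """Parameter recovery across noise realizations at 1% peak noise."""
        t = linlog_time_axis(-1, 1, 1.25e8, 120, lin_step=0.1)
        wl = default_wavelength_axis(n=50)
        truth = np.array([0.45, 2.0, 11.0, 630.0, 4.9e5])
        errs = []
        for seed in range(20):
            ds = simulate_dataset(
                preset8.sequential_scheme, preset8.sequential_spectra,
                preset8.irf, t, wl, noise=NoiseModel(0.01, seed=seed),
            )
            fit = fit_sequential(
                ds, [0.3, 3.0, 15.0, 400.0, 3e5, np.inf],
                irf_init=preset8.irf, n_starts=1,
            )
            errs.append(np.abs(fit.lifetimes[:5] - truth) / truth)
        med = np.median(np.concatenate(errs))
        assert med <= 0.10

    def test_masked_cells_do_not_influence_fit(self, preset8):
        t = linlog_time_axis(-1, 1, 1e6, 90, lin_step=0.1)
        wl = default_wavelength_axis(n=40)
        ds = simulate_dataset(
            preset8.sequential_scheme, preset8.sequential_spectra, preset8.irf,
            t, wl, noise=NoiseModel(0.01, seed=1),
        )
        init = [0.3, 3.0, 15.0, 400.0, 3e5, np.inf]
        fit_a = fit_sequential(ds, init, irf_init=preset8.irf, n_starts=1)
        vandal = ds.delta_A.copy()
        vandal[:, ds.weights[0] == 0] = 1e6  # arbitrary garbage in masked cells
        ds_b = TADataset(t, wl, vandal, weights=ds.weights)
        fit_b = fit_sequential(ds_b, init, irf_init=preset8.irf, n_starts=1)
        for name in fit_a.params:
            a, b = fit_a.params[name], fit_b.params[name]
            if np.isinf(a):
                assert np.isinf(b)
            else:
                assert abs(a - b) <= 1e-12

    def test_near_degenerate_pair_reports_wide_errors(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 30, 80)
        wl = np.linspace(450, 650, 20)
        C = np.stack([np.exp(-t / 3.0), np.exp(-t / 3.6)], axis=1)
        S = rng.normal(size=(2, 20))
        D = C @ S + rng.normal(0, 0.05 * np.abs(C @ S).max(), size=(80, 20))
        ds = TADataset(t, wl, D)
        fit = fit_sequential(ds, [2.5, 4.5], irf_init=None, n_starts=1)
        assert fit.lifetimes.size == 2  # no crash, a result is returned
        rel_err = np.array(
            [fit.stderr["tau1"] / fit.params["tau1"],
             fit.stderr["tau2"] / fit.params["tau2"]]
        )
        assert rel_err.max() > 0.10  # honestly wide uncertainty

    def test_duplicate_initial_lifetimes_rejected(self):
        ds = TADataset(np.linspace(0, 5, 10), np.array([500.0]),
                       np.zeros((10, 1)))
        with pytest.raises(ValueError, match="distinct"):
            fit_sequential(ds, [1.0, 1.0], irf_init=None)


class TestStandardErrors:
    def test_singular_jacobian_flagged_infinite(self):
        jac = np.zeros((10, 2))
        jac[:, 0] = np.arange(10)
        err, _ = standard_errors_from_jacobian(jac, ssq=1.0, dof=8)
        assert np.isinf(err[1]) or np.isnan(err[1]) or err[1] > 1e6

    def test_jacobian_errors_match_bootstrap(self, irf150):
        """Linearized covariance vs refitting fresh noise realizations."""
        taus_true = [0.5, 5.0, 60.0]
        t = linlog_time_axis(-0.5, 0.5, 500.0, 60, lin_step=0.1)
        wl = np.linspace(450, 650, 25)
        rng = np.random.default_rng(17)
        S = rng.normal(size=(3, 25))
        scheme = sequential_scheme(taus_true)
        C = _chain_concentrations(taus_true, irf150, t, 3)
        clean = C @ S
        sigma = 0.01 * np.abs(clean).max()

        def one_fit(seed):
            D = clean + np.random.default_rng(seed).normal(0, sigma, clean.shape)
            ds = TADataset(t, wl, D)
            return fit_sequential(ds, [0.4, 4.0, 80.0], irf_init=irf150,
                                  fit_irf=False, n_starts=1)

        ref = one_fit(0)
        boot = np.array(
            [[one_fit(1000 + i).params[f"tau{j + 1}"] for j in range(3)]
             for i in range(60)]
        )
        boot_sd = boot.std(axis=0, ddof=1)
        jac_sd = np.array([ref.stderr[f"tau{j + 1}"] for j in range(3)])
        assert jac_sd == pytest.approx(boot_sd, rel=0.30)


class TestResidualDiagnostics:
    def test_adequate_fit_has_flat_residual_spectrum(self, ph8_fit):
        diag = svd_residual_diagnostics(ph8_fit)
        assert not diag["structured"]
        assert diag["ratio"] < 2.0

    def test_underfitted_data_flagged(self, ph8_dataset, preset8):
        # four components cannot represent the six-stage evolution
        fit = fit_sequential(
            ph8_dataset, [0.5, 10.0, 3e5, np.inf],
            irf_init=preset8.irf, n_starts=1,
        )
        diag = svd_residual_diagnostics(fit)
        assert diag["structured"]
        assert diag["ratio"] > 2.0

    def test_mildly_underfitted_data_shows_elevated_structure(
        self, ph8_dataset, preset8
    ):
        # dropping one of two similar early stages leaves weaker, but
        # still visible, structure above the noise floor
        fit = fit_sequential(
            ph8_dataset, [0.5, 10.0, 500.0, 3e5, np.inf],
            irf_init=preset8.irf, n_starts=1,
        )
        diag = svd_residual_diagnostics(fit)
        assert diag["ratio"] > 1.2

    def test_masked_cells_excluded_from_noise_estimate(self, ph8_fit):
        diag = svd_residual_diagnostics(ph8_fit)
        sigma_obs = ph8_fit.datasets[0].meta["truth"]["noise_sigma"]
        assert diag["noise_sigma"] == pytest.approx(sigma_obs, rel=0.1)
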