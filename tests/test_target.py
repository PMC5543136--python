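"""Target analysis: rate recovery, spectral constraints, quantum yields."""

import numpy as np
import pytest

from takinetics import (
    DumpEvent,
    NoiseModel,
    apply_bleach_constraint,
    c1c2_presets,
    default_wavelength_axis,
    fit_target,
    linlog_time_axis,
    simulate_dataset,
    simulate_pdp_matrix,
)
from takinetics.schemes import KineticScheme
from takinetics.varpro import IdentifiabilityError


@pytest.fixture(scope="module")
def pp_dataset(preset8):
    """Noisy pump-probe matrix from the branched fs scheme (1% noise)."""
    t = linlog_time_axis(-1, 1, 3000.0, 130)
    return simulate_dataset(
        preset8.target_scheme, preset8.target_spectra, preset8.irf,
        t, default_wavelength_axis(), noise=NoiseModel(0.01, seed=3),
    )


@pytest.fixture(scope="module")
def pdp_pair(preset8):
    """Paired PP/PDP matrices with a 300 fs dump (fractions 0.1/0.1)."""
    ev = DumpEvent(0.3, [("ES1", "GSI", 0.1), ("ES2", "GSI", 0.1)])
    return simulate_pdp_matrix(
        preset8.target_scheme, preset8.target_spectra, preset8.irf, ev,
        linlog_time_axis(-1.0, 1.0, 100.0, 120), default_wavelength_axis(),
        noise=NoiseModel(0.01, seed=11),
    )


class TestFitTarget:
    def test_noiseless_fit_recovers_exact_rates(self, preset8):
        t = linlog_time_axis(-1, 1, 300.0, 100)
        ds = simulate_dataset(
            preset8.target_scheme, preset8.target_spectra, preset8.irf,
            t, default_wavelength_axis(n=60),
        )
        # total decay rates are shape-identifiable with free spectra
        init = preset8.target_scheme.with_rates(
            {("ES2", "GS"): 0.25, ("ES3", "GS"): 0.15}
        )
        fit = fit_target(
            ds, init, irfs=preset8.irf,
            free_rates=[("ES2", "GS"), ("ES3", "GS")],
        )
        assert fit.params["k:ES2->GS"] == pytest.approx(0.38, rel=1e-6)
        assert fit.params["k:ES3->GS"] == pytest.approx(0.09, rel=1e-6)

    def test_es2_branch_rates_recovered_under_bleach_constraint(
        self, pp_dataset, preset8
    ):
        """The ES2 -> ES3 vs ES2 -> GS split trades exactly against the ES3
        spectral amplitude; the equal-bleach condition resolves it."""
        init = preset8.target_scheme.with_rates(
            {("ES2", "ES3"): 0.3, ("ES2", "GS"): 0.2}
        )
        fit = fit_target(
            pp_dataset, init, irfs=preset8.irf,
            free_rates=[("ES2", "ES3"), ("ES2", "GS")],
            bleach_window=(430.0, 465.0), bleach_weight=1.0,
        )
        assert fit.params["k:ES2->ES3"] == pytest.approx(0.12, rel=0.10)
        assert fit.params["k:ES2->GS"] == pytest.approx(0.38, rel=0.10)

    def test_true_model_reaches_noise_floor(self, pp_dataset, preset8):
        fit = fit_target(
            pp_dataset, preset8.target_scheme, irfs=preset8.irf,
            free_rates=[("ES2", "ES3")],
        )
        sigma = pp_dataset.meta["truth"]["noise_sigma"]
        # with unit weights the reduced chi2 equals the noise variance
        assert fit.reduced_chi2 == pytest.approx(sigma**2, rel=0.1)

    def test_joint_pp_pdp_recovers_gsi_rate_and_dump_fractions(
        self, pdp_pair, preset8
    ):
        pp, pdp = pdp_pair
        init = preset8.target_scheme.with_rates({("GSI", "GS"): 0.5})
        fit = fit_target(
            [pp, pdp], init, irfs=preset8.irf,
            free_rates=[("GSI", "GS")],
            free_dump=[("ES1", "GSI"), ("ES2", "GSI")],
        )
        assert fit.params["k:GSI->GS"] == pytest.approx(1.0, rel=0.10)
        assert fit.params["f:ES1->GSI"] == pytest.approx(0.1, abs=0.03)
        assert fit.params["f:ES2->GSI"] == pytest.approx(0.1, abs=0.05)

    def test_unpopulated_compartment_rate_is_unidentifiable(self, preset8, irf150):
        scheme = KineticScheme(
            compartments=("ES1", "K1", "GSI", "GS"),
            rates={("ES1", "K1"): 0.66, ("ES1", "GS"): 1.54, ("GSI", "GS"): 1.0},
            input_weights={"ES1": 1.0},
            terminal=("K1", "GS"),
            dark=("GS",),
        )
        t = linlog_time_axis(-1, 1, 50.0, 60)
        ds = simulate_dataset(
            scheme, c1c2_presets(8).target_spectra, irf150,
            t, default_wavelength_axis(n=30),
        )
        # GSI never receives population: its decay rate cannot move the model
        with pytest.raises(IdentifiabilityError, match="GSI"):
            fit_target(ds, scheme, irfs=irf150, free_rates=[("GSI", "GS")])

    def test_mismatched_wavelength_grids_rejected(self, pp_dataset, preset8):
        other = simulate_dataset(
            preset8.target_scheme, preset8.target_spectra, preset8.irf,
            pp_dataset.times, default_wavelength_axis(n=40),
        )
        with pytest.raises(ValueError, match="wavelength"):
            fit_target([pp_dataset, other], preset8.target_scheme,
                       irfs=preset8.irf, free_rates=[("ES2", "ES3")])


class TestBleachConstraint:
    def test_constraint_restores_degenerate_yield(self, pp_dataset, preset8):
        """The K1 yield is spectrally degenerate until the bleach is pinned."""
        init = preset8.target_scheme.with_rates(
            {("ES1", "K1"): 0.33, ("ES1", "GS"): 0.99}  # wrong split, yield 0.15
        )
        free = [("ES1", "K1"), ("ES1", "GS")]
        fit0 = fit_target(pp_dataset, init, irfs=preset8.irf, free_rates=free)
        fit1 = apply_bleach_constraint(fit0, (430.0, 465.0), weight=1.0)
        y, _ = fit1.extra["yields"]["K1"]
        assert y == pytest.approx(0.30, abs=0.03 * 0.30 + 0.01)
        assert fit1.extra["bleach_spread"] < fit1.extra["bleach_spread_pre"]

    def test_equal_bleach_data_fit_essentially_unchanged(self, preset8):
        # noiseless data from equal-bleach spectra: the unconstrained
        # optimum already satisfies the constraint, so the penalty is
        # (near) zero and the re-fit barely moves
        ds = simulate_dataset(
            preset8.target_scheme, preset8.target_spectra, preset8.irf,
            linlog_time_axis(-1, 1, 3000.0, 130), default_wavelength_axis(),
        )
        fit0 = fit_target(
            ds, preset8.target_scheme, irfs=preset8.irf,
            free_rates=[("ES2", "GS"), ("ES3", "GS")],
        )
        fit1 = apply_bleach_constraint(fit0, (430.0, 465.0), weight=1.0)
        assert fit1.extra["bleach_spread_pre"] < 0.05
        for name in fit0.params:
            assert fit1.params[name] == pytest.approx(fit0.params[name], rel=0.02)

    def test_empty_window_is_configuration_error(self, pp_dataset, preset8):
        fit0 = fit_target(
            pp_dataset, preset8.target_scheme, irfs=preset8.irf,
            free_rates=[("ES2", "ES3")],
        )
        with pytest.raises(ValueError, match="window"):
            apply_bleach_constraint(fit0, (900.0, 910.0))


class TestQuantumYield:
    def test_printed_rates_give_thirty_percent(self, pp_dataset, preset8):
        fit = fit_target(
            pp_dataset, preset8.target_scheme, irfs=preset8.irf,
            free_rates=[("ES2", "ES3")],
        )
        y, err = fit.extra["yields"]["K1"]
        assert y == pytest.approx(0.30, abs=1e-9)  # ES2 rates do not touch K1
        assert err == pytest.approx(0.0, abs=1e-6)

    def test_all_branches_to_photoproduct_give_unity(self, irf150, preset8):
        scheme = KineticScheme(
            compartments=("ES1", "K1"),
            rates={("ES1", "K1"): 2.2},
            input_weights={"ES1": 1.0},
            terminal=("K1",),
            photoproduct=("K1",),
        )
        t = linlog_time_axis(-1, 1, 20.0, 50)
        ds = simulate_dataset(
            scheme, preset8.target_spectra, irf150, t,
            default_wavelength_axis(n=25),
        )
        fit = fit_target(ds, scheme, irfs=irf150, free_rates=[("ES1", "K1")])
        y, _ = fit.extra["yields"]["K1"]
        assert y == pytest.approx(1.0, abs=1e-12)

    def test_delta_method_yield_error_matches_bootstrap(self, preset8):
        """Propagated yield uncertainty vs refitting fresh noise draws."""
        t = linlog_time_axis(-0.5, 0.5, 200.0, 60, lin_step=0.1)
        wl = default_wavelength_axis(n=40)
        scheme = preset8.target_scheme
        free = [("ES1", "K1"), ("ES1", "GS")]

        def one_fit(seed):
            ds = simulate_dataset(
                scheme, preset8.target_spectra, preset8.irf, t, wl,
                noise=NoiseModel(0.02, seed=seed),
            )
            return fit_target(
                ds, scheme, irfs=preset8.irf, free_rates=free,
                bleach_window=(430.0, 465.0), bleach_weight=1.0,
            )

        ref = one_fit(0)
        y_ref, err_ref = ref.extra["yields"]["K1"]
        boot = np.array(
            [one_fit(2000 + i).extra["yields"]["K1"][0] for i in range(40)]
        )
        assert y_ref == pytest.approx(0.30, abs=0.02)
        assert err_ref == pytest.approx(boot.std(ddof=1), rel=0.30)
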