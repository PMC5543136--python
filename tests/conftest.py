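"""Shared fixtures: schemes, presets and reusable (expensive) fits."""

import numpy as np
import pytest

from takinetics import (
    IRFModel,
    KineticScheme,
    NoiseModel,
    c1c2_presets,
    default_wavelength_axis,
    linlog_time_axis,
    simulate_dataset,
)
from takinetics.varpro import fit_sequential


@pytest.fixture(scope="session")
def fig3b_scheme():
    """Branched fs scheme: three excited states, photoproduct K1, GSI."""
    return c1c2_presets(8).target_scheme


@pytest.fixture(scope="session")
def preset8():
    return c1c2_presets(8)


@pytest.fixture(scope="session")
def preset10():
    return c1c2_presets(10)


@pytest.fixture(scope="session")
def irf150():
    return IRFModel.from_fwhm(0.150)


@pytest.fixture(scope="session")
def ph8_dataset(preset8):
    """Full-size noisy pH 8 sequential pump-probe matrix (1% peak noise)."""
    return simulate_dataset(
        preset8.sequential_scheme,
        preset8.sequential_spectra,
        preset8.irf,
        linlog_time_axis(),
        default_wavelength_axis(),
        noise=NoiseModel(0.01, seed=42),
    )


@pytest.fixture(scope="session")
def ph8_fit(ph8_dataset, preset8):
    """Six-component sequential fit of the noisy pH 8 matrix."""
    return fit_sequential(
        ph8_dataset,
        init_lifetimes=[0.3, 3.0, 15.0, 400.0, 3e5, np.inf],
        irf_init=preset8.irf,
        n_starts=2,
        seed=0,
    )


def random_scheme(rng, n_max=6, with_terminal=True):
    """Random small first-order network with every state draining to GS.

    Rates are log-uniform in [1e-4, 10] /ps; extra forward/backward
    edges are added with moderate probability, keeping GS reachable from
    everywhere.
    """
    n = int(rng.integers(2, n_max + 1))
    labels = [f"C{i}" for i in range(n)] + ["GS"]
    rates = {}
    for i in range(n):
        # chain edge keeps the network connected
        dst = labels[i + 1]
        rates[(labels[i], dst)] = 10.0 ** rng.uniform(-4, 1)
        for j in range(n + 1):
            if j != i and rng.random() < 0.25:
                rates[(labels[i], labels[j])] = 10.0 ** rng.uniform(-4, 1)
    weights = rng.random(n) * (rng.random(n) < 0.5)
    if weights.sum() == 0:
        weights[0] = 1.0
    return KineticScheme(
        compartments=tuple(labels),
        rates=rates,
        input_weights={labels[i]: float(weights[i]) for i in range(n)},
        terminal=("GS",) if with_terminal else (),
    )
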