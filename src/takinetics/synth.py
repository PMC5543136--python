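"""Synthetic C1C2-like datasets with known ground truth.

Generates pump-probe, pump-dump-probe and flash-photolysis
difference-absorption matrices from Gaussian-band species spectra and
the kinetic schemes of the channelrhodopsin C1C2 photoreaction: the
branched excited-state scheme (three excited states ES1-3, first
photoproduct K1, ground-state intermediate GSI) on the fs-ps scale, the
sequential six/seven-component description used for global analysis,
and the microsecond-to-second K/L/M/O photocycle chain.

Band *centers* follow the reported spectral features (excited-state
absorption at 541/535/528 nm, photoproduct at 522-530 nm, L at ~440 nm,
M below 400 nm, O at ~530 nm, bleach near 460 nm, stimulated emission
beyond 630 nm).  Band widths and relative amplitudes are invented
calibration constants, chosen once so that bleach/ESA/SE overlap
qualitatively as in the measured spectra; they carry no experimental
meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import TADataset
from .kinetics import apply_dump, concentration_profiles
from .schemes import IRFModel, KineticScheme

__all__ = [
    "SpeciesSpectrumModel",
    "NoiseModel",
    "C1C2Preset",
    "c1c2_presets",
    "linlog_time_axis",
    "default_wavelength_axis",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SpeciesSpectrumModel:
    """Per-species difference spectra as sums of Gaussian bands.

    ``bands`` maps a compartment label to a list of
    ``(center_nm, fwhm_nm, signed_amplitude)``; ground-state bleach and
    stimulated emission are negative, absorptions positive.
    """

    bands: dict

    def spectrum(self, label: str, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for center, fwhm, amp in self.bands.get(label, ()):
            out += amp * np.exp(-4 * np.log(2) * ((wl - center) / fwhm) ** 2)
        return out

    def matrix(self, labels, wavelengths: np.ndarray) -> np.ndarray:
        """Stack of spectra, shape (n_labels, n_wavelengths)."""
        return np.stack([self.spectrum(lb, wavelengths) for lb in labels])

    def check_coverage(self, wavelengths: np.ndarray) -> None:
        wl = np.asarray(wavelengths, dtype=float)
        for label, bands in self.bands.items():
            for center, fwhm, _ in bands:
                if center - 2 * fwhm < wl.min() - fwhm or center + 2 * fwhm > wl.max() + fwhm:
                    raise ValueError(
                        f"band of {label} at {center} nm extends beyond the grid"
                    )


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise, sigma as a fraction of peak |dA|."""

    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def linlog_time_axis(
    t_min: float = -1.0,
    t_switch: float = 1.0,
    t_max: float = 1.25e8,
    n_points: int = 169,
    lin_step: float = 0.05,
) -> np.ndarray:
    """Delay grid, linear up to ``t_switch`` and logarithmic beyond (ps).

    The defaults reproduce the fs-TA sampling used throughout: 169
    points up to 125 us with a minimum (linear) step of 50 fs.  With
    ``t_switch >= t_max`` the grid is purely linear.
    """
    if t_max <= t_min:
        raise ValueError("t_max must exceed t_min")
    if t_switch >= t_max:
        return np.linspace(t_min, t_max, n_points)
    if t_switch <= t_min:
        raise ValueError("t_switch must lie inside (t_min, t_max)")
    if t_switch <= 0:
        raise ValueError("the logarithmic segment requires t_switch > 0")
    n_lin = int(round((t_switch - t_min) / lin_step)) + 1
    n_log = n_points - n_lin
    if n_log < 1:
        raise ValueError(
            f"n_points={n_points} leaves no room for the log segment "
            f"({n_lin} linear points at step {lin_step})"
        )
    lin = t_min + lin_step * np.arange(n_lin)
    logp = np.geomspace(t_switch, t_max, n_log + 1)[1:]
    axis = np.concatenate([lin, logp])
    if not np.all(np.diff(axis) > 0):
        raise ValueError("generated axis is not strictly increasing")
    return axis


def default_wavelength_axis(
    lo: float = 380.0, hi: float = 720.0, n: int = 120
) -> np.ndarray:
    return np.linspace(lo, hi, n)


# ---------------------------------------------------------------------------
# C1C2 presets

#: common ground-state-bleach band shared by the excited states and the
#: photoproducts (the equal-bleach assumption of the target model)
_GSB = (458.0, 48.0, -1.0)

_FS_SADS_BANDS = {
    "ES1": [(541.0, 50.0, 1.30), (700.0, 90.0, -0.50), _GSB],
    "ES2": [(535.0, 44.0, 1.15), (690.0, 85.0, -0.35), _GSB],
    "ES3": [(528.0, 40.0, 1.00), (680.0, 80.0, -0.22), _GSB],
    "K1": [(523.0, 42.0, 0.90), _GSB],
    # red-shifted hot ground state: shifted bleach plus broad red absorption
    "GSI": [(480.0, 45.0, -0.55), (620.0, 130.0, 0.35)],
    "GS": [],
}


def _scaled(bands, factor):
    return [(c, w, a * factor) for c, w, a in bands]


def _fs_target_scheme(ph: int) -> KineticScheme:
    # ES1 drains at 2.2/ps, branching 40/30/30 to ES2/K1/GS; ES2 branches
    # 0.12 vs 0.38/ps to ES3/GS; ES3 decays at 0.09/ps; GSI at 1.0/ps.
    return KineticScheme(
        compartments=("ES1", "ES2", "ES3", "K1", "GSI", "GS"),
        rates={
            ("ES1", "ES2"): 0.88,
            ("ES1", "K1"): 0.66,
            ("ES1", "GS"): 0.66,
            ("ES2", "ES3"): 0.12,
            ("ES2", "GS"): 0.38,
            ("ES3", "GS"): 0.09,
            ("GSI", "GS"): 1.0,
        },
        input_weights={"ES1": 1.0},
        terminal=("K1", "GS"),
        dark=("GS",),
        excited=("ES1", "ES2", "ES3"),
        photoproduct=("K1",),
        name=f"c1c2-fs-target-ph{ph}",
    )


#: photoisomerization quantum yield implied by the fs target scheme;
#: scales every photoproduct difference spectrum in the sequential EADS
_K1_YIELD = 0.30

_SEQ_LIFETIMES = {
    8: (0.45, 2.0, 11.0, 630.0, 4.9e5, np.inf),
    10: (0.45, 2.0, 11.0, 650.0, 2.0e5, 2.6e7, np.inf),
}

_SEQ_EADS_BANDS = {
    8: {
        "S1": _FS_SADS_BANDS["ES1"],
        "S2": _FS_SADS_BANDS["ES2"],
        "S3": _FS_SADS_BANDS["ES3"],
        "S4": _scaled([(523.0, 42.0, 0.90), _GSB], _K1_YIELD),
        "S5": _scaled([(530.0, 42.0, 0.90), _GSB], _K1_YIELD),
        # K <=> L equilibrium tilted towards K at pH 8
        "S6": _scaled([(530.0, 42.0, 0.78), (442.0, 40.0, 0.08), _GSB], _K1_YIELD),
    },
    10: {
        "S1": _FS_SADS_BANDS["ES1"],
        "S2": _FS_SADS_BANDS["ES2"],
        "S3": _FS_SADS_BANDS["ES3"],
        "S4": _scaled([(523.0, 42.0, 0.90), _GSB], _K1_YIELD),
        "S5": _scaled([(530.0, 42.0, 0.90), _GSB], _K1_YIELD),
        "S6": _scaled(
            [(530.0, 42.0, 0.50), (442.0, 40.0, 0.30), (395.0, 38.0, 0.35), _GSB],
            _K1_YIELD,
        ),
        # more M at high pH: the K/L/M equilibrium tilts towards M
        "S7": _scaled(
            [(530.0, 42.0, 0.35), (442.0, 40.0, 0.20), (395.0, 38.0, 0.55), _GSB],
            _K1_YIELD,
        ),
    },
}

_FLASH_LIFETIMES_PS = (2.0e7, 1.5e10, 1.0e11)  # 20 us, 15 ms, 100 ms

_FLASH_BANDS = {
    # K/L mixture before the M rise
    "P1": [(530.0, 45.0, 0.60), (442.0, 40.0, 0.35), (458.0, 48.0, -0.80)],
    # K/L/M equilibrium
    "P2": [
        (530.0, 45.0, 0.35),
        (442.0, 40.0, 0.25),
        (390.0, 38.0, 0.50),
        (458.0, 48.0, -0.80),
    ],
    # red-shifted, reprotonated O intermediate
    "P3": [(530.0, 45.0, 0.80), (458.0, 48.0, -0.80)],
    "GS": [],
}


def _photocycle_scheme(ph: int) -> KineticScheme:
    k1, k2, k3 = (1.0 / t for t in _FLASH_LIFETIMES_PS)
    return KineticScheme(
        compartments=("P1", "P2", "P3", "GS"),
        rates={("P1", "P2"): k1, ("P2", "P3"): k2, ("P3", "GS"): k3},
        input_weights={"P1": 1.0},
        terminal=("GS",),
        dark=("GS",),
        name=f"c1c2-photocycle-ph{ph}",
    )


@dataclass(frozen=True)
class C1C2Preset:
    """Ground-truth models emulating the C1C2 datasets at one pH.

    ``target_scheme``/``target_spectra`` describe the branched fs-ps
    scheme (for target-analysis and pump-dump-probe simulations);
    ``sequential_lifetimes``/``sequential_spectra`` the six- or
    seven-component sequential description (for global-analysis
    simulations); ``photocycle_*`` the microsecond-to-second flash
    photolysis chain.
    """

    ph: int
    irf: IRFModel
    target_scheme: KineticScheme
    target_spectra: SpeciesSpectrumModel
    sequential_lifetimes: tuple
    sequential_spectra: SpeciesSpectrumModel
    photocycle_scheme: KineticScheme
    photocycle_spectra: SpeciesSpectrumModel
    photocycle_lifetimes: tuple = _FLASH_LIFETIMES_PS

    @property
    def sequential_scheme(self) -> KineticScheme:
        from .varpro import sequential_scheme

        return sequential_scheme(self.sequential_lifetimes)


def c1c2_presets(ph: int = 8) -> C1C2Preset:
    """Preset kinetic schemes, spectra and IRF for pH 8 or pH 10.

    pH 8 carries six sequential components (0.45 ps, 2.0 ps, 11 ps,
    630 ps, 490 ns, infinity), pH 10 seven (..., 650 ps, 200 ns, 26 us,
    infinity); both share the branched fs target scheme with a K1
    quantum yield of 0.30 and a 150 fs (FWHM) Gaussian IRF.
    """
    if ph not in (8, 10):
        raise ValueError("presets exist for pH 8 and pH 10 only")
    return C1C2Preset(
        ph=ph,
        irf=IRFModel.from_fwhm(0.150),
        target_scheme=_fs_target_scheme(ph),
        target_spectra=SpeciesSpectrumModel(dict(_FS_SADS_BANDS)),
        sequential_lifetimes=_SEQ_LIFETIMES[ph],
        sequential_spectra=SpeciesSpectrumModel(dict(_SEQ_EADS_BANDS[ph])),
        photocycle_scheme=_photocycle_scheme(ph),
        photocycle_spectra=SpeciesSpectrumModel(dict(_FLASH_BANDS)),
    )


# ---------------------------------------------------------------------------
# forward simulation


def simulate_dataset(
    scheme: KineticScheme,
    spectra: SpeciesSpectrumModel,
    irf: IRFModel | None,
    times,
    wavelengths,
    noise: NoiseModel | None = None,
    mask_windows=((465.0, 495.0),),
    meta: dict | None = None,
) -> TADataset:
    """Forward model: dA = concentrations x spectra + noise.

    Compartments listed in ``scheme.dark`` contribute no signal.  The
    scheme's dump events, if any, are included in the propagation.
    ``mask_windows`` (nm intervals, default the 465-495 nm pump-scatter
    region) are zero-weighted, not removed.  The generating truth
    (scheme, spectra, clean matrix, absolute noise sigma) is bundled
    under ``meta['truth']`` for test harnesses.
    """
    times = np.asarray(times, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if scheme.dump_events:
        conc = apply_dump(scheme, irf, times)
    else:
        conc = concentration_profiles(scheme, irf, times)
    observed = [c for c in scheme.compartments if c not in scheme.dark]
    C = np.stack([conc[c] for c in observed], axis=1)
    S = spectra.matrix(observed, wavelengths)
    clean = C @ S
    sigma_abs = 0.0
    data = clean.copy()
    if noise is not None and noise.sigma > 0:
        sigma_abs = noise.sigma * np.abs(clean).max()
        rng = np.random.default_rng(noise.seed)
        data = clean + rng.normal(0.0, sigma_abs, size=clean.shape)
    ds = TADataset(
        times=times,
        wavelengths=wavelengths,
        delta_A=data,
        meta=dict(meta or {}),
    )
    for lo, hi in mask_windows or ():
        ds = ds.mask_wavelengths(lo, hi)
    ds.meta["truth"] = {
        "scheme": scheme,
        "spectra": spectra,
        "irf": irf,
        "observed": tuple(observed),
        "concentrations": conc,
        "clean": clean,
        "noise_sigma": sigma_abs,
        "noise": noise,
    }
    return ds
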