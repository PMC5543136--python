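"""Containers for difference-absorption data and analysis results."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TADataset", "SpectraSet", "FitResult"]


@dataclass
class TADataset:
    """A time-resolved difference-absorption matrix dA(t, lambda).

    Attributes
    ----------
    times:
        Delay grid in ps, strictly increasing.
    wavelengths:
        Probe wavelengths in nm, strictly increasing.
    delta_A:
        Matrix of shape (n_times, n_wavelengths); arbitrary amplitude
        units (typically mOD).
    weights:
        Nonnegative fit weights of the same shape; 0 marks masked cells
        (e.g. the pump-scatter window) which are ignored by every fit
        and statistic.
    meta:
        Free-form experiment metadata (pump/dump wavelengths, pH label,
        the dump event of a pump-dump-probe run, simulation ground
        truth, ...).
    """

    times: np.ndarray
    wavelengths: np.ndarray
    delta_A: np.ndarray
    weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if self.delta_A.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"delta_A shape {self.delta_A.shape} does not match axes "
                f"({self.times.size}, {self.wavelengths.size})"
            )
        for name, ax in (("times", self.times), ("wavelengths", self.wavelengths)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
        if self.weights is None:
            self.weights = np.ones_like(self.delta_A)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.delta_A.shape:
                raise ValueError("weights shape must match delta_A")
            if not np.all(np.isfinite(self.weights)) or (self.weights < 0).any():
                raise ValueError("weights must be finite and nonnegative")
        # NaN cells are masked data points, carried as zeros with zero weight
        bad = ~np.isfinite(self.delta_A)
        if bad.any():
            self.delta_A = np.where(bad, 0.0, self.delta_A)
            self.weights = np.where(bad, 0.0, self.weights)

    @property
    def shape(self) -> tuple:
        return self.delta_A.shape

    def mask_wavelengths(self, lo: float, hi: float) -> "TADataset":
        """Zero-weight all cells with lo <= wavelength <= hi (scatter window)."""
        w = self.weights.copy()
        w[:, (self.wavelengths >= lo) & (self.wavelengths <= hi)] = 0.0
        return replace(self, weights=w)

    def weighted_ssq(self, model: np.ndarray | None = None) -> float:
        resid = self.delta_A if model is None else self.delta_A - model
        return float(np.sum(self.weights * resid**2))

    def n_observed(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass
class SpectraSet:
    """A stack of component difference spectra on a common amplitude scale.

    ``kind`` distinguishes evolution-associated (EADS, sequential
    interpretation), decay-associated (DADS, parallel interpretation)
    and species-associated (SADS, target-scheme interpretation)
    difference spectra.  Amplitudes are tied to unit initial excitation.
    """

    kind: str
    wavelengths: np.ndarray
    spectra: np.ndarray  # (n_components, n_wavelengths)
    labels: tuple

    def __post_init__(self):
        if self.kind not in ("EADS", "DADS", "SADS"):
            raise ValueError(f"unknown spectra kind {self.kind!r}")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = tuple(self.labels)
        if self.spectra.shape != (len(self.labels), self.wavelengths.size):
            raise ValueError("spectra shape mismatch")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.spectra[self.labels.index(label)]

    def band_integral(self, label: str, lo: float, hi: float) -> float:
        """Trapezoidal integral of one spectrum over [lo, hi] nm."""
        sel = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if sel.sum() < 2:
            raise ValueError(f"window [{lo}, {hi}] nm contains < 2 grid points")
        return float(np.trapezoid(self.spectra[self.labels.index(label), sel],
                                  self.wavelengths[sel]))


@dataclass
class FitResult:
    """Outcome of a global or target fit.

    ``params``/``stderr`` hold the free nonlinear parameters (rates or
    lifetimes in ps, IRF center/width, dump fractions) on their natural
    scale.  ``spectra`` maps kind -> SpectraSet.  ``extra`` carries
    derived quantities (terminal yields, branching, diagnostics).
    """

    params: dict
    stderr: dict
    spectra: dict
    residuals: list  # one weighted-residual matrix per dataset
    ssq: float
    dof: int
    success: bool = True
    message: str = ""
    lifetimes: np.ndarray | None = None
    lifetime_stderr: np.ndarray | None = None
    irf: object | None = None
    scheme: object | None = None
    datasets: list = field(default_factory=list)
    concentrations: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def reduced_chi2(self) -> float:
        return self.ssq / max(self.dof, 1)

    def summary(self) -> str:
        lines = [f"fit: ssq={self.ssq:.6g}, chi2/dof={self.reduced_chi2:.4g}, "
                 f"success={self.success}"]
        for name, val in self.params.items():
            err = self.stderr.get(name, float("nan"))
            lines.append(f"  {name} = {val:.6g} +/- {err:.3g}")
        if self.lifetimes is not None:
            taus = ", ".join(f"{t:.4g}" for t in self.lifetimes)
            lines.append(f"  lifetimes (ps, ascending): {taus}")
        for key, val in self.extra.items():
            if np.isscalar(val):
                lines.append(f"  {key} = {val}")
        return "\n".join(lines)
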