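"""Target analysis: fitting difference-absorption data with an explicit
kinetic scheme.

Unlike the generic sequential/parallel description, a target fit
estimates microscopic rate constants, branching and dump-transfer
fractions of a physically interpreted compartment scheme, and returns
species-associated difference spectra (SADS) on the unit-excitation
scale.  Several datasets (pump-probe plus pump-dump-probe, H2O plus
D2O) can be fitted jointly with shared kinetics and shared SADS; only
dump transfer fractions are specific to the multi-pulse data.

Because the data constrain only the product of a photoproduct's yield
and its spectral amplitude, branching into the photoproduct is fixed by
the spectral equal-bleach constraint: the ground-state-bleach amplitude
integrated over a bleach window must be (roughly) common to the excited
states and the photoproduct.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .datasets import FitResult, SpectraSet, TADataset
from .kinetics import apply_dump, concentration_profiles
from .schemes import DumpEvent, IRFModel, KineticScheme, terminal_yields
from .varpro import IdentifiabilityError, _solve_projection, standard_errors_from_jacobian

__all__ = [
    "fit_target",
    "apply_bleach_constraint",
    "quantum_yield_from_fit",
]


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _TargetModel:
    """Maps a flat parameter vector onto schemes, dump events and IRFs."""

    def __init__(self, datasets, scheme, free_rates, free_dump, irfs, fit_irf):
        self.datasets = datasets
        self.scheme = scheme
        self.free_rates = [tuple(e) for e in free_rates]
        self.free_dump = [tuple(e) for e in free_dump]
        self.fit_irf = fit_irf
        if irfs is None or isinstance(irfs, IRFModel):
            irfs = [irfs] * len(datasets)
        self.irfs = list(irfs)
        for edge in self.free_rates:
            if edge not in scheme.rates:
                raise IdentifiabilityError(f"free rate {edge} is not an edge of the scheme")
        self.dump_inits = {}
        for ds in datasets:
            for ev in ds.meta.get("dump_events", ()):
                for src, dst, f in ev.transfers:
                    if (src, dst) in self.free_dump:
                        self.dump_inits[(src, dst)] = f
        for edge in self.free_dump:
            if edge not in self.dump_inits:
                raise IdentifiabilityError(
                    f"free dump transfer {edge} appears in no dataset"
                )

    @property
    def names(self):
        out = [f"k:{s}->{d}" for s, d in self.free_rates]
        out += [f"f:{s}->{d}" for s, d in self.free_dump]
        if self.fit_irf:
            for i in range(len(self.datasets)):
                out += [f"irf{i}_center", f"irf{i}_width"]
        return out

    def x0(self) -> np.ndarray:
        x = [np.log(self.scheme.rates[e]) for e in self.free_rates]
        x += [_logit(self.dump_inits[e]) for e in self.free_dump]
        if self.fit_irf:
            for irf in self.irfs:
                x += [irf.center, np.log(irf.width)]
        return np.array(x)

    def unpack(self, x):
        nr, nd = len(self.free_rates), len(self.free_dump)
        scheme = self.scheme.with_rates(
            {e: np.exp(x[i]) for i, e in enumerate(self.free_rates)}
        )
        fracs = {e: _sigmoid(x[nr + i]) for i, e in enumerate(self.free_dump)}
        irfs = list(self.irfs)
        if self.fit_irf:
            for i in range(len(self.datasets)):
                mu, ls = x[nr + nd + 2 * i], x[nr + nd + 2 * i + 1]
                irfs[i] = IRFModel(center=mu, width=np.exp(ls))
        return scheme, fracs, irfs

    def concentrations(self, x):
        """Per-dataset populations of the observed (non-dark) compartments."""
        scheme, fracs, irfs = self.unpack(x)
        observed = [c for c in scheme.compartments if c not in scheme.dark]
        blocks = []
        for ds, irf in zip(self.datasets, irfs):
            events = []
            for ev in ds.meta.get("dump_events", ()):
                transfers = [
                    (s, d, fracs.get((s, d), f)) for s, d, f in ev.transfers
                ]
                events.append(DumpEvent(ev.time, transfers))
            sch_d = scheme.with_dump_events(events)
            if events:
                conc = apply_dump(sch_d, irf, ds.times)
            else:
                conc = concentration_profiles(sch_d, irf, ds.times)
            blocks.append(np.stack([conc[c] for c in observed], axis=1))
        return observed, blocks


def _stack(datasets, blocks):
    C = np.concatenate(blocks, axis=0)
    D = np.concatenate([ds.delta_A for ds in datasets], axis=0)
    W = np.concatenate([ds.weights for ds in datasets], axis=0)
    return C, D, W


def _bleach_integrals(spectra: SpectraSet, components, window):
    lo, hi = window
    return np.array([spectra.band_integral(c, lo, hi) for c in components])


def _penalty_covariance(C, W, wl, window, observed, comps, weight, s2):
    """Noise covariance of the penalty residuals w (A_i - mean A).

    The bleach integrals A_i are linear in the projected spectra, whose
    per-wavelength covariance under unit-variance-s2 noise is
    s2 (C^T diag(w) C)^-1; wavelengths are independent.  Needed for a
    sandwich parameter covariance: the penalty rows are not
    constant-variance observations like the data cells.
    """
    sel = np.nonzero((wl >= window[0]) & (wl <= window[1]))[0]
    # trapezoid quadrature weights on the window grid
    x = wl[sel]
    u = np.zeros(sel.size)
    u[:-1] += 0.5 * np.diff(x)
    u[1:] += 0.5 * np.diff(x)
    idx = [observed.index(c) for c in comps]
    covA = np.zeros((len(idx), len(idx)))
    for j, col in enumerate(sel):
        w = W[:, col]
        if not w.any():
            continue
        G = np.linalg.pinv(C.T @ (w[:, None] * C))
        covA += u[j] ** 2 * s2 * G[np.ix_(idx, idx)]
    n = len(idx)
    M = np.eye(n) - np.full((n, n), 1.0 / n)
    return weight**2 * M @ covA @ M.T


def _check_sensitivity_rank(model: _TargetModel, x0: np.ndarray):
    """Structural identifiability screen at the initial point.

    Finite-difference sensitivities of the (weighted) concentration
    blocks with respect to every free parameter; a numerically null
    singular direction means the requested parameter combination cannot
    move the model and is reported by name.
    """
    if x0.size == 0:
        return
    _, blocks0 = model.concentrations(x0)
    base = np.concatenate([b.ravel() for b in blocks0])
    cols = []
    for i in range(x0.size):
        xp = x0.copy()
        h = 1e-5 * max(1.0, abs(x0[i]))
        xp[i] += h
        _, blocks = model.concentrations(xp)
        cols.append((np.concatenate([b.ravel() for b in blocks]) - base) / h)
    Smat = np.stack(cols, axis=1)
    sv = np.linalg.svd(Smat, compute_uv=False)
    if sv[0] == 0 or sv[-1] < 1e-10 * sv[0]:
        _, _, vt = np.linalg.svd(Smat)
        null = vt[-1]
        names = model.names
        terms = [
            f"{null[i]:+.2f}*{names[i]}" for i in np.argsort(-np.abs(null))[:3]
        ]
        raise IdentifiabilityError(
            "structurally unidentifiable parameter combination; null-space "
            "direction: " + " ".join(terms)
        )


def fit_target(
    datasets,
    scheme: KineticScheme,
    *,
    free_rates=(),
    free_dump=(),
    irfs=None,
    fit_irf: bool = False,
    bleach_window=None,
    bleach_components=None,
    bleach_weight: float = 1.0,
    n_starts: int = 1,
    seed: int = 0,
    jitter_factor: float = 3.0,
) -> FitResult:
    """Scheme-based global fit returning SADS and microscopic rates.

    Parameters
    ----------
    datasets:
        One :class:`TADataset` or a list sharing a wavelength grid.
        Pump-dump-probe datasets carry their dump events in
        ``meta['dump_events']``.
    scheme:
        The kinetic scheme; its current rates serve as initial values.
    free_rates:
        Edges ``(src, dst)`` whose rate constants are optimized (in log
        space).
    free_dump:
        Dump transfers ``(src, dst)`` whose fractions are optimized (in
        logit space, shared across datasets).
    irfs:
        A single shared :class:`IRFModel`, one per dataset, or None for
        delta excitation.
    bleach_window:
        Optional ``(lo, hi)`` nm window activating the equal-bleach
        penalty over ``bleach_components`` (default: the scheme's
        excited compartments plus photoproducts) with strength
        ``bleach_weight``.
    """
    if isinstance(datasets, TADataset):
        datasets = [datasets]
    wl = datasets[0].wavelengths
    for ds in datasets[1:]:
        if not np.array_equal(ds.wavelengths, wl):
            raise ValueError("joint fits require a common wavelength grid")

    model = _TargetModel(datasets, scheme, free_rates, free_dump, irfs, fit_irf)
    x0 = model.x0()
    _check_sensitivity_rank(model, x0)

    if bleach_window is not None:
        comps = tuple(bleach_components or (scheme.excited + scheme.photoproduct))
        if not comps:
            raise ValueError("no components for the bleach constraint")
        lo, hi = bleach_window
        if not ((wl >= lo) & (wl <= hi)).sum() >= 2:
            raise ValueError(
                f"bleach window [{lo}, {hi}] nm contains no wavelength grid points"
            )

    sqw_all = [np.sqrt(ds.weights) for ds in datasets]

    def residual(x):
        observed, blocks = model.concentrations(x)
        C, D, W = _stack(datasets, blocks)
        S = _solve_projection(C, D, W)
        parts = []
        row = 0
        for ds, sqw in zip(datasets, sqw_all):
            n = ds.times.size
            parts.append((sqw * (ds.delta_A - blocks.pop(0) @ S)).ravel())
            row += n
        if bleach_window is not None and bleach_weight > 0:
            spec = SpectraSet("SADS", wl, S, observed)
            A = _bleach_integrals(spec, comps, bleach_window)
            # normalized spread: dimensionless, gentle on identifiable
            # directions, decisive on spectrally degenerate ridges
            parts.append(bleach_weight * (A - A.mean()) / max(abs(A.mean()), 1e-300))
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        x_init = x0.copy()
        if start > 0 and x_init.size:
            x_init += rng.uniform(
                -np.log(jitter_factor), np.log(jitter_factor), size=x_init.size
            )
        try:
            sol = least_squares(
                residual, x_init, method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-10
            )
        except (RuntimeError, np.linalg.LinAlgError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")
    sol = best

    fitted_scheme, fracs, fitted_irfs = model.unpack(sol.x)
    observed, blocks = model.concentrations(sol.x)
    C, D, W = _stack(datasets, blocks)
    S = _solve_projection(C, D, W)
    sads = SpectraSet("SADS", wl, S, observed)
    residuals, ssq = [], 0.0
    for ds, block in zip(datasets, blocks):
        r = ds.delta_A - block @ S
        residuals.append(r)
        ssq += float(np.sum(ds.weights * r**2))
    n_lin = len(observed) * wl.size
    dof = sum(ds.n_observed() for ds in datasets) - sol.x.size - n_lin
    err_x, cov = standard_errors_from_jacobian(sol.jac, ssq, dof)
    if bleach_window is not None and bleach_weight > 0 and np.all(np.isfinite(cov)):
        # sandwich covariance: penalty rows carry noise through the
        # projected bleach integrals, not the constant data variance
        s2 = ssq / max(dof, 1)
        n_pen = len(comps)
        Jd, Jp = sol.jac[:-n_pen], sol.jac[-n_pen:]
        A_opt = _bleach_integrals(sads, comps, bleach_window)
        pen_cov = _penalty_covariance(
            C, W, wl, bleach_window, observed, comps, bleach_weight, s2
        ) / max(abs(A_opt.mean()), 1e-300) ** 2
        bread = np.linalg.pinv(sol.jac.T @ sol.jac)
        meat = s2 * (Jd.T @ Jd) + Jp.T @ pen_cov @ Jp
        cov = bread @ meat @ bread
        err_x = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    names = model.names
    params, stderr = {}, {}
    nr, nd = len(model.free_rates), len(model.free_dump)
    for i, name in enumerate(names):
        if i < nr:
            k = fitted_scheme.rates[model.free_rates[i]]
            params[name], stderr[name] = k, k * err_x[i]
        elif i < nr + nd:
            f = fracs[model.free_dump[i - nr]]
            params[name], stderr[name] = f, f * (1 - f) * err_x[i]
        elif name.endswith("center"):
            params[name], stderr[name] = sol.x[i], err_x[i]
        else:
            params[name] = np.exp(sol.x[i])
            stderr[name] = params[name] * err_x[i]

    # dump events as fitted, attached per dataset for reproducibility
    fitted_events = []
    for ds in datasets:
        evs = [
            DumpEvent(ev.time, [(s, d, fracs.get((s, d), f)) for s, d, f in ev.transfers])
            for ev in ds.meta.get("dump_events", ())
        ]
        fitted_events.append(tuple(evs))

    extra = {
        "cov_x": cov,
        "param_names": names,
        "opt_x": sol.x,
        "observed": tuple(observed),
        "fitted_dump_events": fitted_events,
        "call": dict(
            free_rates=tuple(model.free_rates),
            free_dump=tuple(model.free_dump),
            irfs=irfs,
            fit_irf=fit_irf,
            n_starts=n_starts,
            seed=seed,
            jitter_factor=jitter_factor,
        ),
    }
    if bleach_window is not None:
        A = _bleach_integrals(sads, comps, bleach_window)
        extra["bleach_integrals"] = dict(zip(comps, A))
        extra["bleach_spread"] = float(np.ptp(A) / max(abs(A.mean()), 1e-300))

    fit = FitResult(
        params=params,
        stderr=stderr,
        spectra={"SADS": sads},
        residuals=residuals,
        ssq=ssq,
        dof=dof,
        success=bool(sol.success),
        message=str(sol.message),
        irf=fitted_irfs[0] if len(fitted_irfs) == 1 else fitted_irfs,
        scheme=fitted_scheme,
        datasets=list(datasets),
        extra=extra,
    )
    fit.extra["yields"] = quantum_yield_from_fit(fit)
    return fit


def apply_bleach_constraint(
    fit: FitResult,
    bleach_window=(430.0, 465.0),
    components=None,
    weight: float = 1.0,
) -> FitResult:
    """Re-fit a target result under the equal-bleach spectral constraint.

    Adds a penalty equalizing the integrated SADS amplitude over the
    bleach window across the excited states and the photoproduct(s),
    which pins the otherwise spectrally degenerate photoproduct yield.
    The returned result records the pre- and post-constraint amplitude
    spread in ``extra['bleach_spread_pre'/'bleach_spread']``.
    """
    if fit.scheme is None:
        raise ValueError("apply_bleach_constraint requires a target-analysis fit")
    comps = tuple(
        components or (fit.scheme.excited + fit.scheme.photoproduct)
    )
    if not comps:
        raise ValueError("no components to constrain")
    lo, hi = bleach_window
    wl = fit.datasets[0].wavelengths
    if ((wl >= lo) & (wl <= hi)).sum() < 2:
        raise ValueError(
            f"bleach window [{lo}, {hi}] nm contains no wavelength grid points"
        )
    sads = fit.spectra["SADS"]
    A_pre = _bleach_integrals(sads, comps, bleach_window)
    call = fit.extra["call"]
    refit = fit_target(
        fit.datasets,
        fit.scheme,
        free_rates=call["free_rates"],
        free_dump=call["free_dump"],
        irfs=call["irfs"],
        fit_irf=call["fit_irf"],
        bleach_window=bleach_window,
        bleach_components=comps,
        bleach_weight=weight,
        n_starts=call["n_starts"],
        seed=call["seed"],
        jitter_factor=call["jitter_factor"],
    )
    refit.extra["bleach_spread_pre"] = float(
        np.ptp(A_pre) / max(abs(A_pre.mean()), 1e-300)
    )
    return refit


def quantum_yield_from_fit(fit: FitResult, n_sigma_clip: float = 0.0) -> dict:
    """Terminal yields of the fitted scheme with delta-method uncertainties.

    Returns ``{terminal: (yield, stderr)}``.  The uncertainty propagates
    the covariance of the free rate parameters through a numerical
    gradient of the absorbing-state probabilities; dump and IRF
    parameters do not enter the undumped yields.
    """
    if fit.scheme is None:
        raise ValueError("quantum_yield_from_fit requires a target-analysis fit")
    scheme = fit.scheme
    y0 = terminal_yields(scheme)
    names = fit.extra.get("param_names", [])
    cov = fit.extra.get("cov_x")
    out = {}
    rate_idx = [i for i, nm in enumerate(names) if nm.startswith("k:")]
    if cov is None or not rate_idx or not np.all(np.isfinite(cov)):
        return {t: (v, np.nan) for t, v in y0.items()}
    x = fit.extra["opt_x"]
    grads = {t: np.zeros(len(rate_idx)) for t in y0}
    call_edges = list(fit.extra["call"]["free_rates"])
    for j, i in enumerate(rate_idx):
        h = 1e-6
        edge = call_edges[j]
        pert = scheme.with_rates({edge: scheme.rates[edge] * np.exp(h)})
        yp = terminal_yields(pert)
        for t in y0:
            grads[t][j] = (yp[t] - y0[t]) / h
    sub = cov[np.ix_(rate_idx, rate_idx)]
    for t, v in y0.items():
        var = float(grads[t] @ sub @ grads[t])
        out[t] = (v, np.sqrt(max(var, 0.0)))
    return out
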