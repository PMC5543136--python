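"""Variable-projection global analysis of difference-absorption matrices.

The bilinear model dA(t, l) = sum_i c_i(t) s_i(l) is fitted by separable
least squares: for any trial of the nonlinear parameters (lifetimes, IRF)
the spectra are eliminated by weighted linear projection, and only the
nonlinear parameters are iterated.  Sequential chains give
evolution-associated spectra (EADS); the mathematically equivalent
parallel sum-of-exponentials description gives decay-associated spectra
(DADS), connected by an exact triangular basis change.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import least_squares

from .datasets import FitResult, SpectraSet, TADataset
from .kinetics import ConcentrationMatrix, Propagator
from .schemes import IRFModel, KineticScheme

__all__ = [
    "IdentifiabilityError",
    "sequential_scheme",
    "project_spectra",
    "fit_sequential",
    "dads_from_eads",
    "eads_from_dads",
    "sequential_to_parallel_matrix",
    "standard_errors_from_jacobian",
    "svd_residual_diagnostics",
]


class IdentifiabilityError(ValueError):
    """Raised when the requested components cannot be distinguished by the data."""


def sequential_scheme(lifetimes, labels=None) -> KineticScheme:
    """Unbranched chain S1 -> S2 -> ... with the given lifetimes (ps).

    The last lifetime may be ``inf``: the final compartment is then a
    non-decaying terminal (the "infinity" component of a global fit).
    A finite last lifetime decays out of the modelled system.
    """
    lifetimes = [float(t) for t in lifetimes]
    if any(t <= 0 for t in lifetimes):
        raise ValueError("lifetimes must be positive")
    n = len(lifetimes)
    if labels is None:
        labels = tuple(f"S{i + 1}" for i in range(n))
    rates, terminal = {}, []
    for i, tau in enumerate(lifetimes):
        if np.isinf(tau):
            if i != n - 1:
                raise ValueError("only the last component may be non-decaying")
            terminal.append(labels[i])
        elif i < n - 1:
            rates[(labels[i], labels[i + 1])] = 1.0 / tau
        else:
            # final finite component decays to an implicit, unobserved sink
            sink = "_sink"
            labels = tuple(labels) + (sink,)
            rates[(labels[i], sink)] = 1.0 / tau
            terminal.append(sink)
            return KineticScheme(
                compartments=labels,
                rates=rates,
                input_weights={labels[0]: 1.0},
                terminal=tuple(terminal),
                dark=(sink,),
                name="sequential",
            )
    return KineticScheme(
        compartments=tuple(labels),
        rates=rates,
        input_weights={labels[0]: 1.0},
        terminal=tuple(terminal),
        name="sequential",
    )


# ---------------------------------------------------------------------------
# linear projection


def _solve_projection(C: np.ndarray, D: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Weighted per-wavelength least squares for the spectral amplitudes.

    Columns sharing a weight pattern (the common case: fully masked
    scatter columns vs. uniformly weighted ones) are solved in one
    factorization.
    """
    S = np.zeros((C.shape[1], D.shape[1]))
    groups: dict[bytes, list[int]] = {}
    for j in range(D.shape[1]):
        groups.setdefault(W[:, j].tobytes(), []).append(j)
    for cols in groups.values():
        w = W[:, cols[0]]
        if not w.any():
            continue  # fully masked column: spectrum stays zero
        sw = np.sqrt(w)[:, None]
        sol, *_ = np.linalg.lstsq(C * sw, D[:, cols] * sw, rcond=None)
        S[:, cols] = sol
    return S


def _collinear_pairs(C: np.ndarray, labels, tol: float = 1e-8) -> list:
    norms = np.linalg.norm(C, axis=0)
    norms[norms == 0] = 1.0
    G = (C / norms).T @ (C / norms)
    pairs = []
    for i in range(C.shape[1]):
        for j in range(i + 1, C.shape[1]):
            if abs(G[i, j]) > 1 - tol:
                pairs.append((labels[i], labels[j]))
    return pairs


def project_spectra(
    dataset: TADataset,
    concentrations: ConcentrationMatrix | np.ndarray,
    labels=None,
    kind: str = "SADS",
):
    """Spectra given fixed concentrations, by weighted linear least squares.

    Returns ``(SpectraSet, residual_matrix)``.  The residual matrix is
    unweighted (data minus model); masked cells are zero by
    construction of the weights.  Raises :class:`IdentifiabilityError`
    when the concentration columns are numerically rank-deficient,
    naming the collinear component pairs.
    """
    if isinstance(concentrations, ConcentrationMatrix):
        C = concentrations.values
        labels = labels or concentrations.labels
    else:
        C = np.asarray(concentrations, dtype=float)
        labels = labels or tuple(f"c{i + 1}" for i in range(C.shape[1]))
    if C.shape[0] != dataset.times.size:
        raise ValueError("concentration rows must match the delay axis")
    wmean = np.sqrt(dataset.weights.mean(axis=1))[:, None]
    rank = np.linalg.matrix_rank(C * wmean)
    if rank < C.shape[1]:
        pairs = _collinear_pairs(C * wmean, labels)
        raise IdentifiabilityError(
            f"concentration matrix rank {rank} < {C.shape[1]} components; "
            "collinear pairs: "
            + (", ".join(f"{a}~{b}" for a, b in pairs) or "<none isolated>")
        )
    S = _solve_projection(C, dataset.delta_A, dataset.weights)
    resid = dataset.delta_A - C @ S
    spectra = SpectraSet(
        kind=kind, wavelengths=dataset.wavelengths, spectra=S, labels=labels
    )
    return spectra, resid


# ---------------------------------------------------------------------------
# sequential <-> parallel basis change


def sequential_to_parallel_matrix(lifetimes) -> np.ndarray:
    """Matrix B with C_seq = Phi @ B, Phi the parallel decay kernels.

    Classical closed form for an unbranched chain with distinct rates
    k_i = 1/tau_i (an infinite lifetime enters as rate 0)::

        B[j, l] = prod_{m<l} k_m / prod_{m<=l, m!=j} (k_m - k_j),  j <= l.

    The same matrix converts between the two spectra bases:
    DADS = B @ EADS.
    """
    k = np.array([0.0 if np.isinf(t) else 1.0 / t for t in lifetimes])
    n = k.size
    if np.unique(k).size != n:
        raise ValueError("rates must be distinct for the sequential/parallel map")
    B = np.zeros((n, n))
    for l in range(n):
        num = np.prod(k[:l]) if l else 1.0
        for j in range(l + 1):
            den = 1.0
            for m in range(l + 1):
                if m != j:
                    den *= k[m] - k[j]
            B[j, l] = num / den
    return B


def dads_from_eads(eads: SpectraSet, lifetimes) -> SpectraSet:
    """Exact linear transformation from sequential to parallel spectra."""
    B = sequential_to_parallel_matrix(lifetimes)
    return SpectraSet(
        kind="DADS",
        wavelengths=eads.wavelengths,
        spectra=B @ eads.spectra,
        labels=eads.labels,
    )


def eads_from_dads(dads: SpectraSet, lifetimes) -> SpectraSet:
    """Inverse transformation (B is upper triangular; solved exactly)."""
    B = sequential_to_parallel_matrix(lifetimes)
    E = solve_triangular(B, dads.spectra, lower=False)
    return SpectraSet(
        kind="EADS",
        wavelengths=dads.wavelengths,
        spectra=E,
        labels=dads.labels,
    )


# ---------------------------------------------------------------------------
# nonlinear sequential fit


def _chain_concentrations(taus, irf, times, n_obs):
    scheme = sequential_scheme(taus)
    C = Propagator(scheme, irf).profiles(times)
    return C[:, :n_obs]  # drop the implicit sink, if any


def standard_errors_from_jacobian(jac: np.ndarray, ssq: float, dof: int):
    """Linearized parameter covariance at the optimum.

    Returns ``(stderr, cov)`` with infinite errors where the normal
    matrix is singular (flat/unidentifiable directions).
    """
    JTJ = jac.T @ jac
    s2 = ssq / max(dof, 1)
    try:
        cov = np.linalg.inv(JTJ) * s2
        err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full_like(JTJ, np.nan)
        err = np.full(JTJ.shape[0], np.inf)
    return err, cov


def fit_sequential(
    dataset: TADataset,
    init_lifetimes,
    irf_init: IRFModel | None = None,
    *,
    fit_irf: bool = True,
    n_starts: int = 8,
    seed: int = 0,
    jitter_factor: float = 3.0,
) -> FitResult:
    """Sequential (1 -> 2 -> ...) global fit by variable projection.

    Optimizes the chain lifetimes (in log space, keeping them positive
    across a 450 fs .. 26 us dynamic range) and optionally the Gaussian
    IRF center/width; at every iterate the component spectra are
    eliminated by weighted projection.  ``init_lifetimes`` may end in
    ``inf`` for a final non-decaying component.  ``n_starts`` runs are
    launched from multiplicatively jittered initializations (factor
    ``jitter_factor`` around the init, fixed seed) and the best weighted
    sum of squares wins.  Returns both EADS and DADS; the fitted time
    constants apply to both, and are reported sorted ascending.
    """
    init_lifetimes = [float(t) for t in init_lifetimes]
    finite = [t for t in init_lifetimes if np.isfinite(t)]
    has_inf = len(finite) < len(init_lifetimes)
    if has_inf and not np.isinf(init_lifetimes[-1]):
        raise ValueError("the non-decaying component must be last")
    if len(set(finite)) != len(finite):
        raise ValueError("initial lifetimes must be distinct")
    n_comp = len(init_lifetimes)
    do_irf = fit_irf and irf_init is not None

    times, D, W = dataset.times, dataset.delta_A, dataset.weights
    sqw = np.sqrt(W)

    def unpack(x):
        taus = list(np.exp(x[: len(finite)]))
        if has_inf:
            taus.append(np.inf)
        if do_irf:
            irf = IRFModel(center=x[-2], width=np.exp(x[-1]))
        else:
            irf = irf_init
        return taus, irf

    def residual(x):
        taus, irf = unpack(x)
        C = _chain_concentrations(taus, irf, times, n_comp)
        S = _solve_projection(C, D, W)
        return (sqw * (D - C @ S)).ravel()

    x0 = np.log(finite)
    if do_irf:
        x0 = np.concatenate([x0, [irf_init.center, np.log(irf_init.width)]])

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        x_init = x0.copy()
        if start > 0:
            x_init[: len(finite)] += rng.uniform(
                -np.log(jitter_factor), np.log(jitter_factor), size=len(finite)
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

    taus, irf = unpack(best.x)
    # relabel by ascending lifetime at convergence only; the parallel
    # (DADS) basis is order-free, so the weighted SSQ is unchanged
    order = np.argsort(taus[: len(finite)])
    sorted_taus = [taus[i] for i in order] + ([np.inf] if has_inf else [])
    x_sorted = np.concatenate(
        [np.log([sorted_taus[i] for i in range(len(finite))]), best.x[len(finite):]]
    )
    sol = least_squares(
        residual, x_sorted, method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-10
    )
    taus, irf = unpack(sol.x)

    C = _chain_concentrations(taus, irf, times, n_comp)
    S = _solve_projection(C, D, W)
    resid = D - C @ S
    ssq = float(np.sum(W * resid**2))
    n_lin = n_comp * dataset.wavelengths.size
    dof = dataset.n_observed() - sol.x.size - n_lin
    err_x, cov = standard_errors_from_jacobian(sol.jac, 2 * sol.cost, dof)

    labels = tuple(f"EADS{i + 1}" for i in range(n_comp))
    eads = SpectraSet("EADS", dataset.wavelengths, S, labels)
    dads = SpectraSet(
        "DADS",
        dataset.wavelengths,
        sequential_to_parallel_matrix(taus) @ S,
        labels=tuple(f"DADS{i + 1}" for i in range(n_comp)),
    )

    params, stderr = {}, {}
    tau_err = []
    for i in range(len(finite)):
        params[f"tau{i + 1}"] = taus[i]
        stderr[f"tau{i + 1}"] = taus[i] * err_x[i]  # delta method from log space
        tau_err.append(taus[i] * err_x[i])
    if has_inf:
        params[f"tau{n_comp}"] = np.inf
    if do_irf:
        params["irf_center"] = irf.center
        stderr["irf_center"] = err_x[-2]
        params["irf_width"] = irf.width
        stderr["irf_width"] = irf.width * err_x[-1]

    at_bound = ~np.isfinite(err_x)
    return FitResult(
        params=params,
        stderr=stderr,
        spectra={"EADS": eads, "DADS": dads},
        residuals=[resid],
        ssq=ssq,
        dof=dof,
        success=bool(sol.success),
        message=str(sol.status) if sol.success else sol.message,
        lifetimes=np.array(taus),
        lifetime_stderr=np.array(tau_err + ([np.nan] if has_inf else [])),
        irf=irf,
        datasets=[dataset],
        concentrations=[ConcentrationMatrix(times, labels, np.clip(C, 0, None))],
        extra={"n_starts": n_starts, "flat_directions": int(at_bound.sum()),
               "opt_jac": sol.jac, "opt_x": sol.x},
    )


def svd_residual_diagnostics(fit: FitResult, n_vectors: int = 3) -> dict:
    """Singular-value screen of the residual matrix for fit adequacy.

    For an adequate fit the residual is unstructured noise, whose first
    singular value is close to the Marchenko-Pastur edge
    sigma (sqrt(m) + sqrt(n)); values beyond twice that expectation
    indicate unmodelled structure (e.g. a missing component).  The noise
    sigma is estimated from first differences along the wavelength axis,
    which is blind to spectrally smooth structure and so does not let an
    inadequate fit inflate its own acceptance threshold.  Masked cells
    are zero in the residual matrix and excluded from the noise
    estimate.
    """
    out = []
    for resid, ds in zip(fit.residuals, fit.datasets):
        obs = ds.weights > 0
        R = np.where(obs, resid, 0.0)
        u, s, vt = np.linalg.svd(R, full_matrices=False)
        pair = obs[:, 1:] & obs[:, :-1]
        diffs = (R[:, 1:] - R[:, :-1])[pair]
        sigma = float(diffs.std() / np.sqrt(2)) if diffs.size else 0.0
        m, n = R.shape
        expected = sigma * (np.sqrt(m) + np.sqrt(n))
        out.append(
            {
                "singular_values": s,
                "left_vectors": u[:, :n_vectors],
                "right_vectors": vt[:n_vectors],
                "noise_sigma": sigma,
                "expected_first": expected,
                "ratio": float(s[0] / expected) if expected > 0 else np.inf,
                "structured": bool(expected > 0 and s[0] > 2 * expected),
            }
        )
    return out[0] if len(out) == 1 else {"datasets": out}
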