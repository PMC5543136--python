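"""Compartmental kinetic schemes for photoreaction modelling.

A :class:`KineticScheme` is a first-order rate network over named
compartments (excited states, photoproduct intermediates, the ground
state), with optional branching, reversible edges, instantaneous dump
events and an instrument-response model for the excitation pulse.  All
rate constants are stored in reciprocal picoseconds; the helpers in
:mod:`takinetics.io` convert declared units on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KineticScheme",
    "DumpEvent",
    "IRFModel",
    "SchemeError",
    "build_rate_matrix",
    "branching_probabilities",
    "terminal_yields",
    "absorption_matrix",
]

#: multiply a value in ``unit`` by this to obtain picoseconds
UNIT_TO_PS = {
    "fs": 1e-3,
    "ps": 1.0,
    "ns": 1e3,
    "us": 1e6,
    "µs": 1e6,
    "ms": 1e9,
    "s": 1e12,
}

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class SchemeError(ValueError):
    """Raised for structurally invalid kinetic schemes or dump events."""


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: excitation profile of the pump pulse.

    Parameters
    ----------
    center:
        Time-zero offset mu in ps.
    width:
        Gaussian standard deviation sigma in ps (must be positive).
    """

    center: float = 0.0
    width: float = 0.05

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError(f"IRF width must be positive, got {self.width}")

    @property
    def fwhm(self) -> float:
        return self.width * FWHM_PER_SIGMA

    @classmethod
    def from_fwhm(cls, fwhm: float, center: float = 0.0) -> "IRFModel":
        return cls(center=center, width=fwhm / FWHM_PER_SIGMA)


@dataclass(frozen=True)
class DumpEvent:
    """Instantaneous population transfer triggered by a dump pulse.

    ``transfers`` is a sequence of ``(source, destination, fraction)``:
    at ``time`` the source compartment loses ``fraction`` of its current
    population to the destination.  Fractions for a shared source must
    not sum above 1.
    """

    time: float
    transfers: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "transfers", tuple(tuple(t) for t in self.transfers))
        per_source: dict[str, float] = {}
        for src, dst, frac in self.transfers:
            if not (0.0 <= frac <= 1.0):
                raise SchemeError(
                    f"dump transfer fraction {src}->{dst} = {frac} outside [0, 1]"
                )
            per_source[src] = per_source.get(src, 0.0) + frac
        for src, tot in per_source.items():
            if tot > 1.0 + 1e-12:
                raise SchemeError(
                    f"dump transfers from {src} sum to {tot:.3g} > 1"
                )


@dataclass(frozen=True)
class KineticScheme:
    """First-order compartmental network with branching and dump events.

    Attributes
    ----------
    compartments:
        Ordered labels, e.g. ``("ES1", "ES2", "ES3", "K1", "GSI", "GS")``.
    rates:
        Mapping ``(source, destination) -> rate constant`` in 1/ps.
    input_weights:
        Initial excitation fraction per compartment; normalized to 1.
    terminal:
        Labels declared absorbing.  Compartments without outgoing edges
        are treated as absorbing whether or not they are listed here.
    dump_events:
        Instantaneous transfers applied during propagation.
    dark:
        Compartments with identically zero difference spectrum (the
        recovered ground state in difference-absorption data).
    excited, photoproduct:
        Role annotations used by the multi-pulse accounting.
    """

    compartments: tuple
    rates: dict
    input_weights: dict
    terminal: tuple = ()
    dump_events: tuple = ()
    dark: tuple = ()
    excited: tuple = ()
    photoproduct: tuple = ()
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "terminal", tuple(self.terminal))
        object.__setattr__(self, "dump_events", tuple(self.dump_events))
        object.__setattr__(self, "dark", tuple(self.dark))
        object.__setattr__(self, "excited", tuple(self.excited))
        object.__setattr__(self, "photoproduct", tuple(self.photoproduct))
        known = set(self.compartments)
        if len(known) != len(self.compartments):
            raise SchemeError("duplicate compartment labels")
        for (src, dst), k in self.rates.items():
            if src not in known or dst not in known:
                raise SchemeError(
                    f"rate edge {src} -> {dst} references an unknown compartment"
                )
            if k < 0:
                raise SchemeError(f"negative rate constant on edge {src} -> {dst}")
        for grp in (self.terminal, self.dark, self.excited, self.photoproduct):
            for label in grp:
                if label not in known:
                    raise SchemeError(f"unknown compartment label {label!r}")
        for label in self.terminal:
            if any(src == label and k > 0 for (src, _), k in self.rates.items()):
                raise SchemeError(
                    f"terminal compartment {label} has outgoing edges"
                )
        w = {c: float(self.input_weights.get(c, 0.0)) for c in self.compartments}
        if any(v < 0 for v in w.values()):
            raise SchemeError("input weights must be nonnegative")
        total = sum(w.values())
        if total > 0:
            w = {c: v / total for c, v in w.items()}
        object.__setattr__(self, "input_weights", w)
        for ev in self.dump_events:
            for src, dst, _ in ev.transfers:
                if src not in known or dst not in known:
                    raise SchemeError(
                        f"dump transfer {src} -> {dst} references an unknown compartment"
                    )

    # -- basic queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.compartments)

    def index(self, label: str) -> int:
        try:
            return self.compartments.index(label)
        except ValueError:
            raise SchemeError(f"unknown compartment label {label!r}") from None

    def total_outflow(self, label: str) -> float:
        return sum(k for (src, _), k in self.rates.items() if src == label)

    def absorbing_compartments(self) -> tuple:
        """Declared terminals plus any compartment with zero outflow."""
        out = []
        for c in self.compartments:
            if c in self.terminal or self.total_outflow(c) == 0.0:
                out.append(c)
        return tuple(out)

    def input_vector(self) -> np.ndarray:
        return np.array([self.input_weights[c] for c in self.compartments])

    # -- derived structures --------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    def transfer_matrix(self, event: DumpEvent) -> np.ndarray:
        """Column-stochastic matrix applying a dump event to a state vector."""
        T = np.eye(self.n)
        for src, dst, frac in event.transfers:
            i, j = self.index(src), self.index(dst)
            T[i, i] -= frac
            T[j, i] += frac
        return T

    def with_rates(self, updates: dict) -> "KineticScheme":
        rates = dict(self.rates)
        rates.update(updates)
        return replace(self, rates=rates)

    def with_dump_events(self, events) -> "KineticScheme":
        return replace(self, dump_events=tuple(events))


def build_rate_matrix(scheme: KineticScheme) -> np.ndarray:
    """Compartmental rate matrix K with dc/dt = K c.

    ``K[j, i]`` is the microscopic rate i -> j; ``K[i, i]`` is minus the
    total outflow of i.  When every destination (including the ground
    state) is itself a compartment, columns sum to zero and total
    population is conserved.
    """
    n = scheme.n
    K = np.zeros((n, n))
    for (src, dst), k in scheme.rates.items():
        i, j = scheme.index(src), scheme.index(dst)
        K[j, i] += k
        K[i, i] -= k
    return K


def branching_probabilities(scheme: KineticScheme, compartment: str) -> dict:
    """Per-destination branching probabilities of one compartment.

    Probability of leaving via a given edge is that edge's rate divided
    by the compartment's total outflow.
    """
    edges = {
        dst: k for (src, dst), k in scheme.rates.items() if src == compartment and k > 0
    }
    if not edges:
        raise SchemeError(
            f"compartment {compartment} has no outgoing edges; branching undefined"
        )
    total = sum(edges.values())
    return {dst: k / total for dst, k in edges.items()}


def _trapped_components(scheme: KineticScheme, transient: list) -> list:
    """Transient compartments from which no absorbing state is reachable."""
    absorbing = set(scheme.absorbing_compartments())
    # reverse reachability from absorbing states
    reach = set(absorbing)
    changed = True
    while changed:
        changed = False
        for (src, dst), k in scheme.rates.items():
            if k > 0 and dst in reach and src not in reach:
                reach.add(src)
                changed = True
    return [c for c in transient if c not in reach]


def absorption_matrix(scheme: KineticScheme) -> tuple:
    """Absorption probabilities of the embedded jump chain.

    Returns ``(terminals, A)`` where ``A[t, i]`` is the probability that
    a molecule currently in compartment ``i`` is eventually absorbed in
    terminal compartment ``terminals[t]``; identity on the terminals
    themselves.  Solved by the first-step (one-jump conditioning) linear
    equations.
    """
    terminals = list(scheme.absorbing_compartments())
    transient = [c for c in scheme.compartments if c not in terminals]
    trapped = _trapped_components(scheme, transient)
    if trapped:
        raise SchemeError(
            "no absorbing state reachable from compartment(s): " + ", ".join(trapped)
        )
    nt, nq = len(terminals), len(transient)
    A = np.zeros((nt, scheme.n))
    for t, label in enumerate(terminals):
        A[t, scheme.index(label)] = 1.0
    if nq:
        Q = np.zeros((nq, nq))  # Q[i, j] = P(transient i -> transient j)
        R = np.zeros((nq, nt))
        for i, src in enumerate(transient):
            probs = branching_probabilities(scheme, src)
            for dst, p in probs.items():
                if dst in terminals:
                    R[i, terminals.index(dst)] += p
                else:
                    Q[i, transient.index(dst)] += p
        B = np.linalg.solve(np.eye(nq) - Q, R)  # (nq, nt)
        for i, src in enumerate(transient):
            A[:, scheme.index(src)] = B[i]
    return tuple(terminals), A


def terminal_yields(scheme: KineticScheme) -> dict:
    """Probability that an initially excited molecule ends in each terminal.

    This is the quantum yield of each absorbing compartment: e.g. the
    photoisomerization quantum yield is the terminal yield of the first
    photoproduct.  Dump events are ignored here (pump-probe conditions);
    see :func:`takinetics.kinetics.terminal_yields_with_dump`.
    """
    terminals, A = absorption_matrix(scheme)
    w = scheme.input_vector()
    y = A @ w
    return {t: float(v) for t, v in zip(terminals, y)}
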