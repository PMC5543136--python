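"""Stochastic jump-process oracle for compartmental schemes.

Continuous-time Monte-Carlo (Gillespie) sampling of the same first-order
network solved analytically in :mod:`takinetics.kinetics`.  Used as an
independent cross-check of terminal yields and dump-event accounting;
never as the production solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import IRFModel, KineticScheme, branching_probabilities

__all__ = ["McYields", "mc_jump_oracle"]


@dataclass
class McYields:
    """Empirical terminal yields with binomial standard errors."""

    yields: dict
    stderr: dict
    n_traj: int

    def agrees_with(self, exact: dict, n_sigma: float = 3.0) -> bool:
        return all(
            abs(self.yields.get(t, 0.0) - y)
            <= n_sigma * max(self.stderr.get(t, 0.0), 1e-12)
            for t, y in exact.items()
        )


def mc_jump_oracle(
    scheme: KineticScheme,
    n_traj: int = 100_000,
    seed: int = 0,
    irf: IRFModel | None = None,
    include_dump: bool = True,
) -> McYields:
    """Sample trajectory fates of the scheme's jump process.

    Each trajectory starts in a compartment drawn from the input
    weights (at a Gaussian-distributed start time if an IRF is given),
    performs exponentially-timed jumps along the rate network, and is
    subjected to the scheme's dump events: at each dump time a
    trajectory sitting in a source compartment relocates with the
    event's transfer probability.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = scheme.n
    labels = scheme.compartments
    absorbing = set(scheme.absorbing_compartments())
    transient_idx = np.array(
        [i for i, c in enumerate(labels) if c not in absorbing], dtype=int
    )

    # per-compartment total rates and jump-chain destinations
    total_rate = np.array([scheme.total_outflow(c) for c in labels])
    dests: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i in transient_idx:
        probs = branching_probabilities(scheme, labels[i])
        dests[i] = (
            np.array([scheme.index(d) for d in probs]),
            np.array(list(probs.values())),
        )

    w = scheme.input_vector()
    state = rng.choice(n, size=n_traj, p=w)
    if irf is not None:
        t = rng.normal(irf.center, irf.width, size=n_traj)
    else:
        t = np.zeros(n_traj)

    events = sorted(scheme.dump_events, key=lambda e: e.time) if include_dump else []
    horizons = [ev.time for ev in events] + [np.inf]

    is_transient = np.zeros(n, dtype=bool)
    is_transient[transient_idx] = True

    for ev_i, horizon in enumerate(horizons):
        # jump until every trajectory is absorbed or has reached the horizon
        frozen = t >= horizon
        while True:
            active = is_transient[state] & ~frozen
            if not active.any():
                break
            idx = np.nonzero(active)[0]
            dt = rng.exponential(1.0 / total_rate[state[idx]])
            t_new = t[idx] + dt
            cross = t_new > horizon
            # crossing trajectories wait at the horizon (memoryless restart)
            t[idx[cross]] = horizon
            frozen[idx[cross]] = True
            jumpers = idx[~cross]
            t[jumpers] = t_new[~cross]
            for s in np.unique(state[jumpers]):
                sel = jumpers[state[jumpers] == s]
                d_idx, d_p = dests[s]
                state[sel] = rng.choice(d_idx, size=sel.size, p=d_p)
        if ev_i < len(events):
            for src, dst, frac in events[ev_i].transfers:
                i, j = scheme.index(src), scheme.index(dst)
                in_src = np.nonzero(state == i)[0]
                moved = in_src[rng.random(in_src.size) < frac]
                state[moved] = j

    yields, stderr = {}, {}
    for c in labels:
        if c in absorbing:
            p = float(np.mean(state == scheme.index(c)))
            yields[c] = p
            stderr[c] = float(np.sqrt(p * (1 - p) / n_traj))
    return McYields(yields=yields, stderr=stderr, n_traj=n_traj)
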