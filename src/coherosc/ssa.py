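"""Exact stochastic simulation (Gillespie direct method) and ensembles.

Each trajectory is an exact sample path of the chemical master equation:
waiting times are exponential with the total propensity as rate and the next
reaction is chosen proportionally to its propensity.  Ensembles use
independent per-trajectory RNG streams derived from one base seed, so a run
is reproducible bit-exactly regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork

__all__ = [
    "EventPath",
    "TrajectoryEnsemble",
    "gillespie_run",
    "run_ensemble",
    "ensemble_mean",
    "absorption_fraction",
    "absorption_curve",
]


@dataclass(frozen=True)
class EventPath:
    """One SSA realization: jump times and the state after each jump."""

    times: np.ndarray  # (E+1,), times[0] = 0
    states: np.ndarray  # (E+1, N), states[k] holds on [times[k], times[k+1])
    t_end: float
    absorbed: bool  # total propensity hit 0 before t_end

    def sample(self, grid) -> np.ndarray:
        """Right-continuous step interpolation onto a time grid."""
        grid = np.asarray(grid, float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        return self.states[idx]


def _compile_propensity(net: ReactionNetwork):
    """Return a fast propensity evaluator a(state) for repeated SSA calls."""
    pref = net.rate_constants * net.omega ** net.omega_exponents
    terms = []  # per reaction: list of (species index, order)
    s = net.reactant_stoich
    for j in range(net.n_reactions):
        terms.append([(i, int(s[i, j])) for i in range(net.n_species) if s[i, j]])

    def evaluate(state, out):
        for j, t in enumerate(terms):
            v = pref[j]
            for i, order in t:
                ni = state[i]
                for k in range(order):
                    v *= ni - k
            out[j] = v if v > 0 else 0.0
        return out

    return evaluate


def gillespie_run(net: ReactionNetwork, init_state, t_end: float,
                  seed) -> EventPath:
    """Direct-method SSA from ``init_state`` until ``t_end`` or absorption.

    ``seed`` may be an int, a SeedSequence-compatible key, or a Generator.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    state = np.asarray(init_state, dtype=np.int64)
    if state.shape != (net.n_species,) or (state < 0).any():
        raise ValueError("init_state must be a valid copy-number vector")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    evaluate = _compile_propensity(net)
    stoich = net.net_stoich.T.astype(np.int64)
    a = np.empty(net.n_reactions)
    times = [0.0]
    states = [state.copy()]
    t = 0.0
    absorbed = False
    while True:
        evaluate(state, a)
        a_total = a.sum()
        if a_total <= 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / a_total)
        if t >= t_end:
            break
        j = np.searchsorted(np.cumsum(a), rng.uniform(0.0, a_total), side="right")
        j = min(j, net.n_reactions - 1)
        state = state + stoich[j]
        times.append(t)
        states.append(state)
    return EventPath(np.array(times), np.array(states), float(t_end), absorbed)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Seeded SSA realizations sampled on a common uniform time grid."""

    time_grid: np.ndarray  # (T,)
    counts: np.ndarray  # (n_traj, T, N) integer copy numbers
    base_seed: int
    network: ReactionNetwork
    absorbed: np.ndarray = field(default=None)  # (n_traj,) bool

    @property
    def n_traj(self) -> int:
        return self.counts.shape[0]


def run_ensemble(net: ReactionNetwork, init_state, n_traj: int, time_grid,
                 base_seed: int) -> TrajectoryEnsemble:
    """Run ``n_traj`` independent SSA trajectories sampled onto ``time_grid``.

    Trajectory ``k`` uses the RNG stream seeded by ``(base_seed, k)``.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    grid = np.asarray(time_grid, float)
    if grid.ndim != 1 or (np.diff(grid) <= 0).any():
        raise ValueError("time_grid must be strictly increasing")
    t_end = float(grid[-1]) + 1e-12
    counts = np.empty((n_traj, grid.size, net.n_species), dtype=np.int64)
    absorbed = np.empty(n_traj, dtype=bool)
    for k in range(n_traj):
        path = gillespie_run(net, init_state, t_end,
                             np.random.default_rng([int(base_seed), k]))
        counts[k] = path.sample(grid)
        absorbed[k] = path.absorbed
    return TrajectoryEnsemble(grid, counts, int(base_seed), net, absorbed)


def ensemble_mean(ens: TrajectoryEnsemble) -> np.ndarray:
    """Arithmetic mean copy number over trajectories, shape (T, N)."""
    if ens.n_traj == 0:
        raise ValueError("empty ensemble")
    return ens.counts.mean(axis=0)


def _single_species_mask(counts) -> np.ndarray:
    """True where exactly one species is nonzero (per trajectory/time)."""
    return (counts > 0).sum(axis=-1) == 1


def absorption_fraction(ens: TrajectoryEnsemble) -> float:
    """Fraction of trajectories in a single-species state at the final time.

    Only meaningful for closed networks, where such states are absorbing.
    """
    if not ens.network.is_closed():
        raise ValueError("absorption fraction requires a closed network")
    return float(_single_species_mask(ens.counts[:, -1, :]).mean())


def absorption_curve(ens: TrajectoryEnsemble) -> np.ndarray:
    """Single-species-state fraction at every grid time, shape (T,)."""
    if not ens.network.is_closed():
        raise ValueError("absorption curve requires a closed network")
    return _single_species_mask(ens.counts).mean(axis=0)
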