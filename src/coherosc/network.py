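"""Reaction networks, state-space enumeration and master-equation generators.

A continuous-time Markov chain over copy-number states ``n`` evolves as
``dP/dt = M P`` where ``M`` is the transition-rate matrix (generator): the
off-diagonal entry ``M[b, a]`` is the rate of jumping from state ``a`` to
state ``b`` and every column sums to zero, so probability is conserved.  For
a mass-action reaction network the jump rates are the reaction propensities
and ``M`` is the matrix form of the chemical master equation on a finite
(closed or truncated) state space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import yaml

__all__ = [
    "ReactionNetwork",
    "StateSpace",
    "GeneratorMatrix",
    "SpectralSummary",
    "load_network",
    "propensities",
    "enumerate_states",
    "build_generator",
    "spectral_summary",
]

#: eigenvalues with |Re| below this are treated as exactly zero
ZERO_EIG_TOL = 1e-10


class NetworkValidationError(ValueError):
    """Raised when a network specification is inconsistent."""


@dataclass(frozen=True)
class ReactionNetwork:
    """A mass-action reaction network.

    Parameters
    ----------
    species : tuple of str
        Species identifiers, length ``N``.
    reactant_stoich, product_stoich : (N, R) int arrays
        Stoichiometric coefficients ``s[i, j]`` / ``r[i, j]`` of species ``i``
        in reaction ``j`` on the reactant / product side.
    rate_constants : (R,) float array
        Nonnegative rate constants ``c_j`` (units 1/time after volume
        scaling).
    omega_exponents : (R,) int array
        Per-reaction exponent ``w_j`` of the system-size parameter in the
        propensity prefactor ``c_j * omega**w_j`` (e.g. ``-2`` for a
        trimolecular step, ``+1`` for a zeroth-order influx).
    omega : float
        System-size parameter, > 0.
    """

    species: tuple
    reactant_stoich: np.ndarray
    product_stoich: np.ndarray
    rate_constants: np.ndarray
    omega_exponents: np.ndarray
    omega: float = 1.0

    def __post_init__(self):
        s = np.asarray(self.reactant_stoich, dtype=int)
        r = np.asarray(self.product_stoich, dtype=int)
        c = np.asarray(self.rate_constants, dtype=float)
        w = np.asarray(self.omega_exponents, dtype=float)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactant_stoich", s)
        object.__setattr__(self, "product_stoich", r)
        object.__setattr__(self, "rate_constants", c)
        object.__setattr__(self, "omega_exponents", w)
        n = len(self.species)
        if n == 0:
            raise NetworkValidationError("network needs at least one species")
        if s.ndim != 2 or s.shape != r.shape or s.shape[0] != n:
            raise NetworkValidationError(
                f"stoichiometry shapes {s.shape}/{r.shape} inconsistent with "
                f"{n} species"
            )
        if s.shape[1] == 0:
            raise NetworkValidationError("network needs at least one reaction")
        if c.shape != (s.shape[1],) or w.shape != (s.shape[1],):
            raise NetworkValidationError("rate/exponent vectors must have length R")
        if (s < 0).any() or (r < 0).any():
            raise NetworkValidationError("stoichiometric coefficients must be >= 0")
        if (c < 0).any():
            raise NetworkValidationError("rate constants must be >= 0")
        if not self.omega > 0:
            raise NetworkValidationError("omega must be positive")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return self.reactant_stoich.shape[1]

    @property
    def net_stoich(self) -> np.ndarray:
        """Net stoichiometric matrix ``S = r - s`` (N x R)."""
        return self.product_stoich - self.reactant_stoich

    def is_closed(self, weights=None) -> bool:
        """True if ``weights . n`` is conserved by every reaction (default
        weights: all ones, i.e. total copy number)."""
        u = np.ones(self.n_species) if weights is None else np.asarray(weights, float)
        return bool(np.allclose(u @ self.net_stoich, 0.0))


def load_network(source) -> ReactionNetwork:
    """Build a :class:`ReactionNetwork` from a YAML document.

    ``source`` may be a mapping, a YAML string, or a path to a YAML file with
    keys ``species``, ``reactions`` (each with ``reactants``, ``products``,
    ``rate`` and optional ``omega_exponent``) and optional ``omega``.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("{"):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise NetworkValidationError("model document must be a mapping")
    try:
        species = list(doc["species"])
        reactions = list(doc["reactions"])
    except KeyError as exc:
        raise NetworkValidationError(f"missing required field {exc}") from None
    if not reactions:
        raise NetworkValidationError("field 'reactions' is empty")
    index = {name: i for i, name in enumerate(species)}
    n, r = len(species), len(reactions)
    s_mat = np.zeros((n, r), dtype=int)
    r_mat = np.zeros((n, r), dtype=int)
    rates = np.zeros(r)
    exps = np.zeros(r)
    for j, rxn in enumerate(reactions):
        if not isinstance(rxn, dict) or "rate" not in rxn:
            raise NetworkValidationError(f"reaction {j}: missing field 'rate'")
        for side, mat in (("reactants", s_mat), ("products", r_mat)):
            for name, count in (rxn.get(side) or {}).items():
                if name not in index:
                    raise NetworkValidationError(
                        f"reaction {j}: unknown species {name!r} in '{side}'"
                    )
                mat[index[name], j] = int(count)
        rates[j] = float(rxn["rate"])
        if rates[j] < 0:
            raise NetworkValidationError(f"reaction {j}: negative rate {rates[j]}")
        exps[j] = float(rxn.get("omega_exponent", 0))
    return ReactionNetwork(
        species=tuple(species),
        reactant_stoich=s_mat,
        product_stoich=r_mat,
        rate_constants=rates,
        omega_exponents=exps,
        omega=float(doc.get("omega", 1.0)),
    )


def propensities(net: ReactionNetwork, state) -> np.ndarray:
    """Combinatorial mass-action propensities ``a_j(n)``.

    ``a_j = c_j * omega**w_j * prod_i n_i (n_i - 1) ... (n_i - s_ij + 1)``,
    the number of distinct reactant combinations times the scaled rate;
    zero whenever any ``n_i < s_ij``.
    """
    n = np.asarray(state)
    if n.shape != (net.n_species,):
        raise ValueError(f"state must have {net.n_species} entries")
    if (n < 0).any():
        raise ValueError("copy numbers must be >= 0")
    a = net.rate_constants * net.omega ** net.omega_exponents
    s = net.reactant_stoich
    for j in range(net.n_reactions):
        for i in range(net.n_species):
            for k in range(s[i, j]):  # falling factorial n_i * (n_i-1) * ...
                a[j] *= n[i] - k
        if a[j] < 0:
            a[j] = 0.0
    return a


@dataclass(frozen=True)
class StateSpace:
    """An enumerated, ordered finite set of copy-number states."""

    states: tuple  # tuple of N-tuples, lexicographic order
    kind: str  # "closed-conserved" | "truncated-box"
    meta: dict = field(default_factory=dict)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        idx = {s: i for i, s in enumerate(self.states)}
        if len(idx) != len(self.states):
            raise ValueError("duplicate states in enumeration")
        object.__setattr__(self, "_index", idx)

    def __len__(self) -> int:
        return len(self.states)

    def index_of(self, state) -> int:
        return self._index[tuple(int(v) for v in state)]

    def __contains__(self, state) -> bool:
        return tuple(int(v) for v in state) in self._index

    def as_array(self) -> np.ndarray:
        return np.array(self.states, dtype=int)

    def labels(self) -> list:
        return ["(" + ",".join(str(v) for v in s) + ")" for s in self.states]


def enumerate_states(net: ReactionNetwork, mode: str, *, total=None,
                     bounds=None, weights=None) -> StateSpace:
    """Enumerate the reachable finite state space in lexicographic order.

    mode="closed-conserved"
        All nonnegative states with ``weights . n == total`` (weights default
        to all ones).  Every reaction must conserve this sum.
    mode="truncated-box"
        All states with ``0 <= n_i <= bounds[i]``.
    """
    n_sp = net.n_species
    if mode == "closed-conserved":
        if total is None:
            raise ValueError("closed-conserved mode requires 'total'")
        u = np.ones(n_sp, dtype=int) if weights is None else np.asarray(weights, int)
        if not np.allclose(u @ net.net_stoich, 0.0):
            raise NetworkValidationError(
                "a reaction does not conserve the stated weighted total"
            )
        total = int(total)
        states = []

        def fill(prefix, remaining):
            i = len(prefix)
            if i == n_sp - 1:
                if u[i] > 0:
                    if remaining % u[i] == 0:
                        states.append(prefix + (remaining // u[i],))
                elif remaining == 0:
                    states.append(prefix + (0,))
                return
            top = remaining // u[i] if u[i] > 0 else 0
            for v in range(top + 1):
                fill(prefix + (v,), remaining - u[i] * v)

        fill((), total)
        states.sort()
        return StateSpace(tuple(states), "closed-conserved",
                          {"total": total, "weights": tuple(int(v) for v in u)})
    if mode == "truncated-box":
        if bounds is None:
            raise ValueError("truncated-box mode requires 'bounds'")
        bounds = [int(b) for b in bounds]
        if len(bounds) != n_sp:
            raise ValueError("need one bound per species")
        if any(b < 0 for b in bounds):
            raise NetworkValidationError("bounds must be >= 0")
        states = tuple(itertools.product(*(range(b + 1) for b in bounds)))
        return StateSpace(states, "truncated-box", {"bounds": tuple(bounds)})
    raise ValueError(f"unknown enumeration mode {mode!r}")


@dataclass(frozen=True)
class GeneratorMatrix:
    """Transition-rate matrix M over an enumerated state space.

    ``M[b, a]`` for ``b != a`` is the rate from state ``a`` to state ``b``;
    diagonals carry minus the total escape rate so columns sum to zero.
    """

    M: scipy.sparse.csc_matrix
    space: StateSpace

    @property
    def n(self) -> int:
        return self.M.shape[0]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.M.todense())

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.M.sum(axis=0)).ravel()

    def check(self, tol: float = 1e-12) -> None:
        """Assert generator invariants (column sums ~0, signs)."""
        dense = self.to_dense()
        if np.abs(dense.sum(axis=0)).max() > tol:
            raise AssertionError("column sums deviate from zero")
        off = dense - np.diag(np.diag(dense))
        if off.min() < 0:
            raise AssertionError("negative off-diagonal rate")
        if np.diag(dense).max() > tol:
            raise AssertionError("positive diagonal entry")

    def absorbing_indices(self) -> np.ndarray:
        """Indices of states with zero total escape rate (all-zero columns)."""
        col_abs = np.asarray(abs(self.M).sum(axis=0)).ravel()
        return np.flatnonzero(col_abs == 0.0)

    def to_tsv(self, path) -> None:
        """Dense TSV export with state labels on both axes."""
        labels = self.space.labels()
        dense = self.to_dense()
        with open(path, "w") as fh:
            fh.write("state\t" + "\t".join(labels) + "\n")
            for lab, row in zip(labels, dense):
                fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def build_generator(net: ReactionNetwork, space: StateSpace) -> GeneratorMatrix:
    """Assemble the master-equation generator on ``space``.

    For each reaction ``j`` and source state ``n`` with target ``n + S_j``
    inside the space, ``M[target, source] += a_j(n)`` and the source diagonal
    decreases by the same amount.  Jumps leaving a truncated box are dropped
    from both flux and escape rate (reflecting truncation), which keeps M a
    proper generator.
    """
    s_cols = net.net_stoich.T
    rows, cols, vals = [], [], []
    diag = np.zeros(len(space))
    for a_idx, state in enumerate(space.states):
        a = propensities(net, state)
        for j in range(net.n_reactions):
            if a[j] == 0.0:
                continue
            target = tuple(int(v) for v in np.add(state, s_cols[j]))
            if target not in space:
                continue  # reflecting truncation at box boundary
            b_idx = space.index_of(target)
            rows.append(b_idx)
            cols.append(a_idx)
            vals.append(a[j])
            diag[a_idx] -= a[j]
    n = len(space)
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    m = scipy.sparse.csc_matrix(
        (np.array(vals), (np.array(rows), np.array(cols))), shape=(n, n)
    )
    return GeneratorMatrix(m, space)


@dataclass(frozen=True)
class SpectralSummary:
    """Eigenstructure of a generator.

    Eigenvalues are sorted by descending real part (ties by |imag|).  Every
    generator has all real parts <= 0 and at least one zero eigenvalue; a
    violation beyond tolerance marks the summary inconsistent.
    """

    eigenvalues: np.ndarray
    multiplicity_of_zero: int
    null_vectors: np.ndarray  # (n, multiplicity) stationary/absorbing basis
    consistent: bool

    @property
    def spectral_gap(self) -> float:
        """|Re| of the slowest nonzero mode (0 if none)."""
        nz = self.eigenvalues[np.abs(self.eigenvalues) > ZERO_EIG_TOL]
        return float(-nz.real.max()) if nz.size else 0.0


def spectral_summary(gen: GeneratorMatrix | np.ndarray) -> SpectralSummary:
    """Full dense eigendecomposition of a generator with consistency flags."""
    dense = gen.to_dense() if isinstance(gen, GeneratorMatrix) else np.asarray(gen, float)
    eig = scipy.linalg.eigvals(dense)
    order = np.lexsort((np.abs(eig.imag), -eig.real))
    eig = eig[order]
    consistent = bool(eig.real.max() <= ZERO_EIG_TOL)
    null = scipy.linalg.null_space(dense, rcond=1e-9)
    mult = int(np.sum(np.abs(eig) <= ZERO_EIG_TOL))
    if mult == 0:
        consistent = False
    # normalize stationary basis columns to unit probability mass where possible
    basis = []
    for k in range(null.shape[1]):
        v = null[:, k]
        tot = v.sum()
        basis.append(v / tot if abs(tot) > 1e-9 else v)
    null = np.column_stack(basis) if basis else null
    return SpectralSummary(eig, mult, null, consistent)
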