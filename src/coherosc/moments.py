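"""Moment equations for mass-action networks and central-moment-neglect closure.

For a chemical master equation the raw moment ``<n^m>`` (multi-index ``m``)
evolves as

    d<n^m>/dt = sum_j < a_j(n) * ((n + S_j)^m - n^m) >

which is exact but couples order ``|m|`` to order ``|m| + dmax`` where
``dmax`` is the maximum propensity degree minus one.  The hierarchy is closed
at order ``q`` by setting every central moment of order > q to zero and
re-expressing the higher raw moments through lower ones.  Order q = 1
recovers the deterministic rate equations (all covariances neglected).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.linalg
import scipy.optimize
import sympy as sp

from .network import ReactionNetwork

__all__ = [
    "MomentSystem",
    "ClosedMomentSystem",
    "MomentTrajectories",
    "derive_moments",
    "close_system",
    "integrate_moments",
    "deterministic_init",
    "linearized_mode",
]


def _multi_indices(n_species: int, order: int):
    """All multi-indices of exact total order, lexicographically."""
    out = []
    for combo in itertools.product(range(order + 1), repeat=n_species):
        if sum(combo) == order:
            out.append(combo)
    out.sort()
    return out


def _moment_symbol(m) -> sp.Symbol:
    return sp.Symbol("mu_" + "_".join(str(v) for v in m), real=True)


def _poly_to_moments(expr, n_syms, mu):
    """Apply <.> to a polynomial in the count symbols: n^k -> mu[k]."""
    poly = sp.Poly(sp.expand(expr), *n_syms)
    out = sp.Integer(0)
    for monom, coeff in poly.terms():
        if sum(monom) == 0:
            out += coeff
        else:
            key = tuple(int(v) for v in monom)
            if key not in mu:
                mu[key] = _moment_symbol(key)
            out += coeff * mu[key]
    return out


def _symbolic_propensities(net: ReactionNetwork, n_syms, omega=None):
    """Combinatorial mass-action propensities as polynomials in the counts.

    ``omega`` may be a sympy symbol to keep the system-size parameter
    symbolic (useful for scaling-limit checks); default is the numeric value.
    """
    a = []
    omega = sp.Float(net.omega) if omega is None else omega
    for j in range(net.n_reactions):
        expr = sp.Float(net.rate_constants[j]) * omega ** int(
            net.omega_exponents[j]
        )
        for i in range(net.n_species):
            for k in range(int(net.reactant_stoich[i, j])):
                expr *= n_syms[i] - k
        a.append(sp.expand(expr))
    return a


@dataclass(frozen=True)
class MomentSystem:
    """Exact (unclosed) moment equations up to tracked order ``q``.

    ``rhs_raw[m]`` is d<n^m>/dt as a polynomial in raw-moment symbols; it may
    involve moments of order up to ``q + dmax``.
    """

    network: ReactionNetwork
    q: int
    tracked: tuple  # multi-indices with 1 <= |m| <= q, ordered by (|m|, lex)
    rhs_raw: dict  # multi-index -> sympy expr
    mu: dict  # multi-index -> Symbol
    dmax: int


def derive_moments(net: ReactionNetwork, q: int,
                   omega=None) -> MomentSystem:
    """Exact symbolic moment equations for all multi-indices of order <= q.

    Pass a sympy symbol as ``omega`` to keep the system size symbolic in the
    resulting expressions (the system is then not numerically integrable).
    """
    if not 1 <= q <= 5:
        raise ValueError("closure order q must be in 1..5")
    n_sp = net.n_species
    n_syms = sp.symbols(f"n0:{n_sp}", real=True)
    a_syms = _symbolic_propensities(net, n_syms, omega)
    degrees = [max(sp.Poly(a, *n_syms).total_degree() for a in a_syms)]
    dmax = max(degrees[0] - 1, 0)
    stoich = net.net_stoich
    tracked = []
    for order in range(1, q + 1):
        tracked.extend(_multi_indices(n_sp, order))
    mu: dict = {m: _moment_symbol(m) for m in tracked}
    rhs = {}
    for m in tracked:
        total = sp.Integer(0)
        for j in range(net.n_reactions):
            shifted = sp.Integer(1)
            plain = sp.Integer(1)
            for i in range(n_sp):
                if m[i]:
                    shifted *= (n_syms[i] + int(stoich[i, j])) ** m[i]
                    plain *= n_syms[i] ** m[i]
            total += a_syms[j] * (shifted - plain)
        rhs[m] = _poly_to_moments(total, n_syms, mu)
    return MomentSystem(net, q, tuple(tracked), rhs, mu, dmax)


def _central_in_raw(j, mu, mean_syms, n_syms):
    """Central moment C_j expressed through raw moments of order <= |j|."""
    expr = sp.Integer(1)
    for i, ji in enumerate(j):
        if ji:
            expr *= (n_syms[i] - mean_syms[i]) ** ji
    poly = sp.Poly(sp.expand(expr), *n_syms)
    out = sp.Integer(0)
    for monom, coeff in poly.terms():
        if sum(monom) == 0:
            out += coeff
        else:
            out += coeff * mu[tuple(int(v) for v in monom)]
    return sp.expand(out)


def _closure_expression(k, q, mu, n_sp):
    """Raw moment of order |k| > q under central-moment-neglect.

    <n^k> = sum_{j <= k} prod_i C(k_i, j_i) mean_i^(k_i - j_i) * C_j with
    C_j = 0 for |j| > q (and for |j| = 1 identically).
    """
    n_syms = sp.symbols(f"n0:{n_sp}", real=True)
    unit = lambda i: tuple(1 if t == i else 0 for t in range(n_sp))
    mean_syms = [mu[unit(i)] for i in range(n_sp)]
    out = sp.Integer(0)
    for j in itertools.product(*(range(ki + 1) for ki in k)):
        oj = sum(j)
        if oj > q or oj == 1:
            continue
        coeff = sp.Integer(1)
        for i in range(n_sp):
            coeff *= sp.binomial(k[i], j[i]) * mean_syms[i] ** (k[i] - j[i])
        cj = sp.Integer(1) if oj == 0 else _central_in_raw(j, mu, mean_syms, n_syms)
        out += coeff * cj
    return sp.expand(out)


@dataclass(frozen=True)
class ClosedMomentSystem:
    """Self-contained ODE system over raw moments of order <= q."""

    network: ReactionNetwork
    q: int
    tracked: tuple
    rhs: tuple  # sympy exprs aligned with tracked, only tracked symbols
    mu: dict
    scheme: str

    def labels(self) -> list:
        return ["m" + "".join(str(v) for v in m) for m in self.tracked]

    def _callables(self):
        syms = [self.mu[m] for m in self.tracked]
        f = sp.lambdify(syms, list(self.rhs), modules="numpy")
        jac_expr = sp.Matrix(list(self.rhs)).jacobian(syms)
        jac = sp.lambdify(syms, jac_expr, modules="numpy")
        return (lambda t, y: np.asarray(f(*y), dtype=float),
                lambda t, y: np.asarray(jac(*y), dtype=float))

    def jacobian_at(self, y) -> np.ndarray:
        _, jac = self._callables()
        return jac(0.0, np.asarray(y, float))


def close_system(ms: MomentSystem, scheme: str = "central-moment-neglect") -> ClosedMomentSystem:
    """Close the hierarchy at order q by neglecting higher central moments."""
    if scheme != "central-moment-neglect":
        raise ValueError(f"unsupported closure scheme {scheme!r}")
    tracked = set(ms.tracked)
    subs = {}
    for k, sym in ms.mu.items():
        if k not in tracked:
            subs[sym] = _closure_expression(k, ms.q, ms.mu, ms.network.n_species)
    rhs = tuple(sp.expand(ms.rhs_raw[m].xreplace(subs)) for m in ms.tracked)
    return ClosedMomentSystem(ms.network, ms.q, ms.tracked, rhs, ms.mu, scheme)


def deterministic_init(closed: ClosedMomentSystem, n0) -> np.ndarray:
    """Raw moments of a point mass at copy numbers ``n0`` (delta start)."""
    n0 = np.asarray(n0, float)
    return np.array([np.prod(n0 ** np.array(m)) for m in closed.tracked])


@dataclass(frozen=True)
class MomentTrajectories:
    time_grid: np.ndarray
    values: np.ndarray  # (T, K) raw moments aligned with tracked
    closed: ClosedMomentSystem

    def moment(self, m) -> np.ndarray:
        return self.values[:, self.closed.tracked.index(tuple(m))]

    def means(self) -> np.ndarray:
        """First-order moments, shape (T, N)."""
        n_sp = self.closed.network.n_species
        cols = [self.closed.tracked.index(
            tuple(1 if t == i else 0 for t in range(n_sp))) for i in range(n_sp)]
        return self.values[:, cols]


def integrate_moments(closed: ClosedMomentSystem, init_moments, t_grid,
                      rtol: float = 1e-9, atol: float = 1e-9,
                      method: str = "LSODA") -> MomentTrajectories:
    """Integrate the closed moment ODEs on ``t_grid`` (stiff-capable)."""
    grid = np.asarray(t_grid, float)
    y0 = np.asarray(init_moments, float)
    if y0.shape != (len(closed.tracked),):
        raise ValueError("init_moments length must match tracked moments")
    f, jac = closed._callables()
    sol = scipy.integrate.solve_ivp(
        f, (grid[0], grid[-1]), y0, t_eval=grid, method=method,
        jac=jac if method in ("LSODA", "BDF", "Radau") else None,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"moment integration failed: {sol.message}")
    return MomentTrajectories(grid, sol.y.T, closed)


@dataclass(frozen=True)
class LinearizedMode:
    """Leading oscillatory mode of the closed moment system at a fixed point."""

    fixed_point: np.ndarray
    eigenvalues: np.ndarray  # sorted by descending real part
    omega: float | None  # |Im| of leading complex pair, None if all real
    gamma: float  # -Re of the leading mode (negative => growing)


def linearized_mode(closed: ClosedMomentSystem, x0,
                    tol: float = 1e-9) -> LinearizedMode:
    """Locate a fixed point near ``x0`` and report the leading Jacobian mode.

    ``omega`` is the absolute imaginary part of the dominant complex pair and
    ``gamma`` its decay rate (-Re); for a purely real leading mode ``omega``
    is None and ``gamma`` is the relaxation rate.
    """
    f, jac = closed._callables()
    x0 = np.asarray(x0, float)
    best = None
    for method in ("hybr", "lm", "df-sane"):
        kwargs = {"jac": (lambda y: jac(0.0, y))} if method != "df-sane" else {}
        try:
            sol = scipy.optimize.root(lambda y: f(0.0, y), x0,
                                      method=method, tol=tol, **kwargs)
        except Exception:
            continue
        resid = np.max(np.abs(f(0.0, sol.x)))
        if best is None or resid < best[0]:
            best = (resid, sol.x)
        if resid <= 1e-8 * max(1.0, np.abs(sol.x).max()):
            break
    if best is None or best[0] > 1e-6 * max(1.0, np.abs(best[1]).max()):
        raise RuntimeError("fixed-point search failed near the given start")
    fixed = best[1]
    eig = np.linalg.eigvals(jac(0.0, fixed))
    eig = eig[np.lexsort((np.abs(eig.imag), -eig.real))]
    complex_part = eig[np.abs(eig.imag) > 1e-9]
    if complex_part.size:
        lead = complex_part[0]
        return LinearizedMode(fixed, eig, float(abs(lead.imag)),
                              float(-lead.real))
    # skip conserved (zero) modes when quoting a relaxation rate
    nonzero = eig[np.abs(eig) > 1e-9]
    lead = nonzero[0] if nonzero.size else eig[0]
    return LinearizedMode(fixed, eig, None, float(-lead.real))
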