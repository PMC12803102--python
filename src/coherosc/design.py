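"""Coupling design: purely imaginary eigenvalue pairs at a chosen frequency.

A generator M of a Markov chain has only decaying non-zero modes, so
ensemble oscillations always damp out.  Coupling the chain to an auxiliary
(non-Markovian) variable x,

    dP/dt = M P + B1 x,      dx/dt = B2 P + C x,

can move one targeted mode of the combined block matrix A onto the imaginary
axis, producing sustained coherent ensemble oscillations.  The analysis is
done in the real Schur basis of M: reordering the zero (stationary) mode
last makes every other Schur vector orthogonal to the all-ones vector, so a
coupling column built from such a vector automatically conserves
probability.  Targeting a scalar Schur block sigma1 < 0 with an unstable
scalar C = -sigma1 and coupling product q1*q2 = sigma1*sigma2 - omega**2
places an exact +/- i*omega pair in A's spectrum; targeting a 2x2 block goes
through a reduced cubic whose purely-imaginary-root condition is b*c == a*d
with b > 0, c > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .network import ZERO_EIG_TOL, GeneratorMatrix

__all__ = [
    "SchurForm",
    "CoupledLinearSystem",
    "DesignResult",
    "CharacteristicCubic",
    "SuppressionResult",
    "PhaseDiagram",
    "ordered_schur",
    "feasible_sigma_alpha2",
    "design_real_mode",
    "design_complex_mode",
    "suppress_oscillatory_mode",
    "classify_regime",
    "phase_diagram",
    "scaling_exponent",
    "REGIME_LABELS",
]


class WrongModeError(ValueError):
    """Requested index does not name a block of the required kind."""


class DesignVerificationError(RuntimeError):
    """The assembled system's spectrum misses the designed eigenvalues."""

    def __init__(self, message, eigenvalues):
        super().__init__(message)
        self.eigenvalues = eigenvalues


class InfeasibleDesignError(RuntimeError):
    """No coupling product satisfies the imaginary-root conditions."""


@dataclass(frozen=True)
class SchurForm:
    """Real Schur form M = Q D1 Q^T with the zero mode ordered last.

    ``S1`` holds positions of scalar (1x1) diagonal entries, ``S2`` positions
    of the first row of each 2x2 block (a complex-conjugate eigenvalue pair).
    """

    Q: np.ndarray
    D1: np.ndarray
    S1: tuple
    S2: tuple
    zero_positions: tuple  # trailing scalar positions with |eig| ~ 0

    @property
    def n(self) -> int:
        return self.D1.shape[0]

    def eigenvalue_of(self, position: int):
        """Eigenvalue(s) carried by the block starting at ``position``."""
        if position in self.S1:
            return self.D1[position, position]
        if position in self.S2:
            return np.linalg.eigvals(self.D1[position:position + 2,
                                             position:position + 2])
        raise WrongModeError(f"{position} is not a block start")


def _as_dense(M) -> np.ndarray:
    if isinstance(M, GeneratorMatrix):
        return M.to_dense()
    return np.asarray(M, float)


def ordered_schur(M) -> SchurForm:
    """Real Schur decomposition with all zero eigenvalues reordered last.

    Because the all-ones vector is a left null vector of a generator, this
    ordering makes every non-trailing Schur column sum to ~0, which is what
    lets designed couplings conserve probability.
    """
    dense = _as_dense(M)
    D1, Q, sdim = scipy.linalg.schur(
        dense, output="real",
        sort=lambda re, im: re * re + im * im > ZERO_EIG_TOL ** 2)
    n = dense.shape[0]
    if not np.allclose(Q @ D1 @ Q.T, dense,
                       atol=1e-10 * max(1.0, np.abs(dense).max())):
        raise RuntimeError("Schur reconstruction failed beyond tolerance")
    s1, s2 = [], []
    i = 0
    while i < n:
        if i + 1 < n and D1[i + 1, i] != 0.0:
            s2.append(i)
            i += 2
        else:
            s1.append(i)
            i += 1
    zero = tuple(range(sdim, n))
    return SchurForm(Q, D1, tuple(s1), tuple(s2), zero)


@dataclass(frozen=True)
class CoupledLinearSystem:
    """Block system A = [[M, B1], [B2, C]] with probability-conserving B1."""

    M: np.ndarray  # (n, n)
    B1: np.ndarray  # (n, l), zero column sums
    B2: np.ndarray  # (l, n)
    C: np.ndarray  # (l, l)

    def __post_init__(self):
        object.__setattr__(self, "M", np.asarray(self.M, float))
        object.__setattr__(self, "B1", np.atleast_2d(np.asarray(self.B1, float)))
        object.__setattr__(self, "B2", np.atleast_2d(np.asarray(self.B2, float)))
        object.__setattr__(self, "C", np.atleast_2d(np.asarray(self.C, float)))
        m_scale = max(1.0, np.abs(self.M).max())
        is_generator = np.abs(self.M.sum(axis=0)).max() <= 1e-9 * m_scale
        if is_generator and np.abs(self.B1.sum(axis=0)).max() > \
                1e-10 * max(1.0, np.abs(self.B1).max()):
            raise ValueError("columns of B1 must sum to zero (probability conservation)")

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def l(self) -> int:
        return self.C.shape[0]

    @property
    def A(self) -> np.ndarray:
        return np.block([[self.M, self.B1], [self.B2, self.C]])


@dataclass(frozen=True)
class CharacteristicCubic:
    """Reduced characteristic cubic a*l^3 + b*l^2 + c*l + d of a 2x2-block
    design with the weakly coupled dimension dropped (q_beta1 = 0)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def coefficients(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def roots(self) -> np.ndarray:
        return np.roots(self.coefficients)

    def has_imaginary_pair(self, tol: float = 1e-8) -> bool:
        r = self.roots()
        scale = max(1.0, np.abs(r).max())
        return bool(np.any((np.abs(r.real) <= tol * scale)
                           & (np.abs(r.imag) > tol * scale)))

    def condition_satisfied(self, rtol: float = 1e-9) -> bool:
        """Necessary & sufficient imaginary-pair test: bc = ad, b > 0, c > 0."""
        scale = max(abs(self.b * self.c), abs(self.a * self.d), 1e-300)
        return (abs(self.b * self.c - self.a * self.d) <= rtol * scale
                and self.b > 0 and self.c > 0)


@dataclass(frozen=True)
class DesignResult:
    """Outcome of targeting one Schur mode of M with a coupled input."""

    kind: str  # "real" | "complex"
    position: int  # Schur position of the targeted block
    sigma1: np.ndarray | float  # targeted Markov eigenvalue / 2x2 block
    sigma2: np.ndarray | float  # designed non-Markov eigenvalue(s)
    coupling_product: float  # q1 * q2
    q1: float
    q2: float
    predicted_omega: float
    achieved_eigenvalues: np.ndarray  # full spectrum of A, sorted Re desc
    max_other_real_part: float  # max Re outside the designed pair
    system: CoupledLinearSystem
    cubic: CharacteristicCubic | None = None
    mode_vector: np.ndarray | None = None  # eigenvector of the +i*omega mode

    def to_dict(self) -> dict:
        def mat(x):
            x = np.atleast_2d(np.asarray(x, float))
            return {"shape": list(x.shape), "data": x.ravel().tolist()}
        return {
            "kind": self.kind,
            "position": int(self.position),
            "sigma1": np.asarray(self.sigma1, float).ravel().tolist(),
            "sigma2": np.asarray(self.sigma2, float).ravel().tolist(),
            "coupling_product": self.coupling_product,
            "q1": self.q1,
            "q2": self.q2,
            "predicted_omega": self.predicted_omega,
            "max_other_real_part": self.max_other_real_part,
            "achieved_eigenvalues": {
                "real": self.achieved_eigenvalues.real.tolist(),
                "imag": self.achieved_eigenvalues.imag.tolist(),
            },
            "M": mat(self.system.M), "B1": mat(self.system.B1),
            "B2": mat(self.system.B2), "C": mat(self.system.C),
            "cubic": list(self.cubic.coefficients) if self.cubic else None,
        }


def _sorted_eigs(A: np.ndarray) -> np.ndarray:
    eig = np.linalg.eigvals(A)
    return eig[np.lexsort((np.abs(eig.imag), -eig.real))]


def _verify_pair(A: np.ndarray, omega: float, re_tol: float = 1e-8,
                 omega_rtol: float = 1e-6):
    """Check A has a +/- i*omega pair and all other real parts <= re_tol.

    Returns the sorted spectrum, the max real part outside the pair, and the
    right eigenvector of the +i*omega member (phase-normalized).
    """
    eig, vecs = np.linalg.eig(A)
    order = np.lexsort((np.abs(eig.imag), -eig.real))
    eig, vecs = eig[order], vecs[:, order]
    scale = max(1.0, np.abs(eig).max())
    cand = int(np.argmin(np.abs(eig - 1j * omega)))
    lam = eig[cand]
    ok = (abs(lam.real) <= re_tol * scale
          and abs(abs(lam.imag) - omega) <= omega_rtol * max(omega, 1e-12))
    others = np.delete(eig, [cand, int(np.argmin(np.abs(eig + 1j * omega)))])
    max_other = float(others.real.max()) if others.size else -np.inf
    if not ok or max_other > re_tol * scale:
        raise DesignVerificationError(
            f"designed pair not realized: got {lam:.3e}, "
            f"max other Re {max_other:.3e}", eig)
    v = vecs[:, cand]
    v = v / v[np.argmax(np.abs(v))]
    return eig, max_other, v


def design_real_mode(schur: SchurForm, mode_index: int, target_omega: float,
                     M: np.ndarray | None = None):
    """Turn the scalar decaying mode at ``mode_index`` into a +/- i*omega pair.

    Sets sigma2 = -sigma1 (the auxiliary variable is unstable exactly as fast
    as the targeted mode decays) and coupling product
    q1*q2 = sigma1*sigma2 - omega**2 < 0 (negative feedback), split
    antisymmetrically q1 = -q2 = sqrt(-q1*q2).  B1/B2 are the targeted Schur
    vector scaled by q1/q2, so B1's column sums vanish by construction.
    """
    if mode_index not in schur.S1:
        raise WrongModeError(f"index {mode_index} is not a scalar Schur block")
    if mode_index in schur.zero_positions:
        raise WrongModeError("cannot target the stationary (zero) mode")
    sigma1 = float(schur.D1[mode_index, mode_index])
    if sigma1 >= 0:
        raise WrongModeError(f"targeted mode must decay (sigma1={sigma1})")
    if not target_omega > 0:
        raise ValueError("target_omega must be positive")
    sigma2 = -sigma1
    product = sigma1 * sigma2 - target_omega ** 2
    q1 = np.sqrt(-product)
    q2 = -q1
    v = schur.Q[:, mode_index]
    dense = _as_dense(M) if M is not None else schur.Q @ schur.D1 @ schur.Q.T
    sys = CoupledLinearSystem(dense, (q1 * v)[:, None], (q2 * v)[None, :],
                              [[sigma2]])
    eig, max_other, mode_vec = _verify_pair(sys.A, target_omega)
    return DesignResult("real", mode_index, sigma1, sigma2, float(product),
                        float(q1), float(q2), float(target_omega), eig,
                        max_other, sys, mode_vector=mode_vec)


def _reduced_cubic(block: np.ndarray, sigma2: float, product: float) -> CharacteristicCubic:
    """Cubic for [[d_aa, d_ab, q1], [d_ba, d_bb, 0], [q2, 0, sigma2]]."""
    tau = block[0, 0] + block[1, 1]
    delta = block[0, 0] * block[1, 1] - block[0, 1] * block[1, 0]
    a = 1.0
    b = -(tau + sigma2)
    c = delta + sigma2 * tau - product
    d = product * block[1, 1] - sigma2 * delta
    return CharacteristicCubic(a, b, c, d)


def feasible_sigma_alpha2(block: np.ndarray, n_scan: int = 2000):
    """A sigma_alpha2 for which the 2x2-block design is feasible, or None.

    Feasibility requires b = -(tr(block) + sigma2) > 0 together with c > 0 at
    the product solving b*c = a*d; scanning candidate sigma2 values over
    (0, -tr(block)) locates the admissible window and returns its midpoint.
    """
    tau = block[0, 0] + block[1, 1]
    upper = -tau * (1.0 - 1e-9)
    feasible = []
    for u in np.linspace(upper / n_scan, upper, n_scan):
        denom = -(tau + u) + block[1, 1]  # b + d_bb
        if denom == 0.0:
            continue
        cub0 = _reduced_cubic(block, u, 0.0)
        k = (cub0.b * cub0.c - cub0.d) / denom  # g is linear in the product
        cub = _reduced_cubic(block, u, k)
        if cub.b > 0 and cub.c > 0:
            feasible.append(u)
    if not feasible:
        return None
    return float(np.median(feasible))


def design_complex_mode(schur: SchurForm, block_index: int,
                        sigma_alpha2: float | None = None,
                        search=(1e-8, 1e6), sigma_beta2: float = -1.0,
                        M: np.ndarray | None = None):
    """Make the decaying oscillatory 2x2 block at ``block_index`` coherent.

    With the second auxiliary dimension weakly coupled (q_beta1 = 0) the
    block's quartic reduces to a cubic; the coupling product solving
    b*c = a*d with b, c > 0 puts a conjugate pair exactly on the imaginary
    axis at frequency sqrt(c).  The product is located by bracketing and
    bisection of g(product) = b*c - a*d over ``search`` (both signs tried).
    ``sigma_alpha2 = None`` picks a feasible auxiliary eigenvalue
    automatically (for weakly rotating blocks the window sits above
    ``-d_aa``: the input must be strongly unstable).
    """
    if block_index not in schur.S2:
        raise WrongModeError(f"index {block_index} is not a 2x2 Schur block")
    block = schur.D1[block_index:block_index + 2, block_index:block_index + 2]
    if sigma_alpha2 is None:
        sigma_alpha2 = feasible_sigma_alpha2(block)
        if sigma_alpha2 is None:
            raise InfeasibleDesignError(
                "no feasible sigma_alpha2 found for this block")
    b_coef = -(block[0, 0] + block[1, 1] + sigma_alpha2)
    if b_coef <= 0:
        raise InfeasibleDesignError(
            "b <= 0 for this sigma_alpha2; no imaginary pair possible")

    def g(k):
        cub = _reduced_cubic(block, sigma_alpha2, k)
        return cub.b * cub.c - cub.a * cub.d

    lo, hi = search
    product = None
    for sign in (-1.0, 1.0):
        grid = sign * np.geomspace(lo, hi, 200)
        vals = [g(k) for k in grid]
        for i in range(len(grid) - 1):
            if vals[i] == 0.0:
                product = grid[i]
                break
            if vals[i] * vals[i + 1] < 0:
                product = scipy.optimize.brentq(g, grid[i], grid[i + 1],
                                                xtol=1e-14, rtol=1e-15)
                break
        if product is not None:
            cub = _reduced_cubic(block, sigma_alpha2, product)
            if cub.c > 0:
                break
            product = None
    if product is None:
        raise InfeasibleDesignError(
            "no coupling product with b*c = a*d and b, c > 0 in search range")
    cubic = _reduced_cubic(block, sigma_alpha2, product)
    omega = float(np.sqrt(cubic.c))
    if product < 0:
        q1, q2 = float(np.sqrt(-product)), -float(np.sqrt(-product))
    else:
        q1 = q2 = float(np.sqrt(product))
    v = schur.Q[:, block_index]
    n = schur.n
    B1 = np.zeros((n, 2))
    B2 = np.zeros((2, n))
    B1[:, 0] = q1 * v
    B2[0, :] = q2 * v
    C = np.diag([sigma_alpha2, sigma_beta2])
    dense = _as_dense(M) if M is not None else schur.Q @ schur.D1 @ schur.Q.T
    sys = CoupledLinearSystem(dense, B1, B2, C)
    eig, max_other, mode_vec = _verify_pair(sys.A, omega)
    return DesignResult("complex", block_index, block.copy(),
                        np.array([sigma_alpha2, sigma_beta2]), float(product),
                        q1, q2, omega, eig, max_other, sys, cubic,
                        mode_vector=mode_vec)


@dataclass(frozen=True)
class SuppressionResult:
    system: CoupledLinearSystem
    cubic: CharacteristicCubic
    achieved_eigenvalues: np.ndarray
    suppressed: bool  # targeted pair became real


def suppress_oscillatory_mode(schur: SchurForm, block_index: int,
                              product: float, sigma_alpha2: float = -1.0,
                              sigma_beta2: float = -1.0,
                              M: np.ndarray | None = None) -> SuppressionResult:
    """Positive coupling to a 2x2 block to kill its oscillation.

    A large enough product > 0 merges the block's complex pair into real
    eigenvalues; the achieved spectrum is reported either way.
    """
    if block_index not in schur.S2:
        raise WrongModeError(f"index {block_index} is not a 2x2 Schur block")
    if not product > 0:
        raise ValueError("suppression requires a positive coupling product")
    block = schur.D1[block_index:block_index + 2, block_index:block_index + 2]
    cubic = _reduced_cubic(block, sigma_alpha2, product)
    q = float(np.sqrt(product))
    v = schur.Q[:, block_index]
    n = schur.n
    B1 = np.zeros((n, 2))
    B2 = np.zeros((2, n))
    B1[:, 0] = q * v
    B2[0, :] = q * v
    C = np.diag([sigma_alpha2, sigma_beta2])
    dense = _as_dense(M) if M is not None else schur.Q @ schur.D1 @ schur.Q.T
    sys = CoupledLinearSystem(dense, B1, B2, C)
    roots = cubic.roots()
    suppressed = bool(np.all(np.abs(roots.imag) <= 1e-8 * max(1.0, np.abs(roots).max())))
    return SuppressionResult(sys, cubic, _sorted_eigs(sys.A), suppressed)


REGIME_LABELS = (
    "stable-nonoscillatory",
    "decaying-oscillatory",
    "coherent",
    "growing-oscillatory",
    "unstable-nonoscillatory",
)


def classify_regime(sigma1: float, sigma2: float, product: float,
                    tol: float = 1e-10) -> str:
    """Dynamical regime of the 2x2 reduction [[sigma1, q1], [q2, sigma2]].

    Classified through the trace tau = sigma1 + sigma2 and determinant
    delta = sigma1*sigma2 - product: oscillatory iff tau^2 < 4*delta, stable
    iff tau < 0, and coherent exactly on the tau = 0, delta > 0 boundary.
    """
    if sigma1 >= 0:
        raise ValueError("sigma1 must be a negative (decaying) Markov mode")
    tau = sigma1 + sigma2
    delta = sigma1 * sigma2 - product
    if abs(tau) <= tol and delta > tol:
        return "coherent"
    oscillatory = tau * tau < 4.0 * delta
    if oscillatory:
        return "decaying-oscillatory" if tau < 0 else "growing-oscillatory"
    # real eigenvalues (tau +/- sqrt(tau^2 - 4 delta)) / 2
    if tau < 0 and delta > 0:
        return "stable-nonoscillatory"
    return "unstable-nonoscillatory"


@dataclass(frozen=True)
class PhaseDiagram:
    sigma1: float
    sigma2_grid: np.ndarray
    product_grid: np.ndarray
    labels: np.ndarray  # (len(sigma2), len(product)) of str
    omega: np.ndarray  # oscillation frequency |Im(lambda)|, NaN where real

    def open_region_labels(self) -> set:
        """Distinct labels excluding the measure-zero coherent boundary."""
        return {str(v) for v in self.labels.ravel()} - {"coherent"}


def phase_diagram(sigma1: float, sigma2_grid, product_grid) -> PhaseDiagram:
    """Regime label and frequency over a (sigma2, product) grid."""
    s2 = np.asarray(sigma2_grid, float)
    pr = np.asarray(product_grid, float)
    labels = np.empty((s2.size, pr.size), dtype=object)
    omega = np.full((s2.size, pr.size), np.nan)
    for i, sig2 in enumerate(s2):
        for j, prod in enumerate(pr):
            lab = classify_regime(sigma1, sig2, prod)
            labels[i, j] = lab
            tau = sigma1 + sig2
            delta = sigma1 * sig2 - prod
            disc = 4.0 * delta - tau * tau
            if disc > 0:
                omega[i, j] = 0.5 * np.sqrt(disc)
    return PhaseDiagram(float(sigma1), s2, pr, labels, omega)


def scaling_exponent(sigma1: float, offsets) -> tuple:
    """Log-log slope of frequency vs distance to the critical coupling.

    On the coherence line sigma2 = -sigma1 the coupling product at threshold
    is sigma1*sigma2; for offsets eps the frequency (measured from the 2x2
    eigenvalues, not from the closed-form) scales as eps**(1/2).
    Returns (slope, residual norm of the log-log fit).
    """
    eps = np.asarray(offsets, float)
    if np.unique(eps).size < 3:
        raise ValueError("need at least 3 distinct offsets")
    if (eps <= 0).any():
        raise ValueError("offsets must be positive")
    sigma2 = -sigma1
    omegas = []
    for e in eps:
        product = sigma1 * sigma2 - e
        q1 = np.sqrt(-product)
        eig = np.linalg.eigvals([[sigma1, q1], [-q1, sigma2]])
        omegas.append(np.abs(eig.imag).max())
    coeffs, res = np.polynomial.polynomial.polyfit(
        np.log(eps), np.log(omegas), 1, full=True)
    residual = float(np.sqrt(res[0][0])) if len(res[0]) else 0.0
    return float(coeffs[1]), residual
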