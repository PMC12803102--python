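"""Schur analysis, mode targeting, regimes, scaling and the cubic condition."""

import numpy as np
import pytest

import coherosc as co
from coherosc import design as dz
from coherosc.workflows import slowest_real_mode

from conftest import random_generator_matrix


@pytest.fixture(scope="module")
def spiral_schur():
    """Schur form of a matrix whose leading block is a decaying spiral."""
    A = np.zeros((3, 3))
    A[:2, :2] = [[-0.2, 1.0], [-1.0, -0.2]]
    return dz.ordered_schur(A), A


class TestOrderedSchur:
    def test_two_state_chain_form(self, two_state_generator):
        schur = dz.ordered_schur(two_state_generator)
        assert np.allclose(np.diag(schur.D1), [-2.0, 0.0])
        assert schur.zero_positions == (1,)
        assert np.allclose(np.abs(schur.Q[:, 0]), [1, 1] / np.sqrt(2))

    def test_reconstruction_round_trip(self, trimolecular):
        space = co.enumerate_states(trimolecular.network, "closed-conserved",
                                    total=4)
        M = co.build_generator(trimolecular.network, space).to_dense()
        schur = dz.ordered_schur(M)
        assert np.abs(schur.Q @ schur.D1 @ schur.Q.T - M).max() < 1e-10

    def test_nonzero_schur_vectors_sum_to_zero(self, trimolecular_generator_small):
        """Zero-mode-last ordering makes every other Schur column orthogonal
        to the all-ones (probability) direction."""
        schur = dz.ordered_schur(trimolecular_generator_small)
        sums = schur.Q.sum(axis=0)
        keep = [i for i in range(schur.n) if i not in schur.zero_positions]
        assert np.abs(sums[keep]).max() < 1e-10

    def test_block_inventory_partitions_positions(self, trimolecular_generator_small):
        schur = dz.ordered_schur(trimolecular_generator_small)
        covered = sorted(list(schur.S1)
                         + [p for i in schur.S2 for p in (i, i + 1)])
        assert covered == list(range(schur.n))


class TestRealModeDesign:
    def test_abstract_mode_sigma_minus_one(self):
        """sigma1 = -1, omega* = sqrt(2): product -3, eigenvalues +/-i sqrt2."""
        M = np.array([[-0.5, 0.5], [0.5, -0.5]])  # sigma1 = -1
        schur = dz.ordered_schur(M)
        res = dz.design_real_mode(schur, 0, np.sqrt(2.0), M=M)
        assert res.sigma2 == pytest.approx(1.0)
        assert res.coupling_product == pytest.approx(-3.0)
        pair = res.achieved_eigenvalues[np.abs(res.achieved_eigenvalues.imag) > 0.1]
        assert np.allclose(sorted(pair.imag), [-np.sqrt(2), np.sqrt(2)],
                           atol=1e-10)
        assert np.abs(pair.real).max() < 1e-10

    def test_small_frequency_limit_of_the_product(self):
        """As omega* -> 0 the coupling product approaches sigma1*sigma2."""
        M = np.array([[-0.5, 0.5], [0.5, -0.5]])
        schur = dz.ordered_schur(M)
        res = dz.design_real_mode(schur, 0, 1e-3, M=M)
        assert res.coupling_product == pytest.approx(-1.0 - 1e-6, rel=1e-12)

    @pytest.mark.parametrize("omega", [0.5, 1.0, 2.0])
    def test_trimolecular_design_hits_target(self, trimolecular_generator, omega):
        schur = dz.ordered_schur(trimolecular_generator)
        M = trimolecular_generator.to_dense()
        res = dz.design_real_mode(schur, slowest_real_mode(schur), omega, M=M)
        lead = res.achieved_eigenvalues[
            np.argmin(np.abs(res.achieved_eigenvalues - 1j * omega))]
        assert abs(lead.real) <= 1e-8
        assert abs(lead.imag - omega) / omega <= 0.01
        assert res.max_other_real_part <= 1e-8

    def test_markov_spectrum_preserved_outside_target(self):
        """Coupling one Schur mode leaves all other eigenvalues in place.

        Uses a random dense generator so the spectrum is simple (degenerate
        eigenvalues of the symmetric-rate fixtures are ill-conditioned for
        this numerical comparison)."""
        M = random_generator_matrix(np.random.default_rng(42), 12)
        schur = dz.ordered_schur(M)
        idx = slowest_real_mode(schur)
        res = dz.design_real_mode(schur, idx, 1.0, M=M)
        eig_m = np.sort_complex(np.linalg.eigvals(M))
        sigma1 = schur.D1[idx, idx]
        eig_m = np.delete(eig_m, np.argmin(np.abs(eig_m - sigma1)))
        eig_a = res.achieved_eigenvalues
        pair = np.concatenate([
            [np.argmin(np.abs(eig_a - 1j))], [np.argmin(np.abs(eig_a + 1j))]])
        eig_a = np.delete(eig_a, pair)
        for lam in eig_m:
            assert np.min(np.abs(eig_a - lam)) < 1e-8 * max(1, abs(lam))

    def test_probability_conservation_of_coupling(self, trimolecular_generator):
        schur = dz.ordered_schur(trimolecular_generator)
        res = dz.design_real_mode(schur, slowest_real_mode(schur), 1.0,
                                  M=trimolecular_generator.to_dense())
        ones = np.ones(res.system.n)
        assert np.abs(ones @ res.system.M).max() < 1e-12 * 100
        assert np.abs(ones @ res.system.B1).max() < 1e-12

    def test_wrong_mode_kinds_rejected(self, trimolecular_generator_small):
        schur = dz.ordered_schur(trimolecular_generator_small)
        with pytest.raises(dz.WrongModeError):
            dz.design_real_mode(schur, schur.S2[0], 1.0)
        with pytest.raises(dz.WrongModeError):
            dz.design_real_mode(schur, schur.zero_positions[0], 1.0)

    def test_coherent_designs_need_negative_feedback(self):
        """Every successful scalar-mode design has q1*q2 < 0."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = rng.uniform(0.1, 5.0)
            M = np.array([[-k, k], [k, -k]])
            schur = dz.ordered_schur(M)
            res = dz.design_real_mode(schur, 0, rng.uniform(0.05, 4.0), M=M)
            assert res.coupling_product < 0

    def test_frequency_formula_against_eigensolver(self):
        """omega = sqrt(sigma1*sigma2 - q1 q2) matches the 2x2 spectrum."""
        rng = np.random.default_rng(8)
        for _ in range(2000):
            sigma1 = -rng.uniform(0.05, 10.0)
            sigma2 = -sigma1
            product = sigma1 * sigma2 - rng.uniform(0.01, 100.0)
            q1 = np.sqrt(-product)
            eig = np.linalg.eigvals([[sigma1, q1], [-q1, sigma2]])
            omega = np.sqrt(sigma1 * sigma2 - product)
            assert abs(np.abs(eig.imag).max() - omega) <= 1e-9 * omega
            assert np.abs(eig.real).max() <= 1e-9 * max(1.0, omega)


class TestComplexModeDesign:
    def test_spiral_block_design_satisfies_cubic_condition(self, spiral_schur):
        schur, A = spiral_schur
        res = dz.design_complex_mode(schur, schur.S2[0], M=A)
        cub = res.cubic
        assert abs(cub.b * cub.c - cub.a * cub.d) <= 1e-9 * abs(cub.b * cub.c)
        roots = cub.roots()
        pair = roots[np.abs(roots.imag) > 1e-6]
        assert np.abs(pair.real).max() <= 1e-8
        lead = res.achieved_eigenvalues[
            np.argmin(np.abs(res.achieved_eigenvalues
                             - 1j * res.predicted_omega))]
        assert abs(lead.real) <= 1e-8

    def test_decoupled_limit_keeps_block_eigenvalues(self, spiral_schur):
        schur, _ = spiral_schur
        block = schur.D1[:2, :2]
        cub = dz._reduced_cubic(block, -0.7, 0.0)
        expected = sorted(np.append(np.linalg.eigvals(block), -0.7),
                          key=lambda z: (z.real, z.imag))
        got = sorted(cub.roots(), key=lambda z: (z.real, z.imag))
        assert np.allclose(got, expected, atol=1e-9)
        assert not cub.has_imaginary_pair()

    def test_positive_product_pushes_pair_toward_real_axis(self, spiral_schur):
        schur, _ = spiral_schur
        block = schur.D1[:2, :2]
        imags = []
        for k in (0.0, 0.3, 0.6, 0.9):
            roots = dz._reduced_cubic(block, -1.0, k).roots()
            imags.append(np.abs(roots.imag).max())
        assert all(a >= b - 1e-12 for a, b in zip(imags, imags[1:]))

    def test_infeasible_sigma2_raises(self, spiral_schur):
        schur, A = spiral_schur
        with pytest.raises(dz.InfeasibleDesignError):
            dz.design_complex_mode(schur, schur.S2[0], sigma_alpha2=5.0, M=A)

    def test_generator_block_design_verified_in_full_spectrum(self, trimolecular_generator_small):
        schur = dz.ordered_schur(trimolecular_generator_small)
        res = dz.design_complex_mode(schur, schur.S2[0],
                                     M=trimolecular_generator_small.to_dense())
        assert res.cubic.condition_satisfied()
        assert res.max_other_real_part <= 1e-8
        ones = np.ones(res.system.n)
        assert np.abs(ones @ res.system.B1).max() < 1e-10


class TestSuppression:
    def test_weak_rotation_killed_by_strong_positive_product(self):
        A = np.zeros((3, 3))
        A[:2, :2] = [[-1.0, 0.1], [-0.1, -1.0]]
        schur = dz.ordered_schur(A)
        out = dz.suppress_oscillatory_mode(schur, schur.S2[0], product=5.0)
        assert out.suppressed

    def test_tiny_product_leaves_rotation_oscillatory(self, spiral_schur):
        schur, A = spiral_schur
        out = dz.suppress_oscillatory_mode(schur, schur.S2[0], product=1e-4,
                                           M=A)
        assert not out.suppressed

    def test_vanishing_product_keeps_spectrum(self, spiral_schur):
        schur, A = spiral_schur
        out = dz.suppress_oscillatory_mode(schur, schur.S2[0], product=1e-14,
                                           M=A)
        base = np.sort_complex(np.append(np.linalg.eigvals(A), [-1.0, -1.0]))
        assert np.allclose(np.sort_complex(out.achieved_eigenvalues), base,
                           atol=1e-6)


class TestRegimes:
    @pytest.mark.parametrize("sigma2, product, label", [
        (0.5, 0.0, "unstable-nonoscillatory"),  # saddle
        (1.0, -3.0, "coherent"),
        (-1.0, -0.1, "decaying-oscillatory"),
        (-2.0, 0.5, "stable-nonoscillatory"),
        (2.0, -4.0, "growing-oscillatory"),
    ])
    def test_known_regime_classifications(self, sigma2, product, label):
        assert dz.classify_regime(-1.0, sigma2, product) == label

    def test_classification_matches_eigenvalues(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            sigma1 = -rng.uniform(0.1, 3.0)
            sigma2 = rng.uniform(-3.0, 3.0)
            product = rng.uniform(-5.0, 5.0)
            tau = sigma1 + sigma2
            delta = sigma1 * sigma2 - product
            if abs(tau * tau - 4 * delta) < 1e-6 or abs(tau) < 1e-6:
                continue  # skip classification boundaries
            label = dz.classify_regime(sigma1, sigma2, product)
            q = np.sqrt(abs(product))
            eig = np.linalg.eigvals([[sigma1, q],
                                     [np.sign(product) * q, sigma2]])
            oscillatory = np.abs(eig.imag).max() > 1e-9
            stable = eig.real.max() < -1e-9
            assert oscillatory == (label in ("decaying-oscillatory",
                                             "growing-oscillatory"))
            assert stable == (label in ("stable-nonoscillatory",
                                        "decaying-oscillatory"))

    def test_positive_markov_mode_rejected(self):
        with pytest.raises(ValueError):
            dz.classify_regime(0.5, 1.0, 0.0)

    def test_phase_diagram_has_four_open_regions(self):
        grid = dz.phase_diagram(-1.0, np.linspace(-2, 2, 41),
                                np.linspace(-4, 4, 41))
        assert grid.open_region_labels() == {
            "stable-nonoscillatory", "decaying-oscillatory",
            "growing-oscillatory", "unstable-nonoscillatory"}

    def test_zero_coupling_grid_is_nonoscillatory(self):
        grid = dz.phase_diagram(-1.0, np.linspace(-2, 2, 21), np.array([0.0]))
        assert grid.open_region_labels() <= {
            "stable-nonoscillatory", "unstable-nonoscillatory"}

    def test_frequency_continuous_inside_oscillatory_regions(self):
        grid = dz.phase_diagram(-1.0, np.linspace(-2, 2, 81),
                                np.linspace(-4, 4, 81))
        om = grid.omega
        for i in range(om.shape[0]):
            row = om[i]
            finite = np.isfinite(row)
            jumps = np.abs(np.diff(row[finite]))
            if jumps.size:
                assert jumps.max() < 1.0  # bounded by grid resolution


class TestScaling:
    def test_square_root_scaling_at_threshold(self):
        slope, resid = dz.scaling_exponent(
            -1.0, [1e-1, 1e-2, 1e-3, 1e-4])
        assert slope == pytest.approx(0.5, abs=1e-6)
        assert resid < 1e-6

    def test_equal_offsets_rejected(self):
        with pytest.raises(ValueError):
            dz.scaling_exponent(-1.0, [0.1, 0.1, 0.1])

    @pytest.mark.parametrize("sigma1", [-0.5, -1.0, -2.0])
    def test_slope_independent_of_mode_rate(self, sigma1):
        slope, _ = dz.scaling_exponent(sigma1, np.geomspace(1e-1, 1e-4, 7))
        assert slope == pytest.approx(0.5, abs=1e-6)


class TestCharacteristicCubic:
    def test_condition_iff_stable_imaginary_pair(self):
        """bc = ad with b, c > 0 holds exactly when the cubic has a purely
        imaginary conjugate pair and no root in the right half-plane."""
        rng = np.random.default_rng(4)
        for _ in range(2000):
            constructed = rng.uniform() < 0.5
            if constructed:  # exact (lambda + b)(lambda^2 + c) factorization
                b = rng.uniform(-2.0, 3.0)
                c = rng.uniform(-2.0, 4.0)
                cub = dz.CharacteristicCubic(1.0, b, c, b * c)
            else:
                cub = dz.CharacteristicCubic(1.0, *rng.uniform(-3, 3, 3))
            roots = cub.roots()
            scale = max(1.0, np.abs(roots).max())
            pair = np.any((np.abs(roots.real) <= 1e-9 * scale)
                          & (np.abs(roots.imag) > 1e-9 * scale))
            stable = roots.real.max() <= 1e-9 * scale
            if min(abs(cub.b), abs(cub.c)) < 1e-7:
                continue  # b or c indistinguishable from the boundary
            if not constructed and abs(cub.b * cub.c - cub.d) < 1e-7:
                continue  # random draw landed on the knife edge
            assert cub.condition_satisfied(rtol=1e-7) == (pair and stable)

    def test_spec_is_violated_without_stability(self):
        # imaginary pair exists but third root is growing: b < 0
        cub = dz.CharacteristicCubic(1.0, -1.0, 4.0, -4.0)
        assert cub.has_imaginary_pair()
        assert not cub.condition_satisfied()
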