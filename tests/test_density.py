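import numpy as np
import pytest

from mutcorr.density import (
    cumulant,
    matricize_geminal,
    matricize_ph,
    metrics,
    natural_orbitals,
    one_rdm,
    raw_frobenius_sq,
    rotate_one_rdm,
    rotate_two_index_tensor,
    spin_summed_one_rdm,
    two_rdm,
    two_rdm_direct,
)
from mutcorr.examples import EXAMPLES, bell_singlet_paired
from mutcorr.fock_space import parse_state, product_state
from mutcorr.io import random_rotation_fixture


def lam_of(psi):
    g1 = one_rdm(psi)
    return g1, cumulant(g1, two_rdm(psi))


class TestRDMs:
    def test_single_determinant_one_rdm_is_projector(self):
        psi = parse_state([("2u00", 1.0)])
        g1 = one_rdm(psi)
        assert np.allclose(g1, np.diag([1, 1, 0, 0, 1, 0, 0, 0]), atol=1e-14)

    def test_one_rdm_invariants_on_random_states(self, random_state_factory):
        for K, na, nb in [(3, 2, 1), (4, 2, 2), (4, 1, 3)]:
            psi = random_state_factory(K, na, nb)
            g1 = one_rdm(psi)
            assert np.allclose(g1, g1.T, atol=1e-12)
            assert np.trace(g1) == pytest.approx(na + nb, abs=1e-10)
            ev = np.linalg.eigvalsh(g1)
            assert ev.min() > -1e-10 and ev.max() < 1 + 1e-10

    def test_two_rdm_trace_and_hermiticity(self, random_state_factory):
        psi = random_state_factory(4, 2, 2)
        g2 = two_rdm(psi)
        N = 4
        assert np.einsum("pqpq->", g2) == pytest.approx(N * (N - 1), abs=1e-9)
        assert np.allclose(g2, g2.transpose(2, 3, 0, 1), atol=1e-12)
        assert np.allclose(g2, -g2.transpose(1, 0, 2, 3), atol=1e-12)
        assert np.allclose(g2, -g2.transpose(0, 1, 3, 2), atol=1e-12)

    def test_determinant_two_rdm_factorizes(self):
        psi = parse_state([("ud20", 1.0)])
        g1, g2 = one_rdm(psi), two_rdm(psi)
        expect = np.einsum("pr,qs->pqrs", g1, g1) - np.einsum(
            "ps,qr->pqrs", g1, g1
        )
        assert np.allclose(g2, expect, atol=1e-13)

    def test_gram_pathway_matches_brute_force_oracle(self, random_state_factory):
        """RDMs from the pair-annihilation Gram route equal the explicit
        operator-string evaluation on every sector with K <= 3."""
        for K, na, nb in [(2, 1, 1), (3, 2, 1), (3, 1, 1), (2, 2, 2)]:
            psi = random_state_factory(K, na, nb)
            assert np.allclose(
                two_rdm(psi), two_rdm_direct(psi), atol=1e-12
            ), (K, na, nb)


class TestCumulantMetrics:
    def test_cumulant_vanishes_for_determinants(self):
        for term in ["2200", "u0d0", "2u0d"]:
            psi = parse_state([(term, 1.0)])
            _, lam = lam_of(psi)
            assert np.abs(lam).max() < 1e-12

    def test_cumulant_vanishes_for_one_electron_states(self, random_state_factory):
        psi = random_state_factory(4, 1, 0)
        _, lam = lam_of(psi)
        assert np.abs(lam).max() < 1e-12

    @pytest.mark.parametrize("name", list(EXAMPLES))
    def test_worked_examples_metric_table(self, name):
        """The four-electron example states share C = 1.75 and |Tr| = 2 but
        differ in the matricization extremal eigenvalues."""
        expected = {
            "bell_open": (0.250, 1.750),
            "bell_paired": (0.250, 1.750),
            "interpolated": (0.604, 1.457),
            "six_term": (1.250, 0.417),
        }
        psi = EXAMPLES[name]()
        _, lam = lam_of(psi)
        m = metrics(lam)
        assert m.C == pytest.approx(1.750, abs=5e-4)
        assert m.raw_norm == pytest.approx(4 * m.C, rel=1e-14)
        assert abs(m.trace_lambda2) == pytest.approx(2.000, abs=5e-4)
        gem, ph = expected[name]
        assert m.lambda_max_gem == pytest.approx(gem, abs=5e-4)
        assert m.lambda_max_ph == pytest.approx(ph, abs=5e-4)

    def test_bell_geminal_matricization_structure(self):
        _, lam = lam_of(bell_singlet_paired())
        gem = matricize_geminal(lam)
        assert gem.shape == (28, 28)  # 2K^2 - K for K = 4
        ev = np.linalg.eigvalsh(gem)
        assert np.allclose(np.abs(ev), 0.25, atol=1e-12)
        ph = matricize_ph(lam)
        assert ph.shape == (64, 64)

    def test_six_term_ph_spectrum_two_values(self):
        _, lam = lam_of(EXAMPLES["six_term"]())
        ev = np.abs(np.linalg.eigvalsh(matricize_ph(lam)))
        nz = np.unique(np.round(ev[ev > 1e-10], 3))
        assert set(nz) == {0.25, 0.417}

    def test_trace_identity_against_one_rdm_idempotency(
        self, random_state_factory
    ):
        for K, na, nb in [(3, 2, 1), (4, 2, 2)]:
            psi = random_state_factory(K, na, nb)
            g1, lam = lam_of(psi)
            tr = np.einsum("pqpq->", lam)
            assert tr == pytest.approx(
                np.trace(g1 @ g1 - g1), abs=1e-10
            )

    def test_matricization_eigenvalues_real(self, random_state_factory):
        psi = random_state_factory(3, 2, 2)
        _, lam = lam_of(psi)
        for m in (matricize_geminal(lam), matricize_ph(lam)):
            assert np.allclose(m, m.T, atol=1e-12)

    def test_additivity_for_product_states(self, random_state_factory):
        a = random_state_factory(2, 1, 1)
        b = random_state_factory(2, 1, 1)
        prod = product_state(a, b)
        ra = raw_frobenius_sq(lam_of(a)[1])
        rb = raw_frobenius_sq(lam_of(b)[1])
        rp = raw_frobenius_sq(lam_of(prod)[1])
        assert rp == pytest.approx(ra + rb, abs=1e-10)


class TestRotations:
    def test_identity_rotation_is_identity(self, random_state_factory):
        psi = random_state_factory(3, 2, 1)
        g1, lam = lam_of(psi)
        assert np.allclose(rotate_two_index_tensor(lam, np.eye(3)), lam)

    def test_metric_invariance_under_many_random_rotations(
        self, random_state_factory
    ):
        """All four cumulant metrics drift by < 1e-9 over 100 seeded
        restricted rotations."""
        psi = random_state_factory(3, 2, 1)
        g1, lam = lam_of(psi)
        m0 = metrics(lam)
        for seed in range(100):
            U = random_rotation_fixture(seed, 3)
            m = metrics(rotate_two_index_tensor(lam, U))
            assert abs(m.raw_norm - m0.raw_norm) < 1e-9
            assert abs(abs(m.trace_lambda2) - abs(m0.trace_lambda2)) < 1e-9
            assert abs(m.lambda_max_gem - m0.lambda_max_gem) < 1e-9
            assert abs(m.lambda_max_ph - m0.lambda_max_ph) < 1e-9

    def test_non_unitary_rotation_rejected(self, random_state_factory):
        psi = random_state_factory(2, 1, 1)
        _, lam = lam_of(psi)
        with pytest.raises(ValueError, match="unitary"):
            rotate_two_index_tensor(lam, np.array([[1.0, 0.1], [0.0, 1.0]]))

    def test_rotate_then_cumulant_equals_cumulant_then_rotate(
        self, random_state_factory
    ):
        """Rotating RDMs before forming the cumulant commutes with rotating
        the cumulant itself (linearity of the unitary action)."""
        psi = random_state_factory(3, 1, 2)
        g1, g2 = one_rdm(psi), two_rdm(psi)
        U = random_rotation_fixture(11, 3)
        lam_then_rot = rotate_two_index_tensor(cumulant(g1, g2), U)
        rot_then_lam = cumulant(
            rotate_one_rdm(g1, U), rotate_two_index_tensor(g2, U)
        )
        assert np.allclose(lam_then_rot, rot_then_lam, atol=1e-9)


class TestNaturalOrbitals:
    def test_diagonal_input_gives_descending_permutation(self):
        g1 = np.diag([0.2, 0.9, 0.5, 0.2, 0.9, 0.5])
        ss, U, noons = natural_orbitals(g1)
        assert np.allclose(noons, [1.8, 1.0, 0.4])
        assert np.allclose(np.abs(U[np.ix_([1, 2, 0], [0, 1, 2])]), np.eye(3))

    def test_noon_sum_and_diagonalization(self, random_state_factory):
        psi = random_state_factory(4, 2, 2)
        g1 = one_rdm(psi)
        ss, U, noons = natural_orbitals(g1)
        assert noons.sum() == pytest.approx(4.0, abs=1e-10)
        assert (np.diff(noons) <= 1e-12).all()
        rot = U.T @ spin_summed_one_rdm(g1) @ U
        assert np.abs(rot - np.diag(noons)).max() < 1e-10

    def test_oversize_basis_refused(self):
        psi_amps = np.zeros(1)
        from mutcorr.fock_space import CIVector, sector_space

        with pytest.raises(ValueError, match="K <= 16"):
            one_rdm(CIVector(sector_space(17, 0, 0), np.ones(1)))
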