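import numpy as np
import pytest

from mutcorr import one_rdm, two_rdm, cumulant
from mutcorr.analytic_models import toy_MAB, toy_state
from mutcorr.density import metrics
from mutcorr.fock_space import parse_state, product_state
from mutcorr.io import random_ci_fixture, random_partition_fixture
from mutcorr.partition import (
    FragmentPartition,
    classify,
    decompose,
    mutual_pair,
    mutual_pair_expanded,
    mutual_quad,
    mutual_quad_expanded,
    mutual_triple,
    mutual_triple_expanded,
    orbital_mutual_matrix,
    subsystem_correlation,
)


def lam_of(psi):
    g1 = one_rdm(psi)
    return cumulant(g1, two_rdm(psi))


class TestSubsystemCorrelation:
    def test_full_basis_recovers_total(self, random_state_factory):
        psi = random_state_factory(3, 2, 1)
        lam = lam_of(psi)
        assert subsystem_correlation(lam, range(6)) == pytest.approx(
            metrics(lam).C, abs=1e-12
        )

    def test_empty_set_is_zero(self, random_state_factory):
        lam = lam_of(random_state_factory(2, 1, 1))
        assert subsystem_correlation(lam, []) == 0.0

    def test_toy_fragment_value_at_pi_third(self):
        lam = lam_of(toy_state(np.pi / 3))
        got = subsystem_correlation(lam, (0, 2))
        assert got == pytest.approx(9 / 256, abs=1e-12)

    def test_out_of_range_rejected(self, random_state_factory):
        lam = lam_of(random_state_factory(2, 1, 1))
        with pytest.raises(IndexError):
            subsystem_correlation(lam, [7])


class TestMutualPair:
    def test_nonnegative_and_zero_for_separable(self, rng):
        a = random_ci_fixture(5, 2, 1, 1)
        b = random_ci_fixture(6, 2, 1, 1)
        prod = product_state(a, b)
        lam = lam_of(prod)
        A = (0, 1, 4, 5)  # spin orbitals of spatial 0, 1 (K = 4)
        B = (2, 3, 6, 7)
        assert mutual_pair(lam, A, B) == pytest.approx(0.0, abs=1e-10)

    def test_overlapping_fragments_rejected(self, random_state_factory):
        lam = lam_of(random_state_factory(2, 1, 1))
        with pytest.raises(ValueError, match="disjoint"):
            mutual_pair(lam, (0, 1), (1, 2))

    def test_explicit_expansion_equals_inclusion_exclusion(self, rng):
        """The four-sum expansion is the primary transcription check of the
        pair formula; both routes must agree on random states."""
        for seed in range(30):
            psi = random_ci_fixture(seed, 3, 2, 1)
            lam = lam_of(psi)
            part = random_partition_fixture(seed + 1000, 6, 2)
            A, B = part.fragments
            assert mutual_pair_expanded(lam, A, B) == pytest.approx(
                mutual_pair(lam, A, B), abs=1e-10
            )

    def test_toy_value_against_closed_form_grid(self):
        for th in np.linspace(0, np.pi, 50):
            lam = lam_of(toy_state(th))
            assert mutual_pair(lam, (0, 2), (1, 3)) == pytest.approx(
                toy_MAB(th), abs=1e-10
            )

    def test_nonnegativity_on_random_states(self):
        for seed in range(50):
            psi = random_ci_fixture(seed, 3, 1, 2)
            lam = lam_of(psi)
            part = random_partition_fixture(seed + 99, 6, 2)
            assert mutual_pair(lam, *part.fragments) >= -1e-12


class TestHigherOrders:
    def test_triple_zero_for_geminal_times_determinant(self, rng):
        gem = parse_state([("20", 1.0), ("02", -1.0)])
        det = parse_state([("2", 1.0)])
        psi = product_state(gem, det)
        lam = lam_of(psi)
        A, B, C = (0, 3), (1, 4), (2, 5)
        assert mutual_triple(lam, A, B, C) == pytest.approx(0.0, abs=1e-10)

    def test_explicit_triple_and_quad_match_inclusion_exclusion(self):
        for seed in range(20):
            psi = random_ci_fixture(seed, 3, 2, 2)
            lam = lam_of(psi)
            part = random_partition_fixture(seed + 7, 6, 4)
            A, B, C, D = part.fragments
            assert mutual_triple_expanded(lam, A, B, C) == pytest.approx(
                mutual_triple(lam, A, B, C), abs=1e-10
            )
            assert mutual_quad_expanded(lam, A, B, C, D) == pytest.approx(
                mutual_quad(lam, A, B, C, D), abs=1e-10
            )

    def test_single_determinant_all_terms_zero(self):
        lam = lam_of(parse_state([("2u0d", 1.0)]))
        part = random_partition_fixture(3, 8, 4)
        rep = decompose(lam, part)
        assert abs(rep.term_sum) < 1e-12


class TestDecompose:
    def test_completeness_over_many_seeded_cases(self):
        """sum of all decomposition terms equals C_S to 1e-10 for 200
        seeded (state, partition) pairs with 2..5 fragments."""
        count = 0
        for seed in range(200):
            K, na, nb = [(3, 2, 1), (3, 1, 1), (4, 2, 2), (4, 1, 2)][seed % 4]
            psi = random_ci_fixture(seed, K, na, nb)
            lam = lam_of(psi)
            nfrag = 2 + seed % 4
            part = random_partition_fixture(seed + 31, 2 * K, nfrag)
            rep = decompose(lam, part)
            assert rep.term_sum == pytest.approx(rep.C_total, abs=1e-10)
            count += 1
        assert count == 200

    def test_two_fragment_report_is_pair_identity(self, random_state_factory):
        psi = random_state_factory(3, 2, 1)
        lam = lam_of(psi)
        part = FragmentPartition(((0, 1, 3), (2, 4, 5)))
        rep = decompose(lam, part)
        assert not rep.M_triple and not rep.M_quad
        assert rep.C_total == pytest.approx(
            rep.C_frag[0] + rep.C_frag[1] + rep.M_pair[(0, 1)], abs=1e-12
        )

    def test_incomplete_cover_reports_missing(self, random_state_factory):
        lam = lam_of(random_state_factory(2, 1, 1))
        with pytest.raises(ValueError, match=r"\[3\]"):
            decompose(lam, FragmentPartition(((0, 1), (2,))))

    def test_rotation_within_fragment_leaves_terms_unchanged(
        self, random_state_factory
    ):
        """Mixing spin orbitals inside one fragment is a within-subsystem
        unitary, so every decomposition term is invariant."""
        from mutcorr.density import rotate_two_index_tensor

        psi = random_state_factory(4, 2, 2)
        lam = lam_of(psi)
        # fragments = spatial pairs {0,1} and {2,3}; rotate inside {0,1}
        theta = 0.7
        U = np.eye(4)
        U[:2, :2] = [[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]]
        lam_rot = rotate_two_index_tensor(lam, U)
        A, B = (0, 1, 4, 5), (2, 3, 6, 7)
        for f, v in (
            (lambda l: subsystem_correlation(l, A), None),
            (lambda l: subsystem_correlation(l, B), None),
            (lambda l: mutual_pair(l, A, B), None),
        ):
            assert f(lam_rot) == pytest.approx(f(lam), abs=1e-9)


class TestOrbitalMutualMatrix:
    def test_toy_maximum(self):
        lam = lam_of(toy_state(np.pi / 4))
        M = orbital_mutual_matrix(lam)
        assert M[0, 1] == pytest.approx(0.75, abs=1e-12)

    def test_determinant_gives_zero_matrix(self):
        lam = lam_of(parse_state([("20", 1.0)]))
        assert np.abs(orbital_mutual_matrix(lam)).max() < 1e-12

    def test_symmetry_zero_diagonal_and_bound(self):
        """M_PQ stays within [0, 3/4 + eps] over many seeded evaluations."""
        checked = 0
        for seed in range(84):
            psi = random_ci_fixture(seed, 3, *[(2, 1), (1, 1), (2, 2)][seed % 3])
            M = orbital_mutual_matrix(lam_of(psi))
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 0.0)
            assert (M >= -1e-12).all() and (M <= 0.75 + 1e-9).all()
            checked += M[np.triu_indices(3, 1)].size
        assert checked >= 250

    def test_odd_spin_orbital_count_rejected(self):
        with pytest.raises(ValueError):
            orbital_mutual_matrix(np.zeros((3, 3, 3, 3)))


class TestClassify:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.528, "strong"),
            (0.075, "strong"),
            (0.01, "medium"),
            (0.0075, "medium"),
            (0.001, "weak"),
            (0.0001, "negligible"),
            (0.0, "negligible"),
        ],
    )
    def test_band_edges(self, value, band):
        assert classify(value) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify(-0.1)
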