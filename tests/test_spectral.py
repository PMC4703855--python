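import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoloc import (
    ParamConfig,
    biregular_bipartite,
    build_community_matrix,
    build_interaction_matrix,
    ipr,
    leading_modes,
    localization_report,
    localized_species,
    reactivity,
)


def random_stable(S, rng, margin=0.5):
    """Random real matrix shifted to be stable (generically diagonalizable)."""
    M = rng.normal(size=(S, S))
    shift = np.max(np.linalg.eigvals(M).real) + margin
    return M - shift * np.eye(S)


class TestLeadingModes:
    def test_diagonal_matrix(self):
        s = leading_modes(np.diag([-1.0, -2.0]))
        assert s.lambda1 == pytest.approx(-1.0)
        np.testing.assert_allclose(s.v1, [1, 0], atol=1e-12)
        np.testing.assert_allclose(s.u1, [1, 0], atol=1e-12)

    def test_symmetric_left_equals_right(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(6, 6))
        M = np.abs(M + M.T)
        np.fill_diagonal(M, -3.0)
        s = leading_modes(M)
        np.testing.assert_allclose(s.v1, s.u1, atol=1e-8)

    def test_two_by_two_closed_form(self):
        s = leading_modes(np.array([[-1.0, 1.0], [1.0, -1.0]]))
        assert s.lambda1 == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(s.v1, np.ones(2) / np.sqrt(2), atol=1e-12)

    def test_eigenvalue_ordering(self):
        rng = np.random.default_rng(3)
        s = leading_modes(random_stable(12, rng))
        re = s.eigenvalues.real
        assert (np.diff(re) <= 1e-12).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            leading_modes(np.array([[np.nan, 0], [0, -1.0]]))

    def test_complex_leading_eigenvalue_rejected(self):
        # pure rotation: complex pair with equal real parts
        with pytest.raises(ValueError, match="complex"):
            leading_modes(np.array([[0.0, -1.0], [1.0, 0.0]]))

    def test_perron_vector_nonnegative_on_community_matrix(self, powerlaw_net):
        cfg = ParamConfig(delta=0.5, seed=0)
        W = build_interaction_matrix(powerlaw_net, cfg)
        Phi = build_community_matrix(W, np.ones(powerlaw_net.S))
        s = leading_modes(Phi)
        assert (s.v1 >= -1e-10).all()
        assert (s.u1 >= -1e-10).all()
        assert s.u1 @ s.v1 > 0


class TestReactivity:
    def test_symmetric_equals_lambda1(self):
        M = np.array([[-2.0, 1.0], [1.0, -2.0]])
        lamH, _ = reactivity(M)
        assert lamH == pytest.approx(leading_modes(M).lambda1)

    def test_stable_but_reactive_worked_case(self):
        M = np.array([[-1.0, 0.0], [10.0, -1.0]])
        s = leading_modes(M)
        assert s.lambda1 == pytest.approx(-1.0)
        assert s.lambdaH == pytest.approx(4.0)

    def test_continuity_to_decoupled_limit(self):
        lamH, _ = reactivity(np.array([[-1.0, 1e-9], [1e-9, -1.0]]))
        assert lamH == pytest.approx(-1.0, abs=1e-8)

    def test_dominates_lambda1_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            M = random_stable(10, rng)
            lam1 = np.max(np.linalg.eigvals(M).real)
            assert reactivity(M)[0] >= lam1 - 1e-10


class TestIPR:
    def test_basis_vector_is_one(self):
        e = np.zeros(9)
        e[4] = 1.0
        assert ipr(e) == pytest.approx(1.0)

    def test_uniform_vector_is_reciprocal_length(self):
        assert ipr(np.ones(25)) == pytest.approx(1 / 25)

    def test_direct_summation_example(self):
        assert ipr(np.array([3.0, 1.0, 1.0, 1.0])) == pytest.approx(84 / 144)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ipr(np.zeros(4))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 40),
        scale=st.floats(0.01, 100.0),
    )
    def test_invariance_and_bounds(self, seed, n, scale):
        """IPR is scale- and permutation-invariant and within [1/S, 1]."""
        rng = np.random.default_rng(seed)
        q = rng.normal(size=n)
        val = ipr(q)
        assert 1 / n - 1e-12 <= val <= 1 + 1e-12
        assert ipr(scale * q) == pytest.approx(val)
        assert ipr(rng.permutation(q)) == pytest.approx(val)


class TestLocalizedSpecies:
    def test_uniform_vector_has_none(self):
        q = np.ones(16) / 4.0
        _, n = localized_species(q)
        assert n == 0

    def test_basis_vector_has_one(self):
        e = np.zeros(10)
        e[3] = 1.0
        idx, n = localized_species(e)
        assert n == 1 and list(idx) == [3]

    def test_custom_threshold(self):
        q = np.array([0.9, 0.3, 0.3, 0.1])
        q = q / np.linalg.norm(q)
        idx, n = localized_species(q, theta=0.5)
        assert n == 1 and list(idx) == [0]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            localized_species(np.ones(4) / 2.0, theta=0.0)


class TestSpectralStructure:
    def test_biorthogonality_and_reconstruction(self):
        """u_a . v_b vanishes off the diagonal and the eigen-expansion
        rebuilds the matrix."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            M = random_stable(8, rng)
            vals, V = np.linalg.eig(M)
            U = np.linalg.inv(V)  # rows are left eigenvectors, u_a.v_b = delta
            np.testing.assert_allclose(U @ V, np.eye(8), atol=1e-8)
            np.testing.assert_allclose(V @ np.diag(vals) @ U, M, atol=1e-8)

    def test_biregular_mean_field_is_fully_extended(self):
        """Regular topology (equal degrees in both guilds), constant weights,
        flat abundances: v1 uniform and IPR at its 1/S floor."""
        net = biregular_bipartite(10, 10, 2, seed=0)
        cfg = ParamConfig(delta=0.0, d=1.0, abundance_sd=0.0)
        W = build_interaction_matrix(net, cfg)
        Phi = build_community_matrix(W, np.ones(net.S))
        s = leading_modes(Phi)
        assert ipr(s.v1) == pytest.approx(1 / net.S, rel=1e-8)
        assert np.ptp(s.v1) < 1e-10  # exactly flat up to round-off
        # every component sits at the extended benchmark theta = 1/sqrt(S),
        # so nothing exceeds a threshold nudged above the tie
        rep = localization_report(s, theta=(1 + 1e-9) / np.sqrt(net.S))
        assert rep.n_localized["v1"] == 0


def test_localization_report_fields(powerlaw_net):
    cfg = ParamConfig(delta=0.5, seed=1)
    W = build_interaction_matrix(powerlaw_net, cfg)
    Phi = build_community_matrix(W, np.ones(powerlaw_net.S))
    rep = localization_report(leading_modes(Phi))
    S = powerlaw_net.S
    for val in (rep.ipr_v1, rep.ipr_u1, rep.ipr_wH):
        assert 1 / S - 1e-12 <= val <= 1
    assert rep.theta == pytest.approx(1 / np.sqrt(S))
    assert rep.n_localized["u1"] >= 1  # heterogeneous network concentrates u1
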