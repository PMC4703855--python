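import numpy as np
import pytest
from scipy import linalg

from ecoloc import (
    ParamConfig,
    biregular_bipartite,
    leading_amplitude,
    leading_modes,
    make_perturbation,
    mean_field_leading_amplitude,
    mode_amplitudes,
    nm1_randomize,
    parametrize,
    propagate,
)


class TestMakePerturbation:
    def test_demographic_zero_noise_is_ones(self):
        p = make_perturbation("D", 6, zeta=0.0, seed=0)
        np.testing.assert_array_equal(p.xi, np.ones(6))

    def test_environmental_zero_noise_regular_graph_uniform(self):
        k = np.full(6, 3)
        p = make_perturbation("E", 6, degrees=k, zeta=0.0, seed=0)
        np.testing.assert_allclose(p.xi, np.ones(6))

    def test_combined_zero_noise_regular_graph_doubles(self):
        k = np.full(6, 3)
        p = make_perturbation("all", 6, degrees=k, zeta=0.0, seed=0)
        np.testing.assert_allclose(p.xi, 2 * np.ones(6))

    def test_environmental_scales_with_degree(self):
        k = np.array([1, 2, 4])
        p = make_perturbation("E", 3, degrees=k, zeta=0.0, seed=0)
        np.testing.assert_allclose(p.xi, k / 4)

    def test_degree_requirement(self):
        with pytest.raises(ValueError, match="degree"):
            make_perturbation("E", 4, zeta=0.1, seed=0)
        with pytest.raises(ValueError, match="kind"):
            make_perturbation("X", 4, zeta=0.1, seed=0)

    def test_reuse_noise_reuses_demographic_draw(self):
        k = np.array([2.0, 4.0])
        p = make_perturbation("all", 2, degrees=k, zeta=0.5, seed=3, reuse_noise=True)
        d = make_perturbation("D", 2, zeta=0.5, seed=3)
        np.testing.assert_allclose(p.xi, d.xi * (1 + k / 4.0))


class TestModeAmplitudes:
    def test_reconstruction_at_time_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            M = rng.normal(size=(5, 5)) - 4 * np.eye(5)
            xi = rng.normal(size=5)
            A = mode_amplitudes(M, xi)
            vals, V = np.linalg.eig(M)
            order = np.lexsort((np.arange(5), -vals.imag, -vals.real))
            np.testing.assert_allclose((V[:, order] @ A).real, xi, atol=1e-8)

    def test_symmetric_eigenmode_input_is_pure(self):
        M = np.array([[-2.0, 1.0], [1.0, -2.0]])
        s = leading_modes(M)
        A = mode_amplitudes(M, s.v1)
        assert abs(A[0]) == pytest.approx(1.0)
        assert abs(A[1]) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_perturbation_has_zero_leading_amplitude(self):
        """A pulse orthogonal to u1 decays on the subleading timescale."""
        M = np.diag([-1.0, -2.0, -3.0])
        s = leading_modes(M)
        xi = np.array([0.0, 1.0, 1.0])
        assert s.u1 @ xi == pytest.approx(0.0, abs=1e-12)
        assert leading_amplitude(s, xi) == pytest.approx(0.0, abs=1e-12)


class TestPropagate:
    def test_decoupled_decay(self):
        res = propagate(np.diag([-1.0, -1.0]), np.ones(2), t_grid=np.array([0.0, 1.0]))
        np.testing.assert_allclose(res.trajectory[:, 1], np.exp(-1) * np.ones(2), rtol=1e-10)
        np.testing.assert_allclose(res.trajectory[:, 0], np.ones(2), atol=1e-10)

    def test_eigen_and_expm_agree(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(8, 8)) - 6 * np.eye(8)
        xi = rng.normal(size=8)
        t = np.linspace(0, 2, 7)
        a = propagate(M, xi, t, method="eigen").trajectory
        b = propagate(M, xi, t, method="expm").trajectory
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)

    def test_reactive_transient_growth(self):
        """Stable but reactive: the envelope exceeds 1 before decaying."""
        M = np.array([[-1.0, 0.0], [10.0, -1.0]])
        t = np.linspace(0, 8, 60)
        res = propagate(M, np.array([1.0, 0.0]), t)
        assert res.envelope.max() > 1.5
        assert res.envelope[-1] < 0.1

    def test_pure_leading_mode_envelope(self):
        M = np.array([[-2.0, 1.0], [1.0, -2.0]])
        s = leading_modes(M)
        t = np.linspace(0, 3, 10)
        res = propagate(M, s.v1, t)
        np.testing.assert_allclose(res.envelope, np.exp(s.lambda1 * t), rtol=1e-8)

    def test_worst_case_growth_rate_is_reactivity(self):
        """Initial growth of the reactivity eigenvector matches lambda_H."""
        M = np.array([[-1.0, 0.0], [10.0, -1.0]])
        s = leading_modes(M)
        res = propagate(M, s.wH, np.linspace(0, 1, 5))
        assert res.initial_growth_rate == pytest.approx(s.lambdaH, abs=1e-4)

    def test_growth_rate_bounded_by_reactivity(self):
        from ecoloc import reactivity

        rng = np.random.default_rng(4)
        M = rng.normal(size=(6, 6)) - 5 * np.eye(6)
        lamH, _ = reactivity(M)
        for _ in range(10):
            xi = rng.normal(size=6)
            res = propagate(M, xi, np.linspace(0, 1, 5))
            assert res.initial_growth_rate <= lamH + 1e-6

    def test_long_run_trajectory_aligns_with_v1(self, powerlaw_net):
        """Past the spectral gap, the surviving perturbation is carried by v1."""
        cfg = ParamConfig(delta=0.5, abundance_sd=0.0, seed=0)
        _, Phi = parametrize(powerlaw_net, cfg)
        s = leading_modes(Phi)
        rng = np.random.default_rng(2)
        xi = np.abs(rng.normal(1, 0.2, powerlaw_net.S))
        T = 30 / abs(s.lambda1)
        res = propagate(Phi, xi, np.array([0.0, T]))
        final = res.trajectory[:, -1]
        cos = abs(final @ s.v1) / np.linalg.norm(final)
        assert cos > 0.999

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            propagate(-np.eye(2), np.ones(2), np.array([1.0, 0.0]))


class TestMeanFieldAmplitude:
    def test_extremes(self):
        S = 30
        uniform = np.ones(S) / np.sqrt(S)
        basis = np.zeros(S)
        basis[0] = 1.0
        assert mean_field_leading_amplitude(uniform) == pytest.approx(np.sqrt(S))
        assert mean_field_leading_amplitude(basis) == pytest.approx(1.0)

    def test_random_nonnegative_vectors_between_extremes(self):
        rng = np.random.default_rng(6)
        S = 20
        for _ in range(200):
            v = np.abs(rng.normal(size=S))
            a = mean_field_leading_amplitude(v)
            assert 1.0 - 1e-9 <= a <= np.sqrt(S) + 1e-9


def test_localized_sets_of_wH_and_v1_coincide(powerlaw_net):
    """On a heterogeneous network the top reactive-eigenvector species are
    the same ones that absorb the perturbation asymptotically, more so than
    on connectivity-only randomizations."""
    cfg = ParamConfig(delta=0.5, abundance_sd=0.0, seed=0)

    def top_overlap(net):
        _, Phi = parametrize(net, cfg)
        s = leading_modes(Phi)
        m = 10
        top = lambda q: set(np.argsort(-np.abs(q))[:m])
        return len(top(s.wH) & top(s.v1)) / m

    obs = top_overlap(powerlaw_net)
    null = np.mean([top_overlap(nm1_randomize(powerlaw_net, seed=s)) for s in range(15)])
    assert obs >= null
    assert obs >= 0.7
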