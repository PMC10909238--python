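import numpy as np
import pytest

from dtocrop.errors import ConfigurationError
from dtocrop.features import SearchSpace
from dtocrop.optimizers import (
    DTOConfig,
    MSCAConfig,
    Swarm,
    dto_step,
    firefly_move,
    msca_step,
    optimize,
    sca_step,
)
from oracles import scalar_dto_step, scalar_firefly_move, scalar_msca_step, scalar_sca_step


def box(d, lo=-10.0, hi=10.0):
    return SearchSpace(np.full(d, lo), np.full(d, hi))


class _PresetRNG:
    """Stub generator returning preset arrays for the documented draw order."""

    def __init__(self, values):
        self._values = list(values)

    def random(self, *args, **kwargs):
        return self._values.pop(0)

    def uniform(self, *args, **kwargs):
        return self._values.pop(0)

    def standard_normal(self, *args, **kwargs):
        return self._values.pop(0)


def make_swarm(P, V=None, f=None):
    P = np.asarray(P, float)
    f = np.zeros(len(P)) if f is None else np.asarray(f, float)
    best = int(np.argmin(f))
    return Swarm(
        P=P.copy(),
        V=np.zeros_like(P) if V is None else np.asarray(V, float),
        f=f.copy(),
        P_best=P.copy(),
        f_best=f.copy(),
        P_Gbest=P[best].copy(),
        f_Gbest=float(f[best]),
    )


class TestDTOStep:
    def test_defaults_carry_reported_coefficients(self):
        cfg = DTOConfig()
        assert cfg.K4 == 1.7 and cfg.K5 == 1.8
        assert cfg.k_range == (0.0, 2.0)

    def test_fixed_point_of_velocity_branch(self):
        """At P = P_best = P_Gbest with V = 0 and r3 >= 0.5 the position is unchanged."""
        swarm = make_swarm([[0.0]])
        rng = _PresetRNG([np.array([[0.5, 0.5, 0.9]]), np.array([[1.0, 1.0, 1.0]])])
        dto_step(swarm, lambda x: 0.0, box(1), DTOConfig(), t=0, rng=rng)
        assert swarm.P[0, 0] == 0.0 and swarm.V[0, 0] == 0.0

    def test_hand_computed_velocity_branch(self):
        """P=2, P_best=4, P_Gbest=4, V=0, K3=0.5, r1=r2=1, r3=0.9:
        V' = 1.7*2 + 1.8*2 = 7.0 and Y = 9.0."""
        swarm = make_swarm([[2.0]], f=[1.0])
        swarm.P_best = np.array([[4.0]])
        swarm.P_Gbest = np.array([4.0])
        rng = _PresetRNG([np.array([[1.0, 1.0, 0.9]]), np.array([[0.7, 0.3, 0.5]])])
        dto_step(swarm, lambda x: 0.0, box(1), DTOConfig(), t=0, rng=rng)
        assert swarm.V[0, 0] == pytest.approx(7.0)
        assert swarm.P[0, 0] == pytest.approx(9.0)

    def test_matches_scalar_transcription(self, sphere):
        """One full step on m=3, d=2 agrees with the loop oracle to 1e-12."""
        space = box(2, -4, 4)
        rng = np.random.default_rng(77)
        P0 = rng.uniform(-4, 4, (3, 2))
        f0 = np.array([sphere(x) for x in P0])
        swarm = make_swarm(P0, f=f0)
        cfg = DTOConfig(m=3, T=5)
        exp_P, exp_V = scalar_dto_step(
            P0, np.zeros_like(P0), P0, f0, P0[np.argmin(f0)],
            space.lower, space.upper, cfg.K4, cfg.K5, cfg.k_range,
            np.random.default_rng(123),
        )
        dto_step(swarm, sphere, space, cfg, t=0, rng=np.random.default_rng(123))
        np.testing.assert_allclose(swarm.P, exp_P, atol=1e-12)
        np.testing.assert_allclose(swarm.V, exp_V, atol=1e-12)


class TestSCAStep:
    def test_zero_amplitude_leaves_positions_unchanged(self):
        cfg = MSCAConfig(T=10)
        P = np.array([[1.0, -2.0], [0.5, 3.0]])
        out = sca_step(P, np.array([0.0, 0.0]), t=10, cfg=cfg, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out, P)

    def test_hand_computed_sine_branch(self):
        """X=1, best=3, r1=1, r2=pi/2, r3=1, r4=0: X' = 1 + sin(pi/2)*|3-1| = 3."""
        cfg = MSCAConfig(T=2, a=2.0)  # t=1 -> r1 = 2*(1 - 1/2) = 1
        rng = _PresetRNG([np.array([[np.pi / 2]]), np.array([[1.0]]), np.array([[0.0]])])
        out = sca_step(np.array([[1.0]]), np.array([3.0]), t=1, cfg=cfg, rng=rng)
        assert out[0, 0] == pytest.approx(3.0)

    def test_sine_of_zero_angle_keeps_position(self):
        cfg = MSCAConfig(T=2, a=2.0)
        rng = _PresetRNG([np.array([[0.0]]), np.array([[1.0]]), np.array([[0.0]])])
        out = sca_step(np.array([[1.0]]), np.array([3.0]), t=1, cfg=cfg, rng=rng)
        assert out[0, 0] == pytest.approx(1.0)

    def test_matches_scalar_transcription(self):
        cfg = MSCAConfig(m=3, T=7)
        P = np.random.default_rng(5).uniform(-3, 3, (3, 2))
        best = np.array([0.5, -0.5])
        out = sca_step(P, best, t=2, cfg=cfg, rng=np.random.default_rng(9))
        exp = scalar_sca_step(P, best, 2, cfg.T, cfg.a, np.random.default_rng(9))
        np.testing.assert_allclose(out, exp, atol=1e-12)


class TestFireflyMove:
    def test_identical_positions_without_jitter_unmoved(self):
        cfg = MSCAConfig(alpha0=0.0)
        xi = np.array([1.0, 2.0])
        out = firefly_move(xi, xi, t=0, cfg=cfg, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out, xi)

    def test_full_attraction_reaches_partner(self):
        cfg = MSCAConfig(beta0=1.0, gamma=0.0, alpha0=0.0)
        out = firefly_move(np.array([0.0, 1.0]), np.array([5.0, -2.0]), 0, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out, [5.0, -2.0])

    def test_closed_form_damped_attraction(self):
        """xi=0, xj=2, beta0=1, gamma=0.25: 0 + exp(-0.25*4)*2 = 2/e."""
        cfg = MSCAConfig(beta0=1.0, gamma=0.25, alpha0=0.0)
        out = firefly_move(np.array([0.0]), np.array([2.0]), 0, cfg, np.random.default_rng(0))
        assert out[0] == pytest.approx(2.0 * np.exp(-1.0), abs=1e-12)

    def test_matches_scalar_transcription_with_jitter(self):
        cfg = MSCAConfig(beta0=0.8, gamma=0.5, alpha0=0.2, alpha_decay=0.9)
        xi, xj = np.array([0.3, -1.0]), np.array([1.5, 2.0])
        out = firefly_move(xi, xj, t=3, cfg=cfg, rng=np.random.default_rng(21))
        exp = scalar_firefly_move(
            xi, xj, 3, cfg.beta0, cfg.gamma, cfg.alpha0, cfg.alpha_decay,
            np.random.default_rng(21),
        )
        np.testing.assert_allclose(out, exp, atol=1e-12)


class TestMSCAStep:
    def test_matches_scalar_transcription(self, sphere):
        space = box(2, -4, 4)
        P = np.random.default_rng(3).uniform(-4, 4, (3, 2))
        f = np.array([sphere(x) for x in P])
        swarm = make_swarm(P, f=f)
        cfg = MSCAConfig(m=3, T=6, phi_threshold=0.4)
        t = 4  # past the activation point
        exp = scalar_msca_step(
            P, f, swarm.P_Gbest, t, cfg, space.lower, space.upper,
            np.random.default_rng(31), np.random.default_rng(32),
        )
        msca_step(
            swarm, sphere, space, cfg, t,
            rng_move=np.random.default_rng(31), rng_fa=np.random.default_rng(32),
        )
        np.testing.assert_allclose(swarm.P, exp, atol=1e-12)

    def test_inactive_phase_is_pure_sca(self, sphere):
        """Before a third of the budget elapses the trajectory equals SCA's."""
        space = box(3)
        cfg = MSCAConfig(m=4, T=9, seed=13)
        hist_sca = optimize(sphere, space, algo="sca", cfg=cfg).history
        hist_msca = optimize(sphere, space, algo="msca", cfg=cfg).history
        n_inactive = int(np.ceil(cfg.activation_fraction * cfg.T))
        np.testing.assert_array_equal(hist_sca[: n_inactive + 1], hist_msca[: n_inactive + 1])

    def test_unreachable_threshold_is_pure_sca_throughout(self, sphere):
        space = box(3)
        sca = optimize(sphere, space, algo="sca", cfg=MSCAConfig(m=4, T=12, seed=2))
        msca = optimize(
            sphere, space, algo="msca", cfg=MSCAConfig(m=4, T=12, seed=2, phi_threshold=1.0)
        )
        np.testing.assert_array_equal(sca.history, msca.history)
        np.testing.assert_array_equal(sca.x, msca.x)

    def test_zero_threshold_moves_every_row_by_firefly(self, sphere):
        """phi_threshold=0 past activation: all rows take the firefly branch."""
        space = box(2, -4, 4)
        P = np.random.default_rng(6).uniform(-4, 4, (3, 2))
        f = np.array([sphere(x) for x in P])
        swarm = make_swarm(P, f=f)
        cfg = MSCAConfig(m=3, T=6, phi_threshold=0.0, alpha0=0.0)
        msca_step(
            swarm, sphere, space, cfg, t=5,
            rng_move=np.random.default_rng(41), rng_fa=np.random.default_rng(42),
        )
        gbest = P[np.argmin(f)]
        for i in range(3):
            exp = P[i] + cfg.beta0 * np.exp(-cfg.gamma * np.sum((gbest - P[i]) ** 2)) * (gbest - P[i])
            np.testing.assert_allclose(swarm.P[i], np.clip(exp, -4, 4), atol=1e-12)


class TestOptimize:
    @pytest.mark.parametrize("algo", ["dto", "sca", "msca"])
    def test_sphere_convergence_and_monotonicity(self, algo, sphere):
        space = box(5, -5, 5)
        finals = []
        for seed in range(5):
            cfg = (
                DTOConfig(m=20, T=60, seed=seed)
                if algo == "dto"
                else MSCAConfig(m=20, T=60, seed=seed)
            )
            res = optimize(sphere, space, algo=algo, cfg=cfg)
            assert np.all(np.diff(res.history) <= 0)
            assert np.all(res.x >= space.lower) and np.all(res.x <= space.upper)
            assert res.nfev == cfg.m * (cfg.T + 1)
            finals.append(res.fun)
        assert np.median(finals) < 1e-2

    def test_seed_determinism(self, sphere):
        space = box(4)
        a = optimize(sphere, space, "msca", MSCAConfig(m=6, T=20, seed=99))
        b = optimize(sphere, space, "msca", MSCAConfig(m=6, T=20, seed=99))
        np.testing.assert_array_equal(a.history, b.history)
        np.testing.assert_array_equal(a.x, b.x)

    def test_constant_objective_history_is_flat(self):
        res = optimize(lambda x: 3.5, box(2), "dto", DTOConfig(m=4, T=10, seed=0))
        assert np.all(res.history == 3.5)

    def test_zero_iterations_returns_initial_best(self, sphere):
        res = optimize(sphere, box(3), "dto", DTOConfig(m=8, T=0, seed=1))
        assert len(res.history) == 1 and res.nfev == 8
        assert res.fun == res.history[0]

    def test_non_finite_objective_penalized_not_fatal(self):
        def nasty(x):
            return np.nan if x[0] > 0 else float(np.sum(x**2))

        res = optimize(nasty, box(1, -1, 1), "dto", DTOConfig(m=6, T=5, seed=3))
        assert np.isfinite(res.fun)

    def test_msca_vs_sca_sphere_soft_comparison(self, sphere, recwarn):
        """The hybrid is expected to match SCA on the sphere; a miss is logged
        as a warning, not an error (no bound is claimed)."""
        import warnings

        space = box(5, -5, 5)
        med = {}
        for algo in ("sca", "msca"):
            med[algo] = np.median(
                [
                    optimize(sphere, space, algo, MSCAConfig(m=10, T=40, seed=s)).fun
                    for s in range(5)
                ]
            )
        if med["msca"] > med["sca"]:
            warnings.warn(
                f"MSCA median {med['msca']:.2e} above SCA median {med['sca']:.2e} on sphere"
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            DTOConfig(m=1)
        with pytest.raises(ConfigurationError):
            MSCAConfig(phi_threshold=1.5)
        with pytest.raises(ConfigurationError):
            optimize(lambda x: 0.0, box(2), "nope")
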