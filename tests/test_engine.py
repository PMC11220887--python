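import numpy as np
import pytest
from scipy.stats import pearsonr

from sadret import (
    EngineConfig,
    EngineSetup,
    ReflectionSet,
    amplitude_projection,
    cc_pearson,
    cf_real_space,
    init_random_density,
    monitor_fom,
    n_tf_rule,
    pi_half_perturb,
    raar_real_space,
    run_multi,
    run_trial,
    tangent_refine,
    triplet_sums,
)
from sadret.engine import _detect_jump, convolution_grid_dims, fft_grid_dims


class TestNTfRule:
    @pytest.mark.parametrize(
        "n_obs,expected",
        [(4999, 1000), (5000, 1300), (6000, 1300), (7999, 1300),
         (8000, 1500), (9000, 1500)],
    )
    def test_boundaries(self, n_obs, expected):
        assert n_tf_rule(n_obs) == expected

    def test_capped_at_n_obs(self):
        assert n_tf_rule(600) == 600

    def test_invalid(self):
        with pytest.raises(ValueError):
            n_tf_rule(0)


class TestEngineConfig:
    def test_defaults_follow_reported_values(self):
        cfg = EngineConfig()
        assert cfg.beta == 0.82
        assert cfg.perturb_fraction == 0.13
        assert cfg.tf_start == 100 and cfg.tf_stride == 20
        assert cfg.n_trials == 400

    @pytest.mark.parametrize(
        "kw", [{"beta": 0.0}, {"beta": 1.0}, {"perturb_fraction": 0.0},
               {"w_best": 1.5}, {"n_iter": 0}, {"algorithm": "hio"}],
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            EngineConfig(**kw)


def _refl(hkl, E, observed=None, absent=None, beyond=None, phase=None):
    n = len(hkl)
    return ReflectionSet(
        np.asarray(hkl), E=np.asarray(E, float),
        phase=np.zeros(n) if phase is None else np.asarray(phase, float),
        d=np.full(n, 3.0), observed=observed, absent=absent, beyond=beyond,
    )


class TestAmplitudeProjection:
    def setup_method(self):
        self.hkl = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])

    def test_observed_replaced_phase_kept(self):
        calc = _refl(self.hkl, [1.0, 1.0, 1.0], phase=[np.radians(40), 0.1, 0.2])
        obs = _refl(self.hkl, [2.0, 3.0, 4.0])
        out = amplitude_projection(calc, obs)
        assert np.allclose(out.E, [2.0, 3.0, 4.0])
        assert np.isclose(out.phase[0], np.radians(40))

    def test_absent_zeroed(self):
        calc = _refl(self.hkl, [0.7, 0.7, 0.7])
        obs = _refl(self.hkl, [2.0, 2.0, 2.0],
                    observed=[True, False, True], absent=[False, True, False])
        out = amplitude_projection(calc, obs)
        assert out.E[1] == 0.0

    def test_free_untouched_bitwise(self):
        calc = _refl(self.hkl, [0.712345, 0.5, 0.25], phase=[0.3, 0.4, 0.5])
        obs = _refl(self.hkl, [2.0, 0.0, 2.0], observed=[True, False, True])
        out = amplitude_projection(calc, obs)
        assert out.E[1] == calc.E[1]
        assert out.phase[1] == calc.phase[1]

    def test_mismatched_indices_raise(self):
        calc = _refl(self.hkl, [1, 1, 1])
        obs = _refl(self.hkl[::-1], [1, 1, 1])
        with pytest.raises(ValueError):
            amplitude_projection(calc, obs)


class TestPiHalf:
    def test_zero_fraction_identity(self):
        refl = _refl(np.array([[1, 0, 0], [2, 0, 0]]), [1.0, 2.0])
        out = pi_half_perturb(refl, 0.0)
        assert np.array_equal(out.phase, refl.phase)

    def test_four_applications_identity(self, rng):
        hkl = np.stack([np.arange(1, 11), np.zeros(10, int), np.zeros(10, int)], 1)
        refl = _refl(hkl, rng.uniform(0.1, 3.0, 10), phase=rng.uniform(0, 6, 10))
        out = refl
        for _ in range(4):
            out = pi_half_perturb(out, 0.5)
        assert np.allclose(np.exp(1j * out.phase), np.exp(1j * refl.phase))

    def test_exactly_smallest_half_shifted(self):
        hkl = np.stack([np.arange(1, 11), np.zeros(10, int), np.zeros(10, int)], 1)
        E = np.arange(10, 0, -1.0)  # descending: smallest are last 5 rows
        refl = _refl(hkl, E)
        out = pi_half_perturb(refl, 0.5)
        assert out.weak.sum() == 5
        assert set(np.flatnonzero(out.weak)) == set(range(5, 10))
        assert np.allclose(out.phase[out.weak], np.pi / 2)
        assert np.allclose(out.phase[~out.weak], 0.0)

    def test_sign_option(self):
        hkl = np.array([[1, 0, 0], [2, 0, 0]])
        refl = _refl(hkl, [0.1, 5.0])
        out = pi_half_perturb(refl, 0.5, sign=-1)
        assert np.isclose(out.phase[0], -np.pi / 2)


class TestTripletSums:
    def _random_members(self, rng, n, span=6):
        """Friedel-complete random set with Hermitian values."""
        seen = {}
        while len(seen) < n:
            h = tuple(rng.integers(-span, span + 1, 3))
            if h == (0, 0, 0) or h in seen or tuple(-np.array(h)) in seen:
                continue
            seen[h] = rng.normal() + 1j * rng.normal()
        hkl = []
        vals = []
        for h, v in seen.items():
            hkl.append(h)
            vals.append(v)
            hkl.append(tuple(-np.array(h)))
            vals.append(np.conj(v))
        return np.array(hkl), np.array(vals)

    @pytest.mark.parametrize("n", [50, 100, 150])
    def test_fft_matches_brute_force(self, rng, n):
        hkl, vals = self._random_members(rng, n)
        targets = hkl[: 2 * n : 2]
        g_fft = triplet_sums(hkl, vals, targets, method="fft")
        g_direct = triplet_sums(hkl, vals, targets, method="direct")
        scale = np.abs(g_direct).max()
        assert np.abs(g_fft - g_direct).max() < 1e-6 * max(scale, 1.0)

    def test_undersized_grid_rejected(self, rng):
        hkl, vals = self._random_members(rng, 20)
        with pytest.raises(ValueError, match="alias"):
            triplet_sums(hkl, vals, hkl[:5], dims=(8, 8, 8))

    def test_single_triplet_toy(self):
        # members {k, h-k} with phi_k + phi_{h-k} = 60 deg -> phi_tf(h) = 60
        k = np.array([1, 0, 0])
        hmk = np.array([0, 1, 0])
        h = k + hmk
        phi_k, phi_hmk = np.radians(25.0), np.radians(35.0)
        members = np.array([k, -k, hmk, -hmk])
        vals = np.array([
            np.exp(1j * phi_k), np.exp(-1j * phi_k),
            np.exp(1j * phi_hmk), np.exp(-1j * phi_hmk),
        ])
        g = triplet_sums(members, vals, h[None, :], method="direct")
        assert np.isclose(np.degrees(np.angle(g[0])), 60.0, atol=1e-9)
        g2 = triplet_sums(members, vals, h[None, :], method="fft")
        assert np.isclose(np.degrees(np.angle(g2[0])), 60.0, atol=1e-6)


class TestTangentRefine:
    def test_matches_truth_on_clean_data(self, small_p212121_problem):
        cell, sg, refl, truth = small_p212121_problem
        m = {tuple(h): i for i, h in enumerate(truth["hkl"])}
        work = refl.copy()
        work.phase = np.array([truth["phases"][m[tuple(h)]] for h in work.hkl])
        out = tangent_refine(work, sg, n_tf=150)
        s = out.strong
        assert s.sum() == 150
        dphi = np.angle(np.exp(1j * (out.phase[s] - work.phase[s])))
        assert np.degrees(np.abs(dphi)).mean() < 15.0

    def test_strong_set_is_largest_E(self, small_p212121_problem):
        cell, sg, refl, _ = small_p212121_problem
        out = tangent_refine(refl, sg, n_tf=50)
        emin_strong = refl.E[out.strong].min()
        assert (refl.E[~out.strong & refl.observed] <= emin_strong + 1e-12).all()


class TestRealSpaceUpdates:
    def test_raar_zero_fraction_is_abs_passthrough(self, rng):
        rho = rng.normal(size=(6, 6, 6))
        last = rng.normal(size=(6, 6, 6))
        out = raar_real_space(rho, last, beta=0.82, perturb_fraction=0.13,
                              delta=rho.min() - 1.0)
        assert np.array_equal(out, np.abs(rho))

    def test_raar_beta_half_perturbed_branch(self, rng):
        rho = rng.normal(size=(5, 5, 5))
        last = rng.normal(size=(5, 5, 5))
        out = raar_real_space(rho, last, beta=0.5, perturb_fraction=0.5,
                              delta=np.abs(rho).max() + 1.0)
        assert np.allclose(out, np.abs(0.5 * last))

    def test_raar_beta_one_fixed_point_zero(self, rng):
        rho = rng.normal(size=(5, 5, 5))
        out = raar_real_space(rho, np.abs(rho), beta=1.0 - 1e-15,
                              perturb_fraction=0.5,
                              delta=np.abs(rho).max() + 1.0)
        assert np.abs(out).max() < 1e-12

    def test_raar_fraction_semantics(self, rng):
        rho = rng.normal(size=(10, 10, 10))
        last = np.zeros_like(rho)
        out = raar_real_space(rho, last, beta=0.82, perturb_fraction=0.13)
        a = np.abs(rho)
        changed = ~np.isclose(out, a)
        assert abs(changed.mean() - 0.13) < 0.02

    def test_raar_shape_mismatch(self):
        with pytest.raises(ValueError):
            raar_real_space(np.zeros((4, 4, 4)), np.zeros((5, 5, 5)), 0.8, 0.1)

    def test_cf_zero_fraction_identity(self, rng):
        rho = rng.normal(size=(6, 6, 6))
        out = cf_real_space(rho, 0.1, delta=rho.min() - 1.0)
        assert np.array_equal(out, rho)

    def test_cf_flip_everything(self, rng):
        rho = -np.abs(rng.normal(size=(6, 6, 6)))
        out = cf_real_space(rho, 0.5, delta=rho.max() + 1.0)
        assert np.array_equal(out, -rho)

    def test_cf_involution_with_fixed_delta(self, rng):
        rho = rng.uniform(-0.9, 0.9, size=(6, 6, 6))
        once = cf_real_space(rho, 0.5, delta=1.0)
        twice = cf_real_space(once, 0.5, delta=1.0)
        assert np.allclose(twice, rho)


class TestPearson:
    def test_linear_relation(self, rng):
        x = rng.uniform(0, 5, 100)
        assert np.isclose(cc_pearson(x, 3 * x + 1), 1.0)
        assert np.isclose(cc_pearson(x, -x), -1.0)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000) + 0.3 * x
        assert abs(cc_pearson(x, y) - pearsonr(x, y).statistic) < 1e-12

    def test_zero_variance(self):
        assert cc_pearson(np.ones(10), np.arange(10.0)) == 0.0


class TestMonitorFom:
    def test_r_zero_for_identical(self, rng):
        e = rng.uniform(0.5, 2, 50)
        fom = monitor_fom(rng.normal(size=(8, 8, 8)), e, e)
        assert np.isclose(fom["r_factor"], 0.0)

    def test_r_scale_invariant(self, rng):
        e = rng.uniform(0.5, 2, 50)
        fom = monitor_fom(np.zeros((4, 4, 4)), e, 5.0 * e)
        assert np.isclose(fom["r_factor"], 0.0)

    def test_gaussian_skewness_small(self, rng):
        fom = monitor_fom(rng.normal(size=(32, 32, 32)),
                          np.arange(1, 11.0), np.arange(1, 11.0))
        assert abs(fom["skewness"]) < 0.05

    def test_spike_skewness_large(self):
        grid = np.zeros((16, 16, 16))
        grid[3, 4, 5] = 50.0
        fom = monitor_fom(grid, np.arange(1, 11.0), np.arange(1, 11.0))
        assert fom["skewness"] > 1.0


class TestGridDims:
    def test_even_and_smooth(self):
        from sadret import UnitCell
        dims = fft_grid_dims(UnitCell(40, 50, 60), 2.0, factor=3.0)
        for n in dims:
            assert n % 2 == 0
            m = n
            for p in (2, 3, 5):
                while m % p == 0:
                    m //= p
            assert m == 1

    def test_convolution_dims_bound(self):
        dims = convolution_grid_dims([10, 12, 15])
        assert all(d >= 3 * h + 1 for d, h in zip(dims, [10, 12, 15]))


class TestInitRandomDensity:
    def test_real_zero_mean_deterministic(self, small_p1_problem):
        cell, sg, refl, _ = small_p1_problem
        g1 = init_random_density(refl, cell, sg, seed=3)
        g2 = init_random_density(refl, cell, sg, seed=3)
        g3 = init_random_density(refl, cell, sg, seed=4)
        assert np.array_equal(g1.values, g2.values)
        assert not np.array_equal(g1.values, g3.values)
        assert abs(g1.values.mean()) < 1e-12 * np.abs(g1.values).max()

    def test_hermitian_synthesis_is_real(self, small_p212121_problem):
        cell, sg, refl, _ = small_p212121_problem
        cfg = EngineConfig()
        setup = EngineSetup(refl, cell, sg, cfg)
        rng = np.random.default_rng(0)
        z = np.where(setup.obs_mask,
                     setup.E_obs * np.exp(1j * rng.uniform(0, 6.28, len(setup.hkl))),
                     0)
        assert setup.synth_imag_ratio(z) < 1e-10


class TestSetupRoundTrip:
    def test_analyze_of_synthesize_identity(self, small_p212121_problem):
        cell, sg, refl, truth = small_p212121_problem
        setup = EngineSetup(refl, cell, sg, EngineConfig())
        m = {tuple(h): i for i, h in enumerate(truth["hkl"])}
        idx = np.array([m[tuple(h)] for h in setup.hkl])
        z = truth["f_a"][idx] * np.exp(1j * truth["phases"][idx])
        z2 = setup.analyze(setup.synthesize(z))
        assert np.allclose(z, z2, rtol=1e-9, atol=1e-9 * np.abs(z).max())


class TestRunTrial:
    def test_trace_length_and_determinism(self, small_p1_problem):
        cell, sg, refl, _ = small_p1_problem
        cfg = EngineConfig(n_iter=60, w_best=0.3, seed=0)
        setup = EngineSetup(refl, cell, sg, cfg)
        r1 = run_trial(refl, cell, sg, cfg, seed=5, setup=setup)
        r2 = run_trial(refl, cell, sg, cfg, seed=5, setup=setup)
        r3 = run_trial(refl, cell, sg, cfg, seed=6, setup=setup)
        assert len(r1.cc_trace) == 60
        assert np.array_equal(r1.cc_trace, r2.cc_trace)
        assert not np.array_equal(r1.cc_trace, r3.cc_trace)

    def test_true_phases_near_fixed_point(self, small_p1_problem):
        cell, sg, refl, truth = small_p1_problem
        cfg = EngineConfig(n_iter=50, algorithm="raar", w_best=0.3)
        setup = EngineSetup(refl, cell, sg, cfg)
        m = {tuple(h): i for i, h in enumerate(truth["hkl"])}
        phases = np.array([truth["phases"][m[tuple(h)]] for h in setup.hkl])
        res = run_trial(refl, cell, sg, cfg, initial_phases=phases, setup=setup)
        assert res.cc_trace.max() - res.cc_trace.min() < 0.02 * 2 + 0.04
        assert np.abs(res.cc_trace - res.cc_trace[0]).max() < 0.05


class TestRunMulti:
    def test_auto_grid_allocation(self, small_p1_problem):
        cell, sg, refl, _ = small_p1_problem
        cfg = EngineConfig(n_iter=30, n_trials=4, w_best="auto", seed=1)
        best, summary = run_multi(refl, cell, sg, cfg)
        assert sorted(summary["w_best"]) == [0.2, 0.3, 0.4, 0.5]
        assert best.best_cc == summary["best_cc"].max()

    def test_seeds_offset_from_master(self, small_p1_problem):
        cell, sg, refl, _ = small_p1_problem
        cfg = EngineConfig(n_iter=20, n_trials=3, w_best=0.3, seed=100)
        _, summary = run_multi(refl, cell, sg, cfg)
        assert list(summary["seed"]) == [100, 101, 102]


class TestJumpDetector:
    def test_step_trace_detected(self):
        cc = np.concatenate([np.full(200, 0.15), np.full(200, 0.6)])
        converged, jump = _detect_jump(cc, 50, 0.05)
        assert converged
        assert 195 <= jump <= 255

    def test_flat_trace_not_converged(self):
        cc = np.full(400, 0.2)
        converged, jump = _detect_jump(cc, 50, 0.05)
        assert not converged and jump is None

    def test_initial_transient_ignored(self):
        cc = np.concatenate([np.linspace(0.05, 0.2, 10), np.full(390, 0.2)])
        converged, jump = _detect_jump(cc, 50, 0.05)
        assert not converged
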