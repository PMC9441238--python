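import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.stats import spearmanr

from chromstim import StimulationSystem
from chromstim.fitting import (
    FitProblem,
    fit,
    gamut_correct,
    in_gamut,
    metamers,
    resolve_underdetermined,
    silent_substitution,
)
from chromstim.fixtures import dichromat_receptors, gaussian_led_bank

from conftest import random_square_system


class TestFitBasics:
    def test_consistency_interior_recovery(self, system22):
        x_star = np.array([0.31, 0.47])
        target = system22.excitations(x_star)
        r = fit(FitProblem(system22, target))
        assert np.allclose(r.x, x_star, atol=1e-6)
        assert r.residual < 1e-8
        assert r.in_gamut

    def test_identity_skips_step2(self, dichromat, led2):
        rset = dichromat.with_transform("identity")
        sys_ = StimulationSystem(led2, rset, background=np.array([0.5, 0.5]))
        # far out-of-gamut target still solved linear-only under identity
        target = sys_.relative_captures(np.array([5.0, 5.0]))
        r = fit(FitProblem(sys_, target))
        assert r.stage == "linear-only"

    def test_in_gamut_skips_step2(self, system22):
        target = system22.excitations(np.array([0.3, 0.4]))
        r = fit(FitProblem(system22, target))
        assert r.stage == "linear-only"

    def test_out_of_gamut_two_step(self, system22):
        target = system22.transform(
            system22.relative_captures(np.array([3.0, 0.001])))
        r = fit(FitProblem(system22, target))
        assert not r.in_gamut
        assert r.stage == "two-step"
        assert np.all(r.x >= system22.lower - 1e-12)
        assert np.all(r.x <= system22.upper + 1e-12)

    def test_infeasible_bounds_error(self, system22):
        with pytest.raises(ValueError, match="lower > upper"):
            FitProblem(system22, np.zeros(2), lower=np.array([1.0, 1.0]),
                       upper=np.array([0.5, 2.0]))

    def test_nan_target_error(self, system22):
        with pytest.raises(ValueError, match="finite"):
            FitProblem(system22, np.array([np.nan, 0.0]))

    def test_zero_weights_rejected(self, system22):
        with pytest.raises(ValueError, match="zero"):
            FitProblem(system22, np.zeros(2), weights=np.zeros(2))

    def test_determinism_bit_identical(self, system22):
        target = system22.transform(
            system22.relative_captures(np.array([2.5, 0.01])))
        xs = [fit(FitProblem(system22, target)).x for _ in range(3)]
        assert np.array_equal(xs[0], xs[1])
        assert np.array_equal(xs[1], xs[2])

    def test_in_gamut_transform_and_weight_invariance(self):
        rng = np.random.default_rng(7)
        sys_log = None
        while sys_log is None:
            sys_log = random_square_system(rng, n=3, transform="log")
        x_star = rng.uniform(0.05, 0.5, 3)
        q_t = sys_log.relative_captures(x_star)
        results = {}
        for kind in ("identity", "log", "hyperbolic"):
            sys_k = StimulationSystem(list(sys_log.sources),
                                      sys_log.receptors.with_transform(kind),
                                      sys_log.background)
            target = sys_k.transform(q_t)
            for trial in range(3):
                w = rng.uniform(0.1, 2.0, 3)
                r = fit(FitProblem(sys_k, target, weights=w))
                results[(kind, trial)] = r.x
        ref = results[("identity", 0)]
        for x in results.values():
            assert np.allclose(x, ref, atol=1e-6)

    def test_weight_zero_equals_dropped_receptor(self, system32):
        rng = np.random.default_rng(8)
        target = system32.transform(
            system32.relative_captures(np.array([4.0, 0.002, 0.7])))
        w = np.array([1.0, 0.0])
        r_weighted = fit(FitProblem(system32, target, weights=w))
        # oracle: residual on the surviving receptor only
        e1 = system32.excitations(r_weighted.x)[0]
        assert abs(e1 - target[0]) <= r_weighted.residual + 1e-9

    def test_metamer_invariance(self, system22, dichromat, grid1nm):
        # two spectra with equal captures fit identically (via equal targets)
        target = system22.excitations(np.array([0.2, 0.6]))
        r1 = fit(FitProblem(system22, target.copy()))
        r2 = fit(FitProblem(system22, target.copy()))
        assert np.array_equal(r1.x, r2.x)


class TestOutOfGamutOracle:
    def test_matches_dense_grid_search(self, system22):
        """Brute-force 2-D grid search oracle at 1e-3 intensity resolution."""
        A, eta = system22.A, system22.eta
        f = np.log
        g = np.arange(0.0, 1.0 + 5e-4, 1e-3)
        X1, X2 = np.meshgrid(g, g, indexing="ij")
        E1 = f(A[0, 0] * X1 + A[0, 1] * X2 + eta[0])
        E2 = f(A[1, 0] * X1 + A[1, 1] * X2 + eta[1])
        rng = np.random.default_rng(11)
        for _ in range(12):
            q = rng.uniform(0.0, 6.0, 2) + eta  # mostly out of gamut
            target = f(q)
            r = fit(FitProblem(system22, target))
            if r.in_gamut:
                continue
            loss = (E1 - target[0]) ** 2 + (E2 - target[1]) ** 2
            i, j = np.unravel_index(np.argmin(loss), loss.shape)
            assert abs(r.x[0] - g[i]) <= 2e-3
            assert abs(r.x[1] - g[j]) <= 2e-3


class TestUnderdetermined:
    def _segment_oracle(self, system, target_e, num=20001):
        """Dense parameterization of the 1-D feasible metamer segment."""
        A, eta = system.A, system.eta
        b = system.transform.finv(target_e) - eta
        x_p, *_ = np.linalg.lstsq(A, b, rcond=None)
        d = null_space(A)[:, 0]
        ts = np.linspace(-5, 5, num)
        X = x_p[None, :] + ts[:, None] * d[None, :]
        ok = np.all((X >= system.lower - 1e-12) & (X <= system.upper + 1e-12),
                    axis=1)
        return X[ok]

    def test_min_norm_matches_segment_oracle(self, system32):
        target = system32.excitations(np.array([0.3, 0.35, 0.25]))
        r = resolve_underdetermined(FitProblem(system32, target))
        seg = self._segment_oracle(system32, target)
        norms = np.linalg.norm(seg, axis=1)
        assert np.linalg.norm(r.x) <= norms.min() + 1e-6
        assert r.residual < 1e-6

    def test_maximize_source_objective(self, system32):
        target = system32.excitations(np.array([0.3, 0.35, 0.25]))
        r = resolve_underdetermined(
            FitProblem(system32, target, objective="max_source:0"))
        seg = self._segment_oracle(system32, target)
        assert r.x[0] >= seg[:, 0].max() - 1e-5

    def test_square_system_all_objectives_agree(self, system22):
        target = system22.excitations(np.array([0.3, 0.5]))
        xs = [resolve_underdetermined(
            FitProblem(system22, target, objective=obj)).x
            for obj in ("min_norm", "max_source:0", "min_source:1", "min_diff")]
        for x in xs[1:]:
            assert np.allclose(x, xs[0], atol=1e-6)

    def test_unknown_objective(self, system32):
        with pytest.raises(ValueError, match="unknown secondary objective"):
            resolve_underdetermined(
                FitProblem(system32, np.zeros(2), objective="bogus"))


class TestGamutCorrect:
    def test_in_gamut_batch_unchanged(self, system22):
        targets = np.stack([system22.relative_captures(np.array([x, y]))
                            for x, y in [(0.2, 0.3), (0.5, 0.1), (0.3, 0.6)]])
        out = gamut_correct(targets, system22, mode="scale")
        assert np.array_equal(out, targets)

    def test_pure_intensity_overshoot_single_scale(self, system22):
        base = np.stack([system22.relative_captures(np.array([x, y]))
                         for x, y in [(0.2, 0.3), (0.5, 0.1)]])
        k = 8.0
        out = gamut_correct(k * base, system22, mode="scale")
        # one scalar: all ratios to the input identical
        s = out / (k * base)
        assert np.allclose(s, s.flat[0], rtol=1e-6)
        # all corrected targets reachable
        assert all(in_gamut(system22, t, tol=1e-6) for t in out)
        # pairwise distance ratios preserved exactly under a global scale
        d_in = np.linalg.norm(k * base[0] - k * base[1])
        d_out = np.linalg.norm(out[0] - out[1])
        assert d_out / d_in == pytest.approx(s.flat[0], rel=1e-9)

    def test_projection_beats_clipping_on_distance_ranks(self, system22):
        rng = np.random.default_rng(13)
        targets = rng.uniform(0.0, 4.0, size=(25, 2)) + system22.eta
        out = gamut_correct(targets, system22, mode="scale_and_project")
        assert all(in_gamut(system22, t, tol=1e-6) for t in out)
        # clipping baseline oracle: per-point bounded least-squares projection
        from scipy.optimize import lsq_linear

        clipped = np.stack([
            system22.A @ lsq_linear(system22.A, t - system22.eta,
                                    bounds=(system22.lower, system22.upper),
                                    method="bvls").x + system22.eta
            for t in targets
        ])

        def pairwise(v):
            iu = np.triu_indices(len(v), 1)
            d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
            return d[iu]

        rho_proj = spearmanr(pairwise(targets), pairwise(out)).statistic
        rho_clip = spearmanr(pairwise(targets), pairwise(clipped)).statistic
        assert rho_proj >= rho_clip - 1e-9

    def test_empty_batch_error(self, system22):
        with pytest.raises(ValueError, match="empty"):
            gamut_correct(np.empty((0, 2)), system22)

    def test_idempotent_on_corrected_batch(self, system22):
        rng = np.random.default_rng(14)
        targets = rng.uniform(0.0, 3.0, size=(10, 2)) + system22.eta
        once = gamut_correct(targets, system22, mode="scale_and_project")
        twice = gamut_correct(once, system22, mode="scale_and_project")
        assert np.allclose(once, twice, atol=1e-6)


class TestSilentSubstitution:
    def test_identity_matrix_modulates_one_source(self, grid1nm):
        # orthogonal (disjoint) receptors and matched disjoint sources
        import numpy as np

        from chromstim import (
            LightSource,
            Photoreceptor,
            ReceptorSet,
            SensitivityCurve,
            Spectrum,
        )

        wl = grid1nm.wavelengths
        r = ReceptorSet([
            Photoreceptor("a", SensitivityCurve(grid1nm, (wl < 450).astype(float)),
                          epsilon=1e-3),
            Photoreceptor("b", SensitivityCurve(grid1nm, (wl > 550).astype(float)),
                          epsilon=1e-3),
        ])
        sources = [
            LightSource("sa", Spectrum(grid1nm, ((wl > 350) & (wl < 430)).astype(float)),
                        upper=5.0),
            LightSource("sb", Spectrum(grid1nm, ((wl > 570) & (wl < 650)).astype(float)),
                        upper=5.0),
        ]
        sys_ = StimulationSystem(sources, r, background=np.array([1.0, 1.0]))
        x_ref, x_stim = silent_substitution(sys_, isolate=0, contrast=0.5)
        assert x_stim[1] == pytest.approx(x_ref[1], abs=1e-9)
        assert x_stim[0] > x_ref[0]

    def test_pair_verified_by_direct_capture(self, system32):
        x_ref, x_stim = silent_substitution(system32, isolate=0, contrast=0.3)
        q_ref = system32.relative_captures(x_ref)
        q_stim = system32.relative_captures(x_stim)
        assert q_stim[1] == pytest.approx(q_ref[1], abs=1e-9)
        assert q_stim[0] == pytest.approx(q_ref[0] * 1.3, abs=1e-9)

    def test_zero_contrast_identical_pair(self, system32):
        x_ref, x_stim = silent_substitution(system32, isolate=0, contrast=0.0)
        assert np.array_equal(x_ref, x_stim)

    def test_infeasible_contrast_reports_max(self, system32):
        with pytest.raises(ValueError, match="maximum achievable"):
            silent_substitution(system32, isolate=0, contrast=1e6)


class TestMetamers:
    def test_square_system_error_or_single(self, system22):
        target = system22.relative_captures(np.array([0.3, 0.4]))
        with pytest.raises(ValueError, match="fully determined"):
            metamers(system22, target, count=3)

    def test_all_verify_target(self, system32):
        target = system32.relative_captures(np.array([0.3, 0.35, 0.25]))
        xs = metamers(system32, target, count=7)
        assert len(xs) == 7
        for x in xs:
            assert np.allclose(system32.relative_captures(x), target, atol=1e-9)
        assert len(np.unique(np.round(xs, 9), axis=0)) == 7

    def test_endpoints_match_nullspace_oracle(self, system32):
        target = system32.relative_captures(np.array([0.3, 0.35, 0.25]))
        xs = metamers(system32, target, count=5)
        # oracle: feasible interval along the null-space direction
        A = system32.A
        d = null_space(A)[:, 0]
        x_p, *_ = np.linalg.lstsq(A, target - system32.eta, rcond=None)
        ts = np.linspace(-5, 5, 200001)
        X = x_p[None, :] + ts[:, None] * d[None, :]
        ok = np.all((X >= system32.lower - 1e-9) & (X <= system32.upper + 1e-9),
                    axis=1)
        lo_end, hi_end = X[ok][0], X[ok][-1]
        got = xs[np.argsort(xs @ d)]
        assert np.allclose(got[0], lo_end, atol=1e-3) or \
            np.allclose(got[0], hi_end, atol=1e-3)
        assert np.allclose(got[-1], hi_end, atol=1e-3) or \
            np.allclose(got[-1], lo_end, atol=1e-3)

    def test_out_of_gamut_target_error(self, system32):
        with pytest.raises(ValueError, match="out of gamut"):
            metamers(system32, np.array([50.0, 0.001]), count=3)
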