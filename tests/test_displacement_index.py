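import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import eccentric_curves
from refframe.core_io import ConditionGrid, TuningCurve, build_tuning
from refframe.displacement_index import (
    FlatCurveError,
    InsufficientTuningError,
    analyze_neuron,
    bootstrap_ci,
    classify_frame,
    di_by_eccentricity,
    interpolate_circular,
    neuron_di,
    pairwise_di,
)
from refframe.synthetic_data import (
    NeuronSpec,
    NoiseSpec,
    mean_rate,
    simulate_fixation_block,
    vary,
    wrapped_gaussian,
)


def _curve(headings, means):
    headings = np.asarray(headings, float)
    means = np.asarray(means, float)
    return TuningCurve(
        headings_deg=headings,
        mean_rate_hz=means,
        sem_hz=np.zeros_like(means),
        trials=[np.array([m]) for m in means],
    )


def brute_force_lag(dense_i, dense_j):
    """Independent exhaustive-search oracle for the covariance-maximizing lag."""
    a = dense_i - dense_i.mean()
    b = dense_j - dense_j.mean()
    best_k, best_c = None, -np.inf
    for k in sorted(range(-180, 181), key=lambda k: (abs(k), k > 0)):
        c = float(np.mean(a * np.roll(b, -k)))  # b rolled so b[theta+k] aligns
        if c > best_c + 1e-9:
            best_k, best_c = k, c
    return best_k


class TestInterpolateCircular:
    def test_sample_points_reproduced(self):
        h = np.arange(0.0, 360.0, 45.0)
        vals = np.array([3.0, 9.0, 20.0, 9.0, 3.0, 1.0, 0.5, 1.0])
        grid, dense = interpolate_circular(_curve(h, vals))
        for hh, v in zip(h, vals):
            assert dense[int(hh)] == pytest.approx(v)

    def test_circular_midpoint_across_zero(self):
        curve = _curve([10.0, 180.0, 350.0], [20.0, 5.0, 10.0])
        _, dense = interpolate_circular(curve)
        assert dense[0] == pytest.approx(15.0)

    def test_interpolation_error_bounded_vs_dense_oracle(self):
        spec = NeuronSpec(theta_p_deg=100.0, sigma=1.8, noise=NoiseSpec("none"))
        h = np.arange(0.0, 360.0, 45.0)
        curve = _curve(h, mean_rate(spec, h, 0.0))
        grid, dense = interpolate_circular(curve)
        truth = mean_rate(spec, grid, 0.0)
        # brute-force: max deviation of a chord from the function on 45-deg gaps
        max_err = 0.0
        for i in range(8):
            x0, x1 = h[i], h[i] + 45.0
            y0 = mean_rate(spec, x0, 0.0)
            y1 = mean_rate(spec, x1, 0.0)
            xs = np.arange(x0, x1)
            chord = y0 + (y1 - y0) * (xs - x0) / 45.0
            max_err = max(max_err, np.abs(chord - mean_rate(spec, xs, 0.0)).max())
        assert np.abs(dense - truth).max() <= max_err + 1e-9

    def test_duplicate_headings_rejected(self):
        curve = _curve([0.0, 0.0, 90.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="duplicate"):
            interpolate_circular(curve)

    def test_too_few_headings(self):
        with pytest.raises(ValueError):
            interpolate_circular(_curve([0.0, 180.0], [1.0, 2.0]))


class TestPairwiseDI:
    def test_identical_curves_zero(self):
        h = np.arange(0.0, 360.0, 45.0)
        spec = NeuronSpec(noise=NoiseSpec("none"))
        c = _curve(h, mean_rate(spec, h, 0.0))
        di, k = pairwise_di(c, c, 0.0, 20.0)
        assert di == 0.0 and k == 0

    def test_exact_20_degree_shift_gives_one(self):
        h = np.arange(0.0, 360.0, 45.0)
        spec = NeuronSpec(theta_p_deg=90.0, noise=NoiseSpec("none"))
        ci = _curve(h, wrapped_gaussian(h, 90.0, 1.5, 50.0, 0.0, 1.0, 5.0))
        cj = _curve(h, wrapped_gaussian(h, 110.0, 1.5, 50.0, 0.0, 1.0, 5.0))
        di, k = pairwise_di(ci, cj, 0.0, 20.0)
        assert di == 1.0 and k == 20

    def test_half_shift_gives_half(self):
        h = np.arange(0.0, 360.0, 45.0)
        ci = _curve(h, wrapped_gaussian(h, 90.0, 1.5, 50.0))
        cj = _curve(h, wrapped_gaussian(h, 100.0, 1.5, 50.0))
        di, k = pairwise_di(ci, cj, 0.0, 20.0)
        # oracle: exhaustive lag search on the same interpolated curves
        _, di_dense = interpolate_circular(ci)
        _, dj_dense = interpolate_circular(cj)
        assert k == brute_force_lag(di_dense, dj_dense)
        assert di == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            h = np.arange(0.0, 360.0, 45.0)
            spec = NeuronSpec(
                theta_p_deg=float(rng.uniform(0, 360)),
                sigma=float(rng.uniform(0.8, 3.0)),
                a1=float(rng.uniform(20, 80)),
                a2=float(rng.uniform(0, 0.5)),
                r0=float(rng.uniform(0, 10)),
                noise=NoiseSpec("none"),
            )
            vi = mean_rate(spec, h, 0.0) + rng.normal(0, 3, len(h))
            vj = mean_rate(spec, h, 0.0) + rng.normal(0, 3, len(h))
            ci, cj = _curve(h, vi), _curve(h, vj)
            _, di_dense = interpolate_circular(ci)
            _, dj_dense = interpolate_circular(cj)
            _, k = pairwise_di(ci, cj, 0.0, 20.0)
            assert k == brute_force_lag(di_dense, dj_dense)

    def test_symmetry(self, rng):
        h = np.arange(0.0, 360.0, 45.0)
        for _ in range(20):
            vi = rng.uniform(0, 50, len(h))
            vj = rng.uniform(0, 50, len(h))
            ci, cj = _curve(h, vi), _curve(h, vj)
            dij, _ = pairwise_di(ci, cj, -20.0, 20.0)
            dji, _ = pairwise_di(cj, ci, 20.0, -20.0)
            assert dij == pytest.approx(dji)

    def test_affine_invariance(self, rng):
        h = np.arange(0.0, 360.0, 45.0)
        vi = rng.uniform(0, 50, len(h))
        vj = rng.uniform(0, 50, len(h))
        di0, k0 = pairwise_di(_curve(h, vi), _curve(h, vj), 0.0, 20.0)
        for a, b in [(2.5, 3.0), (0.3, -1.0), (10.0, 100.0)]:
            di1, k1 = pairwise_di(
                _curve(h, a * vi + b), _curve(h, vj), 0.0, 20.0
            )
            assert (di1, k1) == (di0, k0)

    def test_flat_curve_raises(self):
        h = np.arange(0.0, 360.0, 45.0)
        flat = _curve(h, np.full(len(h), 7.0))
        tuned = _curve(h, wrapped_gaussian(h, 90.0, 1.5, 50.0))
        with pytest.raises(FlatCurveError):
            pairwise_di(flat, tuned, 0.0, 20.0)

    def test_equal_eye_positions_rejected(self):
        h = np.arange(0.0, 360.0, 45.0)
        c = _curve(h, wrapped_gaussian(h, 90.0, 1.5, 50.0))
        with pytest.raises(ValueError):
            pairwise_di(c, c, 20.0, 20.0)


class TestNeuronDI:
    def test_all_pairs_one_gives_one(self, noiseless_spec):
        table = simulate_fixation_block(noiseless_spec, reps=3)
        res = neuron_di(eccentric_curves(table))
        assert res.di == 1.0
        assert res.n_pairs == 3

    def test_lambda_063_recovery(self):
        spec = NeuronSpec(
            theta_p_deg=90.0, lambda_frame=0.63, noise=NoiseSpec("none")
        )
        table = simulate_fixation_block(spec, reps=3)
        res = neuron_di(eccentric_curves(table))
        assert res.di == pytest.approx(0.63, abs=0.05)

    def test_lambda_grid_noiseless_recovery(self):
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = NeuronSpec(
                theta_p_deg=135.0, lambda_frame=lam, noise=NoiseSpec("none")
            )
            table = simulate_fixation_block(spec, reps=3)
            res = neuron_di(eccentric_curves(table))
            assert abs(res.di - lam) <= 0.05, lam

    def test_two_of_three_significant(self, rng):
        spec = NeuronSpec(theta_p_deg=90.0, noise=NoiseSpec("none"))
        table = simulate_fixation_block(spec, reps=3)
        curves = eccentric_curves(table)
        # replace the +20 curve with pure noise (untuned)
        h = curves[20.0].headings_deg
        flatish = rng.normal(20.0, 0.01, size=(len(h), 3))
        curves[20.0] = TuningCurve(
            headings_deg=h,
            mean_rate_hz=flatish.mean(axis=1),
            sem_hz=flatish.std(axis=1, ddof=1) / np.sqrt(3),
            trials=[flatish[i] for i in range(len(h))],
        )
        res = neuron_di(curves)
        assert res.n_pairs == 1

    def test_fewer_than_two_significant_excluded(self, rng):
        h = np.arange(0.0, 360.0, 45.0)
        curves = {}
        for e in (-20.0, 0.0, 20.0):
            noise = rng.normal(20.0, 1.0, size=(len(h), 3))
            curves[e] = TuningCurve(
                headings_deg=h,
                mean_rate_hz=noise.mean(axis=1),
                sem_hz=noise.std(axis=1, ddof=1) / np.sqrt(3),
                trials=[noise[i] for i in range(len(h))],
            )
        with pytest.raises(InsufficientTuningError):
            neuron_di(curves)


class TestBootstrapCI:
    def test_zero_noise_zero_width(self, noiseless_spec):
        table = simulate_fixation_block(noiseless_spec, reps=3)
        curves = eccentric_curves(table)
        (lo, hi), samples, dropped = bootstrap_ci(curves, n_boot=200, seed=0)
        assert lo == hi == 1.0
        assert dropped == 0

    def test_same_seed_identical(self, noisy_spec):
        table = simulate_fixation_block(noisy_spec, seed=4)
        curves = eccentric_curves(table)
        a = bootstrap_ci(curves, n_boot=100, seed=11)
        b = bootstrap_ci(curves, n_boot=100, seed=11)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_bootstrap_matches_slow_reference(self, noisy_spec):
        """Vectorized bootstrap agrees with a plain-loop reimplementation."""
        table = simulate_fixation_block(noisy_spec, seed=4)
        curves = eccentric_curves(table)

        seed = 99
        rng = np.random.default_rng(seed)
        eyes = sorted(curves)
        n_boot = 50
        # replay the identical resampling stream
        boot_means = {}
        for e in eyes:
            c = curves[e]
            means = np.empty((len(c.headings_deg), n_boot))
            order = np.argsort(c.headings_deg)
            for hi in order:
                vals = np.asarray(c.trials[hi], float)
                idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
                means[hi] = vals[idx].mean(axis=1)
            boot_means[e] = means

        expected = []
        for b in range(n_boot):
            dis = []
            for i, e_i in enumerate(eyes):
                for e_j in eyes[i + 1:]:
                    ci = _curve(curves[e_i].headings_deg, boot_means[e_i][:, b])
                    cj = _curve(curves[e_j].headings_deg, boot_means[e_j][:, b])
                    di_ij, _ = pairwise_di(ci, cj, e_i, e_j)
                    dis.append(di_ij)
            expected.append(np.mean(dis))

        _, samples, _ = bootstrap_ci(curves, n_boot=n_boot, seed=seed)
        np.testing.assert_allclose(samples, expected)

    def test_coverage_small(self):
        """Reduced-scale coverage check (40 neurons); the full 200-neuron run
        lives in the acceptance suite."""
        from refframe.synthetic_data import generate_population

        lam = 0.5
        _, table = generate_population(40, seed=11, lambda_frame=lam)
        rng = np.random.default_rng(5)
        cover = n = 0
        for i in range(40):
            curves = eccentric_curves(table, f"syn{i:04d}")
            try:
                res = analyze_neuron(curves, n_boot=500, seed=rng)
            except InsufficientTuningError:
                continue
            n += 1
            cover += res.ci95[0] <= lam <= res.ci95[1]
        assert n >= 35
        assert 0.80 <= cover / n <= 1.0


class TestClassifyFrame:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((-0.1, 0.3), "head"),
            ((0.7, 1.2), "eye"),
            ((0.2, 0.8), "intermediate"),
            ((-0.2, 1.2), "unclassified"),
            ((1.2, 1.5), "unclassified"),
            ((0.0, 0.5), "head"),  # boundary: CI touching 0 includes it
        ],
    )
    def test_rules(self, ci, expected):
        assert classify_frame(sum(ci) / 2, ci) == expected

    def test_invalid_ci(self):
        with pytest.raises(ValueError):
            classify_frame(0.5, (1.0, 0.0))


class TestDIByEccentricity:
    def _multi_ecc_curves(self, lam):
        spec = NeuronSpec(
            theta_p_deg=90.0, lambda_frame=lam, noise=NoiseSpec("none")
        )
        grid = ConditionGrid(
            list(np.arange(0.0, 360.0, 45.0)),
            [-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0],
        )
        table = simulate_fixation_block(spec, grid, reps=3)
        return {
            e: build_tuning(table, "syn0", "visual", eye_pos_deg=e)
            for e in grid.eye_positions_deg
        }

    def test_lambda1_all_eccentricities(self):
        out = di_by_eccentricity(self._multi_ecc_curves(1.0))
        assert set(out) == {10.0, 20.0, 30.0}
        for v in out.values():
            assert v == pytest.approx(1.0)

    def test_lambda_half(self):
        out = di_by_eccentricity(self._multi_ecc_curves(0.5))
        for ecc, v in out.items():
            assert v == pytest.approx(0.5, abs=0.05), ecc

    def test_homogeneous_lambda_flat_profile(self):
        out = di_by_eccentricity(self._multi_ecc_curves(0.75))
        vals = list(out.values())
        assert max(vals) - min(vals) <= 0.1
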