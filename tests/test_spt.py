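"""Detection, linking, CPD construction and the two-population fit."""

import numpy as np
import pytest

from tirfkit import (
    FilterSpec,
    SimConfig,
    StepSample,
    TwoPopulationCpd,
    TwoPopulationParams,
    detect_and_localize,
    discoidal_filter,
    empirical_cpd,
    fit_cpd_two_population,
    link_trajectories,
    render_particle_movie,
    simulate_trajectories,
    step_sizes,
)
from tirfkit.io import ImageStack, Localization, Trajectory


def brute_force_discoidal(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Per-pixel disk/annulus means with symmetric (reflected) borders."""
    r = spec.r_outer_px
    padded = np.pad(img, r, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            inner, annulus = [], []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    dist = np.hypot(di, dj)
                    v = padded[i + r + di, j + r + dj]
                    if dist <= spec.r_inner_px:
                        inner.append(v)
                    elif dist <= spec.r_outer_px:
                        annulus.append(v)
            out[i, j] = np.mean(inner) - np.mean(annulus)
    return out


class TestDiscoidalFilter:
    def test_constant_image_maps_to_zero(self):
        out = discoidal_filter(np.full((16, 16), 7.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_bright_pixel_sign_structure(self):
        img = np.zeros((15, 15))
        img[7, 7] = 100.0
        out = discoidal_filter(img)
        assert out[7, 7] > 0
        assert out[7, 9] < 0  # inside the annulus ring

    def test_equals_brute_force_oracle(self, rng):
        spec = FilterSpec(1, 3)
        for _ in range(3):
            img = rng.uniform(0, 100, size=(16, 16))
            np.testing.assert_allclose(
                discoidal_filter(img, spec), brute_force_discoidal(img, spec),
                atol=1e-10,
            )

    def test_image_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            discoidal_filter(np.zeros((5, 5)), FilterSpec(1, 3))

    def test_radii_validated(self):
        with pytest.raises(ValueError, match="r_outer"):
            FilterSpec(3, 3)


class TestDetectAndLocalize:
    def test_noise_free_emitter_localized_within_tenth_pixel(self):
        cfg = SimConfig(seed=0, n_frames=2, image_shape=(32, 32), noise_sd=0.0)
        truth = (1.23, 0.97)  # um; deliberately off pixel centers
        trajs = [Trajectory(0, [Localization(f, *truth) for f in range(2)])]
        movie = render_particle_movie(trajs, cfg)
        locs = detect_and_localize(movie, threshold=5.0)
        assert len(locs) == 2
        for loc in locs:
            assert abs(loc.x_um - truth[0]) < 0.1 * 0.08
            assert abs(loc.y_um - truth[1]) < 0.1 * 0.08

    def test_blank_noisy_frames_rare_false_positives(self):
        rng = np.random.default_rng(42)
        frames = rng.normal(100.0, 5.0, size=(100, 32, 32))
        stack = ImageStack(frames)
        locs = detect_and_localize(stack, threshold=5.0)
        assert len(locs) <= 1  # <= 1 false positive per 100 frames

    def test_nearby_emitters_merged(self):
        cfg = SimConfig(seed=0, n_frames=2, image_shape=(32, 32), noise_sd=0.0)
        trajs = [
            Trajectory(0, [Localization(0, 1.20, 1.20)]),
            Trajectory(1, [Localization(0, 1.28, 1.20)]),  # 1 px apart
        ]
        movie = render_particle_movie(trajs, cfg)
        assert len(detect_and_localize(movie, threshold=5.0)) == 1


class TestLinkTrajectories:
    def test_single_emitter_full_length(self):
        locs = [Localization(f, 1.0 + 0.01 * f, 2.0) for f in range(10)]
        trajs = link_trajectories(locs, max_step_um=0.5)
        assert len(trajs) == 1
        assert len(trajs[0]) == 10

    def test_distant_emitters_never_swapped(self):
        locs = []
        for f in range(5):
            locs += [Localization(f, 0.0, 0.0), Localization(f, 10.0, 0.0)]
        trajs = link_trajectories(locs, max_step_um=1.0)
        assert len(trajs) == 2
        for tr in trajs:
            xs = {round(p.x_um, 6) for p in tr.localizations}
            assert len(xs) == 1

    def test_gap_bridging(self):
        locs = [Localization(f, 1.0, 1.0) for f in (0, 1, 3, 4)]
        assert len(link_trajectories(locs, 0.5, max_gap_frames=1)) == 1
        assert len(link_trajectories(locs, 0.5, max_gap_frames=0)) == 2

    def test_link_identity_against_ground_truth(self, aptes_params):
        # sparse field: nearest-neighbor spacing >> typical step
        trajs, _ = simulate_trajectories(
            aptes_params, 20, 15, 10.0, seed=8, start_box_um=(20.0, 20.0)
        )
        pos_to_id = {}
        flat = []
        for tr in trajs:
            for p in tr.localizations:
                pos_to_id[(p.frame_index, round(p.x_um, 9), round(p.y_um, 9))] = tr.id
                flat.append(Localization(p.frame_index, p.x_um, p.y_um))
        linked = link_trajectories(flat, max_step_um=0.5)
        good = total = 0
        for tr in linked:
            ids = [
                pos_to_id[(p.frame_index, round(p.x_um, 9), round(p.y_um, 9))]
                for p in tr.localizations
            ]
            good += sum(a == b for a, b in zip(ids, ids[1:]))
            total += len(ids) - 1
        assert total > 0
        assert good / total >= 0.95


class TestStepSizes:
    def test_static_trajectory_zero_steps(self):
        tr = Trajectory(0, [Localization(f, 1.0, 1.0) for f in range(5)])
        assert all(s.r_um == 0 for s in step_sizes([tr], 1, 1.0))

    def test_three_four_five_triangle(self):
        tr = Trajectory(0, [Localization(0, 0.0, 0.0), Localization(1, 3.0, 4.0)])
        steps = step_sizes([tr], 1, 10.0)
        assert len(steps) == 1
        assert steps[0].r_um == pytest.approx(5.0)
        assert steps[0].lag_s == 10.0

    def test_gapped_pairs_skipped(self):
        tr = Trajectory(0, [Localization(f, float(f), 0.0) for f in (0, 1, 3)])
        steps = step_sizes([tr], 1, 1.0)
        assert len(steps) == 1  # only (0, 1); (1, 3) spans a gap
        steps2 = step_sizes([tr], 2, 1.0)
        assert len(steps2) == 0  # (1, 3) lacks frame 2

    def test_pure_mobile_mean_square_within_3se(self):
        params = TwoPopulationParams(1.0, 5.1e-4, 0.0)
        trajs, _ = simulate_trajectories(params, 300, 20, 10.0, seed=3)
        r2 = np.array([s.r_um for s in step_sizes(trajs, 1, 10.0)]) ** 2
        se = r2.std(ddof=1) / np.sqrt(r2.size)
        assert abs(r2.mean() - 4 * 5.1e-4 * 10.0) < 3 * se


class TestEmpiricalCpd:
    def _steps(self, values, lag=1.0):
        return [StepSample(v, lag) for v in values]

    def test_counting_example(self):
        cpd = empirical_cpd(self._steps([1, 2, 3] * 4))
        idx = np.searchsorted(cpd[:, 0], 4.0, side="right") - 1
        assert cpd[idx, 1] == pytest.approx(2 / 3)

    def test_valid_cdf_estimate(self, rng):
        cpd = empirical_cpd(self._steps(rng.rayleigh(0.1, size=200)))
        assert cpd[-1, 1] == 1.0
        assert np.all(np.diff(cpd[:, 1]) >= 0)
        assert cpd[0, 1] == pytest.approx(1 / 200)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="9"):
            empirical_cpd(self._steps(range(1, 10)))

    def test_dkw_band_against_analytic_rayleigh_cdf(self):
        d, t, n = 5.1e-4, 10.0, 1000
        rng = np.random.default_rng(77)
        r = rng.rayleigh(np.sqrt(2 * d * t), size=n)
        cpd = empirical_cpd(self._steps(r, lag=t))
        analytic = 1 - np.exp(-cpd[:, 0] / (4 * d * t))
        eps = np.sqrt(np.log(2 / 0.05) / (2 * n))
        assert np.max(np.abs(cpd[:, 1] - analytic)) < eps


class TestTwoPopulationFit:
    def test_analytic_curve_recovered_to_four_significant_figures(self):
        t, a, d1, d2 = 10.0, 0.57, 5.1e-4, 1e-5
        r2 = np.linspace(1e-4, 0.12, 200)
        p = 1 - a * np.exp(-r2 / (4 * d1 * t)) - (1 - a) * np.exp(-r2 / (4 * d2 * t))
        fit = fit_cpd_two_population(np.column_stack([r2, p]), t, n_boot=0)
        assert fit.alpha_mobile == pytest.approx(a, rel=1e-4)
        assert fit.d_mobile == pytest.approx(d1, rel=1e-4)
        assert fit.d_immobile == pytest.approx(d2, rel=1e-4)

    def test_single_population_d_within_ten_percent(self):
        params = TwoPopulationParams(1.0, 5.1e-4, 0.0)
        trajs, _ = simulate_trajectories(params, 2000, 1, 10.0, seed=6)
        r = np.array([s.r_um for s in step_sizes(trajs, 1, 10.0)])
        est = TwoPopulationCpd(lag_s=10.0, fix_alpha=1.0, n_boot=0).fit(r)
        assert est.d_mobile_ == pytest.approx(5.1e-4, rel=0.10)

    def test_fixed_alpha_one_reduces_to_single_population_form(self, rng):
        r = rng.rayleigh(np.sqrt(2 * 5.1e-4 * 10.0), size=500)
        est = TwoPopulationCpd(lag_s=10.0, fix_alpha=1.0, n_boot=0).fit(r)
        # independent closed-form check: minimize || P_emp - (1 - exp(.)) ||
        # over a fine D grid
        r2 = np.sort(r**2)
        p = np.arange(1, r2.size + 1) / r2.size
        grid = np.linspace(3e-4, 8e-4, 2001)
        costs = [
            np.sum((p - (1 - np.exp(-r2 / (4 * d * 10.0)))) ** 2) for d in grid
        ]
        assert est.d_mobile_ == pytest.approx(grid[int(np.argmin(costs))], rel=2e-3)
        assert est.alpha_mobile_ == 1.0
        assert est.d_immobile_ == 0.0

    def test_consistency_bias_shrinks_with_n(self, aptes_params):
        tol = {500: 1.5 / np.sqrt(500), 2000: 1.5 / np.sqrt(2000), 8000: 1.5 / np.sqrt(8000)}
        for n, bound in tol.items():
            alphas, ds = [], []
            for seed in range(3):
                trajs, _ = simulate_trajectories(aptes_params, n, 1, 10.0, seed=100 + seed)
                r = np.array([s.r_um for s in step_sizes(trajs, 1, 10.0)])
                est = TwoPopulationCpd(lag_s=10.0, n_boot=0).fit(r)
                alphas.append(est.alpha_mobile_)
                ds.append(est.d_mobile_)
            assert abs(np.mean(alphas) - 0.57) < bound
            assert abs(np.mean(ds) / 5.1e-4 - 1) < 4 / np.sqrt(n)

    def test_bootstrap_errors_are_plausible(self, aptes_params):
        trajs, _ = simulate_trajectories(aptes_params, 1000, 1, 10.0, seed=4)
        r = np.array([s.r_um for s in step_sizes(trajs, 1, 10.0)])
        est = TwoPopulationCpd(lag_s=10.0, n_boot=60, random_state=0).fit(r)
        # binomial scale of the mixture weight at n = 1000
        assert 0.005 < est.se_alpha_ < 0.08
        assert est.se_d_mobile_ > 0

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="50"):
            TwoPopulationCpd(lag_s=10.0).fit(np.ones(20))


class TestFullPipelineRecovery:
    def test_rendered_movie_round_trip_recovers_mixture(self):
        """detect -> localize -> link -> CPD fit on a rendered movie recovers
        the generating mobile fraction (vs realized labels) and D_mobile."""
        import json
        import tempfile

        from tirfkit.pipeline import RunConfig, run_pipeline

        with tempfile.TemporaryDirectory() as d:
            run_pipeline(RunConfig(preset="aptes_yeast", seed=1, out_dir=d))
            fit = json.load(open(f"{d}/fit.json"))
            gt = json.load(open(f"{d}/ground_truth.json"))
        realized_alpha = np.mean(gt["params"]["mobile_labels"])
        assert abs(fit["alpha_mobile"] - realized_alpha) < 0.05
        assert abs(fit["d_mobile"] / 5.1e-4 - 1) < 0.15
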