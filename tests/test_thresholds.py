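import numpy as np
import pytest

from groupdelim import (
    DistanceSample,
    DirectionalNNRecord,
    bootstrap_cutoff_interval,
    estimate_density,
    estimate_thresholds,
    find_cutoffs,
    pool_distances,
    stratified_thresholds,
)
from groupdelim.thresholds import silverman_bandwidth
from oracles import lognormal_mixture_antimode, lognormal_mixture_antimodes


def lognormal_mixture_sample(rng, params, weights, n):
    comp = rng.choice(len(weights), size=n, p=weights)
    mus = np.array([p[0] for p in params])[comp]
    sigmas = np.array([p[1] for p in params])[comp]
    return np.exp(rng.normal(mus, sigmas))


def nn_record(distance, scene="s", src="a", state=None):
    return DirectionalNNRecord(
        scene_id=scene,
        source_id=src,
        neighbor_id="b",
        distance=distance,
        bearing=0.0,
        source_state=state,
    )


class TestPooling:
    def test_concatenates_scenes_and_keeps_provenance(self):
        recs_a = [nn_record(d, scene="s1") for d in (1.0, 2.0, 3.0)]
        recs_b = [nn_record(d, scene="s2") for d in (4.0, 5.0, 6.0, 7.0)]
        sample = pool_distances([recs_a, recs_b])
        assert sample.n == 7
        assert sorted(set(sample.provenance)) == ["s1", "s2"]

    def test_stratum_sizes_sum_to_total(self):
        recs = [nn_record(1.0 + i, state=s) for i, s in enumerate("rrff")]
        sample = pool_distances(recs, stratify_by_state=True)
        assert sample.stratum("r").n + sample.stratum("f").n == sample.n

    def test_single_state_stratum_equals_pool(self):
        recs = [nn_record(1.0 + i, state="rest") for i in range(5)]
        sample = pool_distances(recs, stratify_by_state=True)
        assert np.array_equal(sample.stratum("rest").distances, sample.distances)

    def test_zero_distance_rejected_naming_the_pair(self):
        recs = [nn_record(1.0), nn_record(0.0, src="bad")]
        with pytest.raises(ValueError, match="bad"):
            pool_distances(recs)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_distances([])


class TestDensityEstimation:
    def test_lognormal_linear_mode_matches_closed_form(self, rng):
        """On the linear scale the KDE mode of lognormal draws approaches
        the analytic mode exp(mu - sigma^2)."""
        mu, sigma = 1.0, 0.5
        x = np.exp(rng.normal(mu, sigma, 10_000))
        curve = estimate_density(DistanceSample(distances=x), log_scale=False)
        mode = curve.grid_m[np.argmax(curve.values)]
        assert mode == pytest.approx(np.exp(mu - sigma**2), rel=0.05)

    @pytest.mark.parametrize("log_scale", [True, False])
    def test_density_integrates_to_one(self, rng, log_scale):
        x = np.exp(rng.normal(0.5, 0.8, 2_000))
        curve = estimate_density(DistanceSample(distances=x), log_scale=log_scale)
        assert np.trapezoid(curve.values, curve.grid) == pytest.approx(1.0, abs=0.01)

    def test_tight_sample_peaks_at_its_value(self, rng):
        x = 42.0 + rng.normal(0, 1e-3, 500)
        curve = estimate_density(DistanceSample(distances=x), log_scale=False)
        peak = curve.grid_m[np.argmax(curve.values)]
        step = curve.grid[1] - curve.grid[0]
        assert abs(peak - 42.0) <= step + 1e-3

    def test_small_sample_flagged_unreliable(self, rng):
        x = np.exp(rng.normal(0, 0.5, 10))
        curve = estimate_density(DistanceSample(distances=x))
        assert not curve.reliable

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(DistanceSample(distances=np.array([])))

    def test_silverman_bandwidth_is_scale_covariant(self, rng):
        x = rng.lognormal(1.0, 0.6, 500)
        assert silverman_bandwidth(3.7 * x) == pytest.approx(
            3.7 * silverman_bandwidth(x), rel=1e-9
        )


class TestCutoffDetection:
    def test_unimodal_sample_has_no_cutoff(self, rng):
        x = lognormal_mixture_sample(rng, [(1.0, 0.5)], [1.0], 5_000)
        est = estimate_thresholds(DistanceSample(distances=x))
        assert est.cutoffs == ()
        assert len(est.modes) == 1

    def test_two_component_mixture_cutoff_near_analytic_antimode(self, rng):
        params, weights = [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5]
        oracle = lognormal_mixture_antimode(params, weights)
        x = lognormal_mixture_sample(rng, params, weights, 5_000)
        est = estimate_thresholds(DistanceSample(distances=x))
        assert len(est.cutoffs) == 1
        assert est.cutoffs[0] == pytest.approx(oracle, rel=0.15)

    def test_three_component_mixture_yields_two_interleaved_cutoffs(self, rng):
        params = [(0.0, 0.3), (2.5, 0.3), (5.0, 0.3)]
        weights = [1 / 3] * 3
        oracles = lognormal_mixture_antimodes(params, weights)
        assert len(oracles) == 2
        x = lognormal_mixture_sample(rng, params, weights, 5_000)
        est = estimate_thresholds(DistanceSample(distances=x))
        assert len(est.cutoffs) == 2
        assert list(est.cutoffs) == sorted(est.cutoffs)
        for got, want in zip(est.cutoffs, oracles):
            assert got == pytest.approx(want, rel=0.15)
        # interleaving: mode < cutoff < mode < cutoff < mode
        for i, c in enumerate(est.cutoffs):
            assert est.modes[i] < c < est.modes[i + 1]

    def test_cutoff_count_non_increasing_in_prominence(self, rng):
        params = [(0.0, 0.4), (2.0, 0.4), (4.5, 0.3)]
        x = lognormal_mixture_sample(rng, params, [0.4, 0.3, 0.3], 4_000)
        curve = estimate_density(DistanceSample(distances=x))
        counts = [
            len(find_cutoffs(curve, min_prominence=p).cutoffs)
            for p in (0.0, 0.05, 0.1, 0.3, 0.6, 0.9)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scale_equivariance(self, rng):
        """Multiplying all distances by c multiplies every cutoff by c."""
        params, weights = [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5]
        x = lognormal_mixture_sample(rng, params, weights, 4_000)
        c = 7.3
        for log_scale in (True, False):
            a = estimate_thresholds(DistanceSample(distances=x), log_scale=log_scale)
            b = estimate_thresholds(
                DistanceSample(distances=c * x), log_scale=log_scale
            )
            assert len(a.cutoffs) == len(b.cutoffs) >= 1
            for ca, cb in zip(a.cutoffs, b.cutoffs):
                assert cb == pytest.approx(c * ca, rel=0.02)

    def test_cutoffs_lie_within_observed_range(self, rng):
        params, weights = [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5]
        x = lognormal_mixture_sample(rng, params, weights, 3_000)
        est = estimate_thresholds(DistanceSample(distances=x))
        for cut in est.cutoffs:
            assert x.min() < cut < x.max()

    def test_max_levels_keeps_deepest_valleys(self, rng):
        params = [(0.0, 0.3), (2.5, 0.3), (5.0, 0.3)]
        x = lognormal_mixture_sample(rng, params, [1 / 3] * 3, 4_000)
        curve = estimate_density(DistanceSample(distances=x))
        full = find_cutoffs(curve, max_levels=3)
        capped = find_cutoffs(curve, max_levels=1)
        assert len(capped.cutoffs) == 1
        assert capped.primary_cutoff in full.cutoffs


class TestStratifiedThresholds:
    def test_single_stratum_equals_pooled(self, rng):
        params, weights = [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5]
        x = lognormal_mixture_sample(rng, params, weights, 2_000)
        sample = DistanceSample(distances=x, strata=np.array(["rest"] * x.size))
        est = stratified_thresholds(sample)
        assert est.per_stratum.keys() == {"rest"}
        assert est.per_stratum["rest"].cutoffs == est.cutoffs

    def test_tighter_state_gets_smaller_cutoff(self, rng):
        """Simulated rest (1 m spread) vs forage (25 m spread) strata with
        the same between-group spacing produce ordered cutoffs."""
        from groupdelim import (
            SimulationConfig,
            directional_nn_distances,
            simulate_scene,
        )

        cfg = SimulationConfig(
            window=(0, 0, 2000, 2000),
            n_groups=6,
            group_size_dist=("fixed", 6),
            spread_by_state={"rest": 1.0, "forage": 25.0},
            state_probs={"rest": 0.5, "forage": 0.5},
            min_center_separation=300.0,
        )
        recs = [
            directional_nn_distances(
                simulate_scene(cfg, seed=int(rng.integers(0, 2**31 - 1))).scene
            )
            for _ in range(8)
        ]
        est = stratified_thresholds(pool_distances(recs, stratify_by_state=True))
        rest = est.per_stratum["rest"].primary_cutoff
        forage = est.per_stratum["forage"].primary_cutoff
        assert rest is not None and forage is not None
        assert rest < forage

    def test_equal_distribution_strata_agree(self):
        """Two strata drawn from the identical mixture give cutoffs within
        20% of each other across seeds."""
        params, weights = [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5]
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = lognormal_mixture_sample(rng, params, weights, 3_000)
            strata = np.where(np.arange(x.size) % 2 == 0, "a", "b")
            est = stratified_thresholds(DistanceSample(distances=x, strata=strata))
            ca = est.per_stratum["a"].primary_cutoff
            cb = est.per_stratum["b"].primary_cutoff
            assert ca is not None and cb is not None
            assert abs(ca - cb) / max(ca, cb) <= 0.20

    def test_small_strata_skipped_and_reported(self, rng):
        x = lognormal_mixture_sample(rng, [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5], 500)
        strata = np.array(["big"] * 490 + ["tiny"] * 10)
        est = stratified_thresholds(DistanceSample(distances=x, strata=strata))
        assert "tiny" not in est.per_stratum
        assert est.diagnostics["skipped_strata"] == ["tiny"]

    def test_all_strata_too_small_rejected(self, rng):
        x = np.exp(rng.normal(0, 0.5, 20))
        strata = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.raises(ValueError, match="minimum sample size"):
            stratified_thresholds(DistanceSample(distances=x, strata=strata))


class TestBootstrap:
    def test_fixed_seed_reproduces_intervals(self, rng):
        x = lognormal_mixture_sample(rng, [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5], 1_000)
        sample = DistanceSample(distances=x)
        a = bootstrap_cutoff_interval(sample, B=100, seed=11)
        b = bootstrap_cutoff_interval(sample, B=100, seed=11)
        assert a == b

    def test_mixture_replicates_mostly_find_one_cutoff(self, rng):
        x = lognormal_mixture_sample(rng, [(0.0, 0.35), (3.2, 0.35)], [0.5, 0.5], 2_000)
        out = bootstrap_cutoff_interval(DistanceSample(distances=x), B=100, seed=5)
        assert out["replicate_cutoff_counts"].get("1", 0) >= 90

    def test_interval_narrows_as_components_concentrate(self, rng):
        widths = []
        for sigma in (0.35, 0.10):
            x = lognormal_mixture_sample(
                rng, [(0.0, sigma), (3.2, sigma)], [0.5, 0.5], 2_000
            )
            out = bootstrap_cutoff_interval(DistanceSample(distances=x), B=100, seed=3)
            iv = out["intervals"][0]
            widths.append(iv["hi_m"] - iv["lo_m"])
        assert widths[1] < widths[0]

    def test_too_few_replicates_rejected(self, rng):
        x = np.exp(rng.normal(0, 0.5, 100))
        with pytest.raises(ValueError):
            bootstrap_cutoff_interval(DistanceSample(distances=x), B=10, seed=0)
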