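"""Endpoint truncation, elastic-region search, and the four extractors."""

import numpy as np
import pytest
from scipy import stats as sps

from vertmech import (CompressionTest, ElasticRegion, ExtractionConfig,
                      ExtractionError, ForceDisplacementCurve, analyze_curve,
                      compute_failure_load, compute_max_load,
                      compute_stiffness, detect_elastic_region, detect_yield,
                      generate_curve, truncate_at_endpoint)

from conftest import OVX_MEANS, SHAM_MEANS, make_params, random_params
from oracles import (brute_endpoint, brute_failure_load, brute_max_load,
                     brute_yield)


def _curve(displacement, force, **kw):
    return ForceDisplacementCurve(np.asarray(displacement, float),
                                  np.asarray(force, float), **kw)


class TestEndpointTruncation:
    def test_fifty_percent_force_drop_triggers(self):
        # force climbs to 100 N then one sample reads 49 N <= 0.5 * 100
        f = np.concatenate([np.linspace(0, 100, 40), [49.0, 30.0, 20.0]])
        d = np.arange(f.size) * 0.01
        truncated, idx, reason = truncate_at_endpoint(_curve(d, f))
        assert (idx, reason) == (40, "force_drop")
        assert truncated.n_samples == 41
        assert truncated.force[-1] == 49.0

    def test_two_mm_displacement_triggers_on_plateau(self):
        # force plateaus at 80 N and never drops; travel passes 2 mm
        d = np.arange(0, 2.4, 0.01)
        f = np.minimum(80.0, 120.0 * d)
        truncated, idx, reason = truncate_at_endpoint(_curve(d, f))
        assert reason == "displacement"
        assert d[idx] > 2.0 and d[idx - 1] <= 2.0

    def test_neither_criterion_gives_end_of_data(self):
        d = np.arange(0, 1.5, 0.01)
        f = 90.0 * d  # strictly increasing
        _, idx, reason = truncate_at_endpoint(_curve(d, f))
        assert (idx, reason) == (d.size - 1, "end_of_data")

    def test_drop_rule_unarmed_below_min_peak_force(self):
        # a dip while the running max is still inside the noise region must
        # not end the test
        f = np.concatenate([[2.0, -0.5, 1.0], np.linspace(1, 150, 40)])
        d = np.arange(f.size) * 0.01
        _, idx, reason = truncate_at_endpoint(_curve(d, f))
        assert reason == "end_of_data"

    def test_first_trigger_property_matches_exhaustive_scan(self, rng):
        # no sample before the endpoint may violate either criterion
        for _ in range(25):
            n = 120
            f = np.cumsum(rng.normal(2.0, 4.0, n))
            d = np.arange(n) * rng.uniform(0.005, 0.03)
            curve = _curve(d, f)
            _, idx, reason = truncate_at_endpoint(curve)
            oidx, oreason = brute_endpoint(f, d)
            assert (idx, reason) == (oidx, oreason)


class TestElasticRegion:
    def test_bilinear_curve_recovers_first_limb(self):
        # slope 150 N/mm for 0.6 mm, then 15 N/mm
        d = np.arange(0, 1.2, 0.001)
        f = np.where(d <= 0.6, 150.0 * d, 90.0 + 15.0 * (d - 0.6))
        region = detect_elastic_region(_curve(d, f))
        assert region.slope == pytest.approx(150.0, rel=5e-3)
        assert region.r_squared >= 0.9999
        kink = 600
        assert region.start_index >= 0
        assert region.end_index <= kink + region.window_width

    def test_noiseless_reference_curve_recovers_slope(self, sham_curve):
        truncated, _, _ = truncate_at_endpoint(sham_curve)
        region = detect_elastic_region(truncated)
        assert region.slope == pytest.approx(SHAM_MEANS["stiffness"], rel=5e-3)
        assert region.local_slope_sd >= 0.0

    def test_noisy_linear_slope_equals_closed_form_ols(self, rng):
        d = np.arange(0, 1.0, 0.001)
        f = 120.0 * d + rng.normal(0, 0.5, d.size)
        cfg = ExtractionConfig.noisy()
        region = detect_elastic_region(_curve(d, f), cfg)
        expected = sps.linregress(d[region.start_index:region.end_index + 1],
                                  f[region.start_index:region.end_index + 1])
        assert region.slope == pytest.approx(expected.slope, rel=1e-9)
        assert region.intercept == pytest.approx(expected.intercept, abs=1e-9)

    def test_no_linear_region_raises(self, rng):
        # pure noise around a rising staircase: no window reaches the floor
        d = np.arange(0, 1.0, 0.005)
        f = 50.0 * np.sqrt(d) + rng.normal(0, 6.0, d.size)
        f = np.maximum.accumulate(f)  # keep a well-defined peak at the end
        with pytest.raises(ExtractionError, match="no linear elastic region"):
            detect_elastic_region(_curve(d, f))

    def test_too_few_pre_peak_samples_raises(self):
        d = np.arange(15) * 0.01
        f = np.concatenate([[0, 1, 2, 3, 100.0], 50.0 * np.ones(10)])
        with pytest.raises(ExtractionError):
            detect_elastic_region(_curve(d, f))


class TestStiffness:
    def test_reciprocal_identity(self):
        region = ElasticRegion(start_index=0, end_index=99, slope=100.0,
                               intercept=0.0, r_squared=1.0,
                               local_slope_mean=100.0, local_slope_sd=0.0,
                               window_width=11, local_window=11)
        s, n = compute_stiffness(region)
        assert (s, n) == (100.0, 0.01)

    def test_reference_group_slopes(self):
        for mean in (174.2, 133.2):
            region = ElasticRegion(start_index=0, end_index=99, slope=mean,
                                   intercept=0.0, r_squared=1.0,
                                   local_slope_mean=mean, local_slope_sd=0.0,
                                   window_width=11, local_window=11)
            s, n = compute_stiffness(region)
            assert s == mean
            assert s * n == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_slope_rejected(self):
        with pytest.raises(ExtractionError):
            ElasticRegion(start_index=0, end_index=99, slope=-5.0,
                          intercept=0.0, r_squared=1.0, local_slope_mean=0.0,
                          local_slope_sd=0.0, window_width=11, local_window=11)


class TestYield:
    def test_abrupt_kink_detected_within_one_window(self):
        # bilinear: slope S to 0.1 S kinking at 50 N
        S = 150.0
        d = np.arange(0, 1.0, 0.001)
        f = np.where(d <= 50.0 / S, S * d, 50.0 + 0.1 * S * (d - 50.0 / S))
        curve = _curve(d, f)
        region = detect_elastic_region(curve)
        yield_load, idx, at_peak = detect_yield(curve, region)
        window_span = region.local_window * 0.001 * S
        assert not at_peak
        assert abs(yield_load - 50.0) <= window_span

    def test_noiseless_reference_curve(self, sham_curve):
        truncated, _, _ = truncate_at_endpoint(sham_curve)
        region = detect_elastic_region(truncated)
        yield_load, idx, at_peak = detect_yield(truncated, region)
        assert not at_peak
        assert yield_load == pytest.approx(SHAM_MEANS["yield_load"], rel=0.02)

    def test_matches_exhaustive_scan_on_noisy_curves(self):
        cfg = ExtractionConfig.noisy()
        for seed in range(10):
            params = random_params(np.random.default_rng(seed), noise_sd=1.0,
                                   seed=seed)
            curve = generate_curve(params)
            truncated, _, _ = truncate_at_endpoint(curve)
            region = detect_elastic_region(truncated, cfg)
            assert detect_yield(truncated, region, config=cfg) == \
                brute_yield(truncated, region)

    def test_yield_at_peak_flag_when_no_slope_drop(self):
        # purely linear up to the peak then a clean drop: no pre-peak sample
        # loses stiffness, so the yield pins to the peak with a flag
        d = np.arange(0, 1.0, 0.001)
        f = np.where(d <= 0.8, 150.0 * d, 120.0 - 400.0 * (d - 0.8))
        curve = _curve(d, np.maximum(f, 0.0))
        truncated, _, _ = truncate_at_endpoint(curve)
        region = detect_elastic_region(truncated)
        yield_load, idx, at_peak = detect_yield(truncated, region)
        assert at_peak
        assert idx == int(np.argmax(truncated.force))


class TestMaxAndFailure:
    def test_tie_broken_to_first_index(self):
        curve = _curve(np.arange(5) * 0.01, [0.0, 10.0, 25.0, 25.0, 7.0])
        assert compute_max_load(curve) == (25.0, 2)

    def test_max_matches_brute_force(self, rng):
        for _ in range(20):
            f = rng.normal(50, 20, 200)
            curve = _curve(np.arange(200) * 0.01, f)
            assert compute_max_load(curve) == brute_max_load(f)

    def test_failure_is_last_local_max_before_terminal_drop(self):
        f = [0.0, 80.0, 154.0, 150.0, 151.0, 60.0]
        curve = _curve(np.arange(6) * 0.01, f)
        load, idx = compute_failure_load(curve, 2, 5)
        assert (load, idx) == (151.0, 4)

    def test_monotone_decrease_falls_back_to_peak(self):
        f = [0.0, 100.0, 90.0, 80.0, 40.0]
        curve = _curve(np.arange(5) * 0.01, f)
        assert compute_failure_load(curve, 1, 4) == (100.0, 1)

    def test_failure_matches_brute_force(self, rng):
        for _ in range(20):
            n = 150
            f = np.abs(rng.normal(50, 20, n))
            max_idx = int(np.argmax(f))
            curve = _curve(np.arange(n) * 0.01, f)
            assert compute_failure_load(curve, max_idx, n - 1) == \
                brute_failure_load(f, max_idx, n - 1)


class TestAnalyzeCurve:
    def test_toy_bilinear_then_drop_hand_values(self):
        # elastic slope 100 N/mm to 80 N, plastic slope 10 N/mm to 100 N,
        # then collapse: S=100, yL~80, Fmax=100, fL=100
        step = 0.001
        d1 = np.arange(0, 0.8, step)
        d2 = np.arange(0.8, 2.8, step)
        f = np.concatenate([100.0 * d1, 80.0 + 10.0 * (d2 - 0.8)])
        peak = f.max()
        d = np.arange(f.size + 3) * step
        f = np.concatenate([f, [0.3 * peak, 0.2 * peak, 0.1 * peak]])
        curve = _curve(d, f)
        m = analyze_curve(curve, ExtractionConfig(max_displacement=5.0))
        assert m.stiffness == pytest.approx(100.0, rel=5e-3)
        assert m.yield_load == pytest.approx(80.0, abs=2.5)
        assert m.max_load == pytest.approx(peak, abs=1e-9)
        assert m.failure_load == pytest.approx(peak, abs=1e-9)
        assert m.endpoint_reason == "force_drop"

    @pytest.mark.parametrize("means", [SHAM_MEANS, OVX_MEANS],
                             ids=["sham", "ovx"])
    def test_noiseless_reference_recovery(self, means):
        m = analyze_curve(generate_curve(make_params(means)))
        assert m.stiffness == pytest.approx(means["stiffness"], rel=5e-3)
        assert m.yield_load == pytest.approx(means["yield_load"], rel=0.02)
        assert m.max_load == pytest.approx(means["max_load"], rel=1e-3)
        assert m.failure_load == pytest.approx(means["failure_load"], rel=0.02)

    def test_invariants_hold_on_noisy_curves(self):
        cfg = ExtractionConfig.noisy()
        for seed in range(15):
            params = random_params(np.random.default_rng(1000 + seed),
                                   noise_sd=1.0, seed=seed)
            m = analyze_curve(generate_curve(params), cfg)
            assert m.yield_load <= m.max_load + 1e-9
            assert m.failure_load <= m.max_load + 1e-9
            assert (m.yield_index <= m.max_index <= m.failure_index
                    <= m.endpoint_index)
            assert m.compliance * m.stiffness == pytest.approx(1.0, abs=1e-9)

    def test_affine_equivariance_of_force_scaling(self, sham_curve):
        # scaling force by c scales all four extracted loads by exactly c
        base = analyze_curve(sham_curve)
        for c in (0.5, 2.0):
            scaled = ForceDisplacementCurve(sham_curve.displacement,
                                            c * sham_curve.force)
            m = analyze_curve(scaled)
            assert m.stiffness == pytest.approx(c * base.stiffness, rel=1e-9)
            assert m.yield_load == pytest.approx(c * base.yield_load, rel=1e-9)
            assert m.max_load == pytest.approx(c * base.max_load, rel=1e-9)
            assert m.failure_load == pytest.approx(c * base.failure_load,
                                                   rel=1e-9)

    def test_error_carries_specimen_id(self):
        d = np.arange(0, 1.0, 0.005)
        f = np.maximum.accumulate(
            50.0 * np.sqrt(d) + np.random.default_rng(5).normal(0, 6.0, d.size))
        curve = _curve(d, f, specimen_id="L5-bad")
        with pytest.raises(ExtractionError, match="L5-bad"):
            analyze_curve(curve)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, sham_curve):
        res = CompressionTest(sham_curve).fit()
        assert res.stiffness == pytest.approx(SHAM_MEANS["stiffness"],
                                              rel=5e-3)
        text = res.summary()
        assert "stiffness" in text and "Fmax" in text
        record = res.to_record()
        assert record["endpoint_reason"] == "force_drop"

    def test_from_file_round_trip(self, tmp_path, sham_curve):
        from vertmech import write_curve
        path = tmp_path / "c.csv"
        write_curve(sham_curve, path)
        res = CompressionTest.from_file(path).fit()
        assert res.max_load == pytest.approx(SHAM_MEANS["max_load"], rel=1e-3)
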