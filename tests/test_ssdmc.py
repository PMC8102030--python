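"""RRF/RRT computation, quantification round-trips, and validation stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbdiff.compounds import PEAK_COMPOUNDS
from herbdiff.errors import ValidationError
from herbdiff.io import CalibrationSeries
from herbdiff.simulate import GeneratorConfig, generate_calibration_series
from herbdiff.ssdmc import (
    build_rrf_table,
    compare_methods,
    compute_rrf,
    compute_rrt,
    fit_esm_calibration,
    lod_loq,
    quantify_esm,
    quantify_ssdmc,
    quantify_tables,
    recovery,
    rrf_mw_extrapolate,
    rsd,
    run_validation,
)


def _series(slope, concs=(1, 2, 4, 8, 16, 32, 64), name="x", instrument="i", intercept=0.0):
    return CalibrationSeries(name, instrument, [(float(c), float(slope * c + intercept)) for c in concs])


class TestRrf:
    def test_identity_against_itself(self):
        s = _series(2.5e4)
        assert compute_rrf(s, s).rrf == pytest.approx(1.0)

    def test_slope_ratio_closed_form(self):
        ref = _series(2.5e4, name="ref")
        analyte = _series(2.5e4 / 0.85, name="a")
        assert compute_rrf(ref, analyte).rrf == pytest.approx(0.85, abs=1e-10)

    def test_inverse_multiplicative(self):
        a = _series(2.0e4, name="a")
        b = _series(3.1e4, name="b")
        assert compute_rrf(a, b).rrf * compute_rrf(b, a).rrf == pytest.approx(1.0, abs=1e-10)

    def test_uses_seven_levels_by_default(self):
        cfg = GeneratorConfig(seed=0, area_cv=0.0)
        ref = generate_calibration_series(PEAK_COMPOUNDS[2], cfg)
        analyte = generate_calibration_series(PEAK_COMPOUNDS[9], cfg)
        assert compute_rrf(ref, analyte).n_levels == 7

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValidationError, match="instrument"):
            compute_rrf(_series(1e4), _series(1e4, instrument="j"))
        with pytest.raises(ValidationError, match="level count"):
            compute_rrf(_series(1e4), _series(1e4, concs=(1, 2, 4)))


class TestRrt:
    def test_reference_against_itself(self):
        assert compute_rrt(9.89, 9.89) == pytest.approx(1.0)

    def test_double_retention(self):
        assert compute_rrt(19.78, 9.89) == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            compute_rrt(-1.0, 9.89)


class TestMwExtrapolation:
    @pytest.mark.parametrize("analyte_mr,base_mr,base_rrf,expected", [
        (462.3, 448.3, 1.00, 1.03),   # luteolin-7-O-glucuronide / diosmetin-7-O-glucoside
        (518.1, 432.8, 0.76, 0.91),   # apigenin-7-O-6''-malonylglucoside
        (333.3, 333.3, 0.58, 0.58),   # identity
    ])
    def test_worked_examples(self, analyte_mr, base_mr, base_rrf, expected):
        assert rrf_mw_extrapolate(analyte_mr, base_mr, base_rrf) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            rrf_mw_extrapolate(0.0, 448.3, 1.0)


class TestQuantification:
    def test_one_point_external_standard_identity(self):
        assert quantify_ssdmc(500.0, 500.0, 12.5, 1.0) == pytest.approx(12.5)

    def test_noiseless_round_trip_recovers_truth(self, noiseless_world):
        registry, cfg, tables, truth = noiseless_world
        rrf_table = build_rrf_table(cfg, compounds=registry)
        quant = quantify_tables(tables, rrf_table, cfg, compounds=registry)
        merged = quant.merge(truth, on=["sample_id", "peak_id"])
        present = merged[merged.content_pct > 0]
        np.testing.assert_allclose(present.content, present.content_pct, rtol=1e-9)

    def test_ssdmc_equals_esm_with_zero_intercepts(self, noiseless_world):
        registry, cfg, tables, _ = noiseless_world
        spec = registry[9]
        ref = registry[2]
        ref_series = generate_calibration_series(ref, cfg)
        an_series = generate_calibration_series(spec, cfg)
        rrf = compute_rrf(ref_series, an_series).rrf
        slope, intercept, _ = fit_esm_calibration(an_series)
        cs = ref.stock_conc * 1000 / 4
        a_s = ref.calib_slope * cs
        for t in tables:
            ax = t.peak(9).area
            if ax == 0:
                continue
            assert quantify_ssdmc(ax, a_s, cs, rrf) == pytest.approx(
                quantify_esm(ax, slope, intercept), rel=1e-9)

    def test_esm_round_trip_on_printed_line(self):
        cfg = GeneratorConfig(seed=0, area_cv=0.0)
        series = generate_calibration_series(PEAK_COMPOUNDS[2], cfg)
        slope, intercept, r2 = fit_esm_calibration(series)
        assert slope == pytest.approx(2.564e4, rel=1e-10)
        assert intercept == pytest.approx(5.208e3, rel=1e-8)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        for conc in series.concentrations:
            assert quantify_esm(slope * conc + intercept, slope, intercept) == pytest.approx(conc)

    def test_esm_linearity_under_noise(self):
        # the synthetic series keep r2 above the published linearity floor
        for seed in range(10):
            cfg = GeneratorConfig(seed=seed, area_cv=0.005)
            _, _, r2 = fit_esm_calibration(generate_calibration_series(PEAK_COMPOUNDS[2], cfg))
            assert r2 > 0.9993

    def test_esm_trivial_points(self):
        assert quantify_esm(5.0e3, 2.5e4, 5.0e3) == 0.0
        assert quantify_esm(3.0e4, 2.5e4, 5.0e3) == pytest.approx(1.0)

    def test_esm_negative_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            assert quantify_esm(1.0, 2.5e4, 5.0e3) == 0.0

    def test_printed_orientation_differs(self):
        assert quantify_ssdmc(10.0, 100.0, 5.0, 1.2, orientation="as_printed") != pytest.approx(
            quantify_ssdmc(10.0, 100.0, 5.0, 1.2))


class TestLodLoq:
    def test_ratio_is_ten_thirds(self):
        lod, loq = lod_loq(2.5e4, 20.0)
        assert loq / lod == pytest.approx(10 / 3)

    def test_doubling_slope_halves_lod(self):
        lod1, _ = lod_loq(1e4, 20.0)
        lod2, _ = lod_loq(2e4, 20.0)
        assert lod2 == pytest.approx(lod1 / 2)


class TestRecoveryAndRsd:
    def test_perfect_measurement_is_100(self):
        assert recovery(20.0, 10.0, 10.0) == pytest.approx(100.0)

    def test_no_added_signal_recovered_is_0(self):
        assert recovery(10.0, 10.0, 5.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("values,expected", [
        ([1.04, 1.05], 0.7),     # luteolin-7-O-glucuronide RRT pair
        ([1.65, 1.64], 0.4),     # diosmetin-7-O-glucoside RRT pair
        ([2.65, 2.64], 0.3),     # apigenin-7-O-6''-malonylglucoside RRT pair
    ])
    def test_instrument_pair_rsds(self, values, expected):
        assert round(rsd(values), 1) == expected

    def test_constant_list_is_zero(self):
        assert rsd([3.3, 3.3, 3.3]) == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.01, 1e3),
           values=st.lists(st.floats(1.0, 100.0), min_size=2, max_size=10))
    def test_rsd_scale_invariance(self, scale, values):
        v = np.asarray(values)
        assert rsd(scale * v) == pytest.approx(rsd(v), abs=1e-6)


class TestCompareMethods:
    def test_identical_vectors_degenerate(self):
        c = compare_methods([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.paired_t_p == 1.0 and c.zero_variance

    def test_pure_noise_rarely_significant(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            base = rng.uniform(10, 20, 20)
            a = base * (1 + 0.01 * rng.standard_normal(20))
            b = base * (1 + 0.01 * rng.standard_normal(20))
            if compare_methods(a, b).paired_t_p <= 0.05:
                hits += 1
        assert hits <= 2  # > 0.05 in >= 90% of seeded runs

    def test_systematic_bias_detected(self, rng):
        base = rng.uniform(10, 20, 20)
        biased = base * 1.10 * (1 + 0.005 * rng.standard_normal(20))
        assert compare_methods(biased, base).paired_t_p < 0.01


class TestValidationBattery:
    def test_report_structure_and_bounds(self):
        report = run_validation(GeneratorConfig(seed=3))
        df = report.per_analyte
        assert len(df) == 7
        assert (df.loq > df.lod).all() and (df.lod > 0).all()
        assert df.r2.between(0, 1).all()
        assert df.recovery_mean.between(80, 120).all()
        assert np.isfinite(report.comparison.paired_t_p)
        assert "SSDMC vs ESM" in report.summary()
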