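"""JIP-test parameter extraction: formulas, markers, areas, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytojip.curves import CurveValidationError, InductionCurve
from phytojip.ojip import (
    DegenerateTransientError,
    MarkerConfig,
    OJIPMarkers,
    UndefinedRatioError,
    analyze_transient,
    area_over_curve,
    average_transients,
    difference_kinetics,
    double_normalize,
    extract_markers,
    fitted_initial_slope,
    fv_fm,
    initial_slope,
    jip_summary,
    pi_abs,
    rc_abs,
    relative_variable_fluorescence,
)
from phytojip.synthetic import OJIPGenConfig, generate_ojip, ojip_v_true

MARKER_TIMES = (20e-6, 300e-6, 2e-3, 30e-3)


def _curve_through(points, fo=500.0, fm=2500.0):
    """Monotone curve hitting given (time, value) pairs exactly.

    Knots at the marker times plus log-spaced filler, linear in
    log-time between knots, so interpolation reproduces the points.
    """
    t = np.unique(np.concatenate([
        np.logspace(-5, 0, 118), [p[0] for p in points]
    ]))
    anchor_t = np.array([1e-5] + [p[0] for p in points] + [1.0])
    anchor_v = np.array([fo] + [p[1] for p in points] + [fm])
    values = np.interp(np.log10(t), np.log10(anchor_t), anchor_v)
    return InductionCurve(t, values)


class TestFormulas:
    """Hand-computed oracle values on the reference marker set."""

    def test_fv_fm(self, reference_markers):
        assert fv_fm(reference_markers) == pytest.approx(0.8, abs=1e-12)

    def test_fv_fm_boundary(self):
        m = OJIPMarkers(fo=1000.0, f300=1000.0, fj=1000.0, fi=1000.0,
                        fm=1000.0, t_fm=0.3)
        assert fv_fm(m) == 0.0

    def test_m0_chord(self, reference_markers):
        assert initial_slope(reference_markers) == pytest.approx(
            0.8, abs=1e-12
        )

    def test_m0_flat_rise(self):
        m = OJIPMarkers(fo=500.0, f300=500.0, fj=1500.0, fi=2000.0,
                        fm=2500.0, t_fm=0.3)
        assert initial_slope(m) == 0.0

    def test_m0_monotone_in_f300(self):
        slopes = [
            initial_slope(OJIPMarkers(fo=500.0, f300=f300, fj=1500.0,
                                      fi=2000.0, fm=2500.0, t_fm=0.3))
            for f300 in (600.0, 900.0, 1200.0)
        ]
        assert slopes == sorted(slopes) and len(set(slopes)) == 3

    def test_rc_abs(self, reference_markers):
        assert rc_abs(reference_markers) == pytest.approx(0.5, abs=1e-12)

    def test_rc_abs_degenerate_denominator(self):
        m = OJIPMarkers(fo=500.0, f300=500.0, fj=1500.0, fi=2000.0,
                        fm=2500.0, t_fm=0.3)
        with pytest.raises(UndefinedRatioError):
            rc_abs(m)

    def test_pi_abs(self, reference_markers):
        assert pi_abs(reference_markers) == pytest.approx(2.0, abs=1e-12)

    def test_pi_abs_vanishes_when_fj_equals_fm(self):
        m = OJIPMarkers(fo=500.0, f300=900.0, fj=2500.0, fi=2500.0,
                        fm=2500.0, t_fm=0.3)
        assert pi_abs(m) == pytest.approx(0.0, abs=1e-12)

    @given(
        fo=st.floats(10.0, 5000.0),
        d300=st.floats(1e-3, 1.0),
        dj=st.floats(1e-3, 1.0),
        dm=st.floats(1e-3, 1.0),
        scale=st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance_and_identity(self, fo, d300, dj, dm, scale):
        """Ratio parameters are invariant under F -> c*F, and PI(abs)
        factors into its three printed terms."""
        f300 = fo * (1 + d300)
        fj = f300 * (1 + dj)
        fm = fj * (1 + dm)
        m = OJIPMarkers(fo=fo, f300=f300, fj=fj, fi=fj, fm=fm, t_fm=0.3)
        ms = OJIPMarkers(fo=fo * scale, f300=f300 * scale, fj=fj * scale,
                         fi=fj * scale, fm=fm * scale, t_fm=0.3)
        for fn in (fv_fm, initial_slope, rc_abs, pi_abs):
            assert fn(ms) == pytest.approx(fn(m), rel=1e-9)
        phi = fv_fm(m)
        expected = rc_abs(m) * (phi / (1 - phi)) * (
            (m.fm - m.fj) / (m.fj - m.fo)
        )
        assert pi_abs(m) == pytest.approx(expected, rel=1e-12)


class TestMarkers:
    def test_exact_at_sampled_marker_times(self):
        points = list(zip(MARKER_TIMES, (500.0, 900.0, 1500.0, 2000.0)))
        curve = _curve_through(points)
        m = extract_markers(curve)
        assert (m.fo, m.f300, m.fj, m.fi) == pytest.approx(
            (500.0, 900.0, 1500.0, 2000.0), rel=1e-12
        )
        assert m.fm == pytest.approx(2500.0, rel=1e-12)

    def test_noise_free_generator_markers_match_closed_form(self):
        config = OJIPGenConfig(noise_cv=0.0)
        curve, truth = generate_ojip(config, seed=0)
        m = extract_markers(curve)
        fv = config.fm - config.fo
        # oracle: the generator's closed-form V at each marker time
        for got, t in ((m.fo, 20e-6), (m.f300, 300e-6), (m.fj, 2e-3),
                       (m.fi, 30e-3)):
            expected = config.fo + fv * float(ojip_v_true(config, t))
            # log-time linear interpolation on the 118-point grid
            assert got == pytest.approx(expected, rel=5e-4)
        assert m.fo == pytest.approx(config.fo, abs=3.0)
        assert m.fm == pytest.approx(config.fm, rel=0.01)

    def test_constant_curve_is_degenerate(self, make_curve):
        curve = make_curve(lambda t: np.full_like(t, 1000.0))
        with pytest.raises(DegenerateTransientError):
            extract_markers(curve)

    def test_marker_time_outside_range(self, make_curve):
        curve = make_curve(lambda t: 1000.0 + 100.0 * np.log10(t) + 600.0)
        config = MarkerConfig(t_fo=1e-7)
        with pytest.raises(CurveValidationError):
            extract_markers(curve, config)

    def test_non_monotone_rise_flagged_not_fatal(self):
        points = list(zip(MARKER_TIMES, (500.0, 1600.0, 1500.0, 2000.0)))
        curve = _curve_through(points)
        m = extract_markers(curve)
        assert any("non-monotone" in f for f in m.flags)


class TestVCurves:
    def test_v_anchors(self):
        points = list(zip(MARKER_TIMES, (500.0, 900.0, 1500.0, 2000.0)))
        curve = _curve_through(points)
        m = extract_markers(curve)
        v = relative_variable_fluorescence(curve, m)
        v_at_fo = np.interp(np.log10(m.t_fo), np.log10(v.times), v.v_values)
        v_at_fm = np.interp(np.log10(m.t_fm), np.log10(v.times), v.v_values)
        assert v_at_fo == pytest.approx(0.0, abs=1e-9)
        assert v_at_fm == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_vj(self):
        points = list(zip(MARKER_TIMES, (500.0, 900.0, 1500.0, 2000.0)))
        curve = _curve_through(points)
        m = extract_markers(curve)
        v = relative_variable_fluorescence(curve, m)
        vj = np.interp(np.log10(2e-3), np.log10(v.times), v.v_values)
        assert vj == pytest.approx(0.5, abs=1e-9)  # (1500-500)/2000

    def test_double_normalize_op_equals_v(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        m = extract_markers(curve)
        v = relative_variable_fluorescence(curve, m)
        w = double_normalize(curve, m, "OP")
        np.testing.assert_allclose(w.v_values, v.v_values, rtol=1e-12)

    def test_double_normalize_oj_anchor(self):
        points = list(zip(MARKER_TIMES, (500.0, 900.0, 1500.0, 2000.0)))
        curve = _curve_through(points)
        m = extract_markers(curve)
        w = double_normalize(curve, m, "OJ")
        w_at_j = np.interp(np.log10(2e-3), np.log10(w.times), w.v_values)
        assert w_at_j == pytest.approx(1.0, abs=1e-9)

    def test_woj_dominates_wop_before_j(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        m = extract_markers(curve)
        w_oj = double_normalize(curve, m, "OJ")
        w_op = double_normalize(curve, m, "OP")
        # ordering holds where F_t >= Fo, i.e. from the Fo marker onward
        early = (curve.times >= m.t_fo) & (curve.times <= 2e-3)
        assert np.all(w_oj.v_values[early] >= w_op.v_values[early] - 1e-12)

    def test_difference_identical_is_zero(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        m = extract_markers(curve)
        v = relative_variable_fluorescence(curve, m)
        dv = difference_kinetics(v, v)
        np.testing.assert_allclose(dv.v_values, 0.0, atol=1e-12)

    def test_difference_constant_offset(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        m = extract_markers(curve)
        v = relative_variable_fluorescence(curve, m)
        from phytojip.ojip import VCurve

        shifted = VCurve(v.times, v.v_values + 0.1, v.span_tag)
        dv = difference_kinetics(shifted, v)
        np.testing.assert_allclose(dv.v_values, 0.1, atol=1e-9)

    def test_lowered_j_weight_gives_negative_delta_near_j(self):
        control, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        treated, _ = generate_ojip(
            OJIPGenConfig(noise_cv=0.0, weights=(0.35, 0.35, 0.30)), seed=0
        )
        mc = extract_markers(control)
        mt = extract_markers(treated)
        dv = difference_kinetics(
            relative_variable_fluorescence(treated, mt),
            relative_variable_fluorescence(control, mc),
        )
        near_j = np.argmin(np.abs(dv.times - 2e-3))
        assert dv.v_values[near_j] < 0

    def test_span_mismatch_rejected(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        m = extract_markers(curve)
        with pytest.raises(ValueError, match="span"):
            difference_kinetics(
                double_normalize(curve, m, "OJ"),
                double_normalize(curve, m, "OP"),
            )


class TestArea:
    def test_flat_at_fm_gives_zero(self, make_curve):
        curve = make_curve(lambda t: np.full_like(t, 2500.0))
        m = OJIPMarkers(fo=500.0, f300=900.0, fj=1500.0, fi=2000.0,
                        fm=2500.0, t_fm=1.0, t_fo=1e-5)
        assert area_over_curve(curve, m) == pytest.approx(0.0, abs=1e-12)

    def test_linear_rise_closed_form(self):
        fo, fm, T = 500.0, 2500.0, 1.0
        t = np.logspace(-5, 0, 2000)
        curve = InductionCurve(t, fo + (fm - fo) * t / T)
        t0 = t[0]
        m = OJIPMarkers(fo=fo, f300=fo, fj=fo, fi=fo, fm=fm,
                        t_fm=T, t_fo=t0)
        expected = (fm - fo) * (T / 2 - t0 + t0**2 / (2 * T))
        got = area_over_curve(curve, m)
        assert got == pytest.approx(expected, rel=1e-6)
        assert area_over_curve(curve, m, normalized=True) == pytest.approx(
            expected / (fm - fo), rel=1e-6
        )

    def test_refinement_stability(self):
        dense, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0, n_points=236),
                                 seed=0)
        coarse, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0, n_points=118),
                                  seed=0)
        a_dense = area_over_curve(dense, extract_markers(dense))
        a_coarse = area_over_curve(coarse, extract_markers(coarse))
        assert abs(a_coarse - a_dense) / a_dense < 0.005

    def test_area_scales_with_fluorescence(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        m = extract_markers(curve)
        scaled = curve.scaled(3.0)
        ms = extract_markers(scaled)
        assert area_over_curve(scaled, ms) == pytest.approx(
            3.0 * area_over_curve(curve, m), rel=1e-9
        )
        assert area_over_curve(scaled, ms, normalized=True) == pytest.approx(
            area_over_curve(curve, m, normalized=True), rel=1e-9
        )


class TestAveraging:
    def test_identical_curves_unchanged(self):
        curve, _ = generate_ojip(OJIPGenConfig(), seed=5)
        avg = average_transients([curve, curve, curve])
        np.testing.assert_allclose(avg.values, curve.values, rtol=1e-12)

    def test_mean_of_v_and_3v(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        avg = average_transients([curve, curve.scaled(3.0)])
        np.testing.assert_allclose(avg.values, 2.0 * curve.values,
                                   rtol=1e-12)
        assert avg.metadata["n"] == 2

    def test_single_curve_rejected(self):
        curve, _ = generate_ojip(OJIPGenConfig(), seed=0)
        with pytest.raises(ValueError):
            average_transients([curve])

    def test_averaging_reduces_rms_error(self):
        """Mean of 6 noisy replicates beats every single replicate
        against the noise-free truth, across 20 seed groups."""
        config = OJIPGenConfig(noise_cv=0.05)
        clean, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
        wins = 0
        for group in range(20):
            reps = [generate_ojip(config, seed=1000 * group + r)[0]
                    for r in range(6)]
            avg = average_transients(reps)

            def rms(c):
                return np.sqrt(np.mean((c.values - clean.values) ** 2))

            if rms(avg) < min(rms(r) for r in reps):
                wins += 1
        assert wins >= 19


class TestSummary:
    def test_row_count_and_zero_se(self):
        curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0,
                                 metadata={"group": "A"})
        per_curve, groups = jip_summary([curve, curve, curve],
                                        group_by="group")
        assert len(per_curve) == 3
        assert np.allclose(groups["se"], 0.0)

    def test_percent_change_sign_matches_generator(self):
        low = [generate_ojip(OJIPGenConfig(fo=750.0, noise_cv=0.0), seed=s,
                             metadata={"group": "stressed"})[0]
               for s in range(3)]
        high = [generate_ojip(OJIPGenConfig(fo=500.0, noise_cv=0.0), seed=s,
                              metadata={"group": "control"})[0]
                for s in range(3)]
        _, groups = jip_summary(low + high, group_by="group",
                                reference="control")
        fvfm = groups[groups["parameter"] == "fv_fm"].set_index("group")
        assert fvfm.loc["stressed", "pct_change_vs_control"] < 0
        assert fvfm.loc["control", "pct_change_vs_control"] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_degenerate_curve_flagged_not_fatal(self, make_curve):
        good, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0,
                                metadata={"group": "A"})
        flat = make_curve(lambda t: np.full_like(t, 1000.0),
                          metadata={"group": "A"})
        per_curve, groups = jip_summary([good, flat, good], group_by="group")
        assert len(per_curve) == 3
        flagged = per_curve["flags"].str.startswith("degenerate")
        assert flagged.sum() == 1
        assert (groups["n"] == 2).all()


def test_fitted_slope_close_to_chord_on_smooth_curve():
    curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
    m = extract_markers(curve)
    chord = initial_slope(m)
    fitted = fitted_initial_slope(curve, m)
    assert fitted == pytest.approx(chord, rel=0.35)
    assert fitted > 0


def test_analyze_transient_parameter_consistency():
    curve, _ = generate_ojip(OJIPGenConfig(noise_cv=0.0), seed=0)
    p = analyze_transient(curve)
    assert 0 <= p.v_j <= p.v_i <= 1
    assert p.sm == pytest.approx(p.area / (2500.0 * 0.8), rel=0.02)
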