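"""DSC analysis: baseline, peak detection, 5% rule, enthalpy, phase diagram."""

import numpy as np
import pandas as pd
import pytest

from membraneloc import dsc, fixtures, synthetic as syn

from conftest import dense_scan_crossings

FLANKS = fixtures.DSC_FLANK_WINDOWS


def analyze(tg, **kw):
    kw.setdefault("flank_windows", FLANKS)
    return dsc.analyze_thermogram(tg, **kw)


def main_peak(peaks):
    return next(p for p in peaks if p.kind == dsc.MAIN)


class TestBaseline:
    def test_flat_trace_subtracts_to_zero(self):
        T = np.arange(10.0, 40.0, 0.05)
        tg = dsc.Thermogram(T, np.full_like(T, 3.7))
        out, (slope, intercept) = dsc.subtract_baseline(tg)
        np.testing.assert_allclose(out.Cp, 0.0, atol=1e-12)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(3.7)

    def test_sloped_baseline_recovers_generator_enthalpy(self):
        spec = fixtures.dsc_thermogram_spec(0.02, baseline=(0.012, -0.3))
        tg = syn.simulate_thermogram(spec)
        peaks = analyze(tg)
        assert main_peak(peaks).dH == pytest.approx(6.548, rel=0.01)

    def test_window_straddling_the_peak_is_rejected(self, high_drug_scan):
        with pytest.raises(ValueError, match="peak"):
            dsc.subtract_baseline(high_drug_scan, ((16.0, 19.0), (37.0, 40.0)))

    def test_overlapping_windows_rejected(self, high_drug_scan):
        with pytest.raises(ValueError, match="overlap"):
            dsc.subtract_baseline(high_drug_scan, ((10.0, 12.0), (11.0, 14.0)))

    def test_window_outside_grid_rejected(self, high_drug_scan):
        with pytest.raises(ValueError, match="outside"):
            dsc.subtract_baseline(high_drug_scan, ((5.0, 9.0), (37.0, 40.0)))


class TestDetectPeaks:
    def test_pure_lipid_scan_shows_pre_and_main_transition(self, pure_dmpc_scan):
        sub, _ = dsc.subtract_baseline(pure_dmpc_scan, FLANKS)
        peaks = dsc.detect_peaks(sub)
        kinds = {p.kind: p for p in peaks}
        assert set(kinds) == {dsc.PRE, dsc.MAIN}
        assert kinds[dsc.PRE].Tm == pytest.approx(12.5, abs=0.2)
        assert kinds[dsc.MAIN].Tm == pytest.approx(23.7, abs=0.05)

    def test_single_transition_scan_yields_one_main(self, high_drug_scan):
        sub, _ = dsc.subtract_baseline(high_drug_scan, FLANKS)
        peaks = dsc.detect_peaks(sub)
        assert [p.kind for p in peaks] == [dsc.MAIN]

    def test_two_equal_peaks_tie_breaks_to_lower_pre_transition(self):
        # two bit-identical Gaussian peaks 6 °C apart: deterministic labelling
        T = np.arange(10.0, 40.0, 0.01)
        Cp = 2.0 * (np.exp(-((T - 18.0) ** 2) / 0.5) + np.exp(-((T - 24.0) ** 2) / 0.5))
        peaks = dsc.detect_peaks(dsc.Thermogram(T, Cp))
        assert [p.kind for p in peaks] == [dsc.PRE, dsc.MAIN]
        assert peaks[0].Tm < peaks[1].Tm

    def test_featureless_trace_yields_empty_list(self):
        T = np.arange(10.0, 40.0, 0.05)
        tg = dsc.Thermogram(T, np.zeros_like(T))
        assert dsc.detect_peaks(tg) == []


class TestTransitionBounds:
    def test_symmetric_peak_has_symmetric_bounds(self):
        T = np.arange(10.0, 40.0, 0.01)
        tg = dsc.Thermogram(T, 3.0 * np.exp(-((T - 25.0) ** 2) / 1.3))
        peak = main_peak(dsc.detect_peaks(tg))
        lo, hi = dsc.transition_bounds(tg, peak)
        assert peak.Tm - lo == pytest.approx(hi - peak.Tm, abs=0.011)

    @pytest.mark.parametrize("ratio,onset", [(0.5, 14.4), (0.0, 22.6)])
    def test_onset_recovers_planted_solidus(self, ratio, onset):
        tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(ratio))
        peaks = analyze(tg)
        assert main_peak(peaks).T_onset == pytest.approx(onset, abs=0.05)

    @pytest.mark.parametrize("ratio", [0.0, 0.1, 0.5])
    def test_bounds_agree_with_dense_scan_oracle(self, ratio):
        tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(ratio))
        sub, _ = dsc.subtract_baseline(tg, FLANKS)
        peak = main_peak(dsc.detect_peaks(sub))
        lo, hi = dsc.transition_bounds(sub, peak)
        # oracle on the main-peak region only (exclude the pre-transition)
        m = sub.T > 14.0 if ratio == 0.0 else np.ones_like(sub.T, bool)
        o_lo, o_hi = dense_scan_crossings(sub.T[m], sub.Cp[m])
        assert lo == pytest.approx(o_lo, abs=0.01)
        assert hi == pytest.approx(o_hi, abs=0.01)

    def test_error_names_the_unresolved_side(self):
        # truncate the grid right of the peak so the trace never drops below 5%
        tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(0.5))
        m = tg.T <= 22.0
        cut = dsc.Thermogram(tg.T[m], tg.Cp[m])
        peak = main_peak(dsc.detect_peaks(cut))
        with pytest.raises(ValueError, match="high"):
            dsc.transition_bounds(cut, peak)

    @pytest.mark.parametrize("ratio", [0.02, 0.5])
    def test_raising_fraction_never_widens_bounds(self, ratio):
        tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(ratio))
        sub, _ = dsc.subtract_baseline(tg, FLANKS)
        peak = main_peak(dsc.detect_peaks(sub))
        lo5, hi5 = dsc.transition_bounds(sub, peak, 0.05)
        lo10, hi10 = dsc.transition_bounds(sub, peak, 0.10)
        assert lo10 >= lo5 and hi10 <= hi5


class TestEnthalpy:
    @pytest.mark.parametrize("ratio,dH", [(0.02, 6.548), (0.5, 6.348), (0.0, 6.626)])
    def test_integration_recovers_planted_enthalpy(self, ratio, dH):
        tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(ratio))
        assert main_peak(analyze(tg)).dH == pytest.approx(dH, rel=0.01)

    def test_integral_matches_refined_riemann_oracle(self, high_drug_scan):
        peak = main_peak(analyze(high_drug_scan))
        spec = fixtures.dsc_thermogram_spec(0.5)
        fine = syn.ThermogramSpec(transitions=spec.transitions, T_step=0.001)
        ref = syn.simulate_thermogram(fine)
        oracle = float(np.sum(ref.Cp) * 0.001)
        assert peak.dH == pytest.approx(oracle, rel=0.005)

    def test_negative_region_reports_zero_with_warning(self):
        T = np.arange(10.0, 40.0, 0.05)
        Cp = np.full_like(T, -0.01)
        tg = dsc.Thermogram(T, Cp)
        peak = dsc.TransitionPeak(Tm=25.0, height=1.0, T_onset=24.0, T_end=26.0)
        with pytest.warns(UserWarning, match="negative"):
            assert dsc.transition_enthalpy(tg, peak) == 0.0


class TestAnalyzeThermogram:
    @pytest.mark.parametrize("ratio,Tm", [(0.0, 23.7), (0.02, 22.1), (0.5, 17.8)])
    def test_main_transition_temperature_recovery(self, ratio, Tm):
        tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(ratio))
        assert main_peak(analyze(tg)).Tm == pytest.approx(Tm, abs=0.05)

    def test_empty_trace_gives_empty_result(self):
        T = np.arange(10.0, 40.0, 0.05)
        tg = dsc.Thermogram(T, np.zeros_like(T))
        assert analyze(tg, flank_windows=None) == []

    def test_noise_robust_tm_recovery(self):
        # 1% of peak height ≈ 0.064; Tm over 100 noisy replicates stays tight
        tms = []
        for seed in range(100):
            spec = fixtures.dsc_thermogram_spec(0.02, noise_sd=0.064, seed=seed)
            tg = syn.simulate_thermogram(spec)
            tms.append(main_peak(analyze(tg, min_prominence=1.0)).Tm)
        assert np.std(tms) < 0.1
        assert np.mean(tms) == pytest.approx(22.1, abs=0.05)


@pytest.fixture(scope="module")
def series():
    out = {}
    for ratio in fixtures.DSC_SERIES:
        tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(ratio))
        out[ratio] = main_peak(analyze(tg))
    return out


class TestPhaseDiagram:
    def test_solidus_falls_while_fluidus_stays(self, series):
        diagram = dsc.build_phase_diagram(series)
        t = diagram.table
        assert t["solidus_C"].iloc[0] == pytest.approx(22.6, abs=0.05)
        assert t["solidus_C"].iloc[-1] == pytest.approx(14.4, abs=0.05)
        assert t["solidus_C"].is_monotonic_decreasing
        assert np.ptp(t["fluidus_C"]) < 0.1
        assert (t["solidus_C"] <= t["fluidus_C"]).all()

    def test_every_row_brackets_the_peak_temperature(self, series):
        for ratio, p in series.items():
            assert p.T_onset <= p.Tm <= p.T_end

    def test_input_order_does_not_matter(self, series):
        fwd = dsc.build_phase_diagram(series)
        rev = dsc.build_phase_diagram(dict(reversed(list(series.items()))))
        pd.testing.assert_frame_equal(fwd.table, rev.table)

    def test_duplicated_pure_row_gives_flat_diagram(self, series):
        p = series[0.0]
        diagram = dsc.build_phase_diagram({0.0: p, 0.1: p, 0.2: p})
        assert np.ptp(diagram.table["solidus_C"]) == 0.0

    def test_replicates_propagate_sd(self, series):
        from dataclasses import replace

        a = series[0.0]
        b = replace(a, T_onset=a.T_onset + 0.2)
        diagram = dsc.build_phase_diagram({0.0: [a, b], 0.5: series[0.5]})
        assert diagram.table.loc[0, "solidus_sd"] > 0

    def test_requires_pure_lipid_row(self, series):
        with pytest.raises(ValueError, match="ratio 0"):
            dsc.build_phase_diagram({0.1: series[0.1], 0.5: series[0.5]})

    def test_inconsistent_bounds_rejected(self, series):
        p = series[0.0]
        bad = dsc.TransitionPeak(p.Tm, p.height, p.kind, p.dH, T_onset=25.0, T_end=20.0)
        with pytest.raises(ValueError, match="solidus"):
            dsc.build_phase_diagram({0.0: p, 0.5: bad})


class TestFluidImmiscibility:
    def _diagram(self, ratios, solidus, fluidus):
        rows = pd.DataFrame(
            {
                "ratio": ratios,
                "solidus_C": solidus,
                "solidus_sd": 0.0,
                "fluidus_C": fluidus,
                "fluidus_sd": 0.0,
            }
        )
        return dsc.PhaseDiagram(rows)

    def test_reference_series_flags_immiscibility(self):
        analyses = {}
        for ratio in fixtures.DSC_SERIES:
            tg = syn.simulate_thermogram(fixtures.dsc_thermogram_spec(ratio))
            analyses[ratio] = main_peak(analyze(tg))
        assessment = dsc.assess_fluid_immiscibility(dsc.build_phase_diagram(analyses))
        assert assessment.fluid_immiscibility
        assert assessment.solidus_slope < -2.0

    def test_ideal_mixing_is_not_flagged(self):
        d = self._diagram([0, 0.2, 0.5], [22.6, 20.0, 14.4], [24.6, 22.0, 18.0])
        assert not dsc.assess_fluid_immiscibility(d).fluid_immiscibility

    def test_slope_matches_two_point_finite_difference_on_linear_data(self):
        d = self._diagram([0, 0.25, 0.5], [22.6, 18.5, 14.4], [24.6, 24.1, 23.6])
        a = dsc.assess_fluid_immiscibility(d, slope_tol=0.1)
        assert a.fluidus_slope == pytest.approx((23.6 - 24.6) / 0.5)
        assert a.solidus_slope == pytest.approx((14.4 - 22.6) / 0.5)

    def test_too_few_rows_rejected(self):
        d = self._diagram([0, 0.5], [22.6, 14.4], [24.6, 24.6])
        with pytest.raises(ValueError, match="3"):
            dsc.assess_fluid_immiscibility(d)
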