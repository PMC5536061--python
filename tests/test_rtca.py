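"""Delta cell index, linear-phase slopes, doubling time and fluorescence ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocultrx.exceptions import ComputationError, ValidationError
from cocultrx.rtca import (
    FluorWell,
    RtcaTrace,
    delta_cell_index,
    dose_response_summary,
    doubling_time,
    linear_phase_slope,
    tg_storage,
)


def make_trace(times, ci_rows, **kw):
    return RtcaTrace(
        times=np.asarray(times, dtype=float),
        cell_index=np.asarray(ci_rows, dtype=float),
        well_ids=tuple(f"w{i}" for i in range(len(ci_rows))),
        **kw,
    )


class TestTraceValidation:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            make_trace([0, 1, 1], [[1, 2, 3]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            RtcaTrace(np.array([0.0, 1.0]), np.ones((2, 2)), ("w1",))

    def test_from_long_roundtrip(self):
        df = pd.DataFrame(
            {
                "time_h": [0.0, 1.0, 0.0, 1.0],
                "well": ["a", "a", "b", "b"],
                "cell_index": [1.0, 2.0, 3.0, 4.0],
            }
        )
        trace = RtcaTrace.from_long(df)
        assert trace.n_wells == 2
        assert np.allclose(trace.mean_ci(), [2.0, 3.0])


class TestDeltaCellIndex:
    def test_constant_trace_all_zero(self):
        trace = make_trace(np.arange(10), [np.full(10, 2.5)] * 3)
        delta = delta_cell_index(trace, t_treat=4.0)
        assert np.allclose(delta.delta, 0.0)

    def test_doubling_gives_delta_one(self):
        trace = make_trace([0, 1, 2], [[2.0, 3.0, 4.0]])
        delta = delta_cell_index(trace, t_treat=0.0)
        assert delta.delta[0, -1] == pytest.approx(1.0)

    def test_closed_form_linear_trace(self):
        t = np.arange(0.0, 48.25, 0.25)
        trace = make_trace(t, [2.0 + 0.1 * t])
        delta = delta_cell_index(trace, t_treat=0.0)
        assert np.allclose(delta.delta[0], 0.05 * t, rtol=0, atol=1e-12)

    def test_zero_at_treatment_time_for_every_well(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 24.0, 0.5)
        trace = make_trace(t, 1.0 + rng.random((8, t.size)))
        delta = delta_cell_index(trace, t_treat=12.2)
        i0 = int(np.searchsorted(t, 12.2, "right")) - 1
        assert np.allclose(delta.delta[:, i0], 0.0)
        assert delta.t_treat == t[i0]

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=30)
    def test_invariant_under_uniform_rescaling(self, c):
        t = np.arange(0.0, 10.0, 1.0)
        ci = 1.0 + 0.2 * t
        d1 = delta_cell_index(make_trace(t, [ci]), 2.0).delta
        d2 = delta_cell_index(make_trace(t, [c * ci]), 2.0).delta
        assert np.allclose(d1, d2)

    def test_zero_ci_at_treatment_rejected(self):
        trace = make_trace([0, 1, 2], [[0.0, 1.0, 2.0]])
        with pytest.raises(ValidationError, match="w0"):
            delta_cell_index(trace, t_treat=0.0)


class TestSlope:
    def test_noiseless_line_recovered_exactly(self):
        t = np.arange(0.0, 48.25, 0.25)
        trace = make_trace(t, [1.0 + 0.023 * t] * 4)
        fit = linear_phase_slope(trace)
        assert fit.slope == pytest.approx(0.023, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_trace_slope_zero(self):
        t = np.arange(0.0, 24.5, 0.5)
        fit = linear_phase_slope(make_trace(t, [np.full(t.size, 3.0)]))
        assert fit.slope == pytest.approx(0.0)

    def test_explicit_window(self):
        t = np.arange(0.0, 48.0, 1.0)
        y = np.where(t < 24, 1.0, 1.0 + 0.05 * (t - 24))
        fit = linear_phase_slope(make_trace(t, [y]), window=(24.0, 47.0))
        assert fit.slope == pytest.approx(0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            linear_phase_slope(
                make_trace([0, 1, 2, 3], [[1, 2, 3, 4]]), window=(0.0, 1.0)
            )

    def test_no_adequate_window_raises(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 24.0, 1.0)
        noisy = rng.normal(0.0, 5.0, t.size)
        with pytest.raises(ComputationError):
            linear_phase_slope(make_trace(t, [noisy]), r2_min=0.999)


class TestDoublingTime:
    def test_linear_convention_closed_form(self):
        t = np.arange(0.0, 30.0, 1.0)
        fit = linear_phase_slope(make_trace(t, [1.0 + 0.05 * t]))
        assert doubling_time(fit, "linear", ref_ci=1.0) == pytest.approx(20.0)

    def test_exponential_convention(self):
        t = np.arange(0.0, 72.0, 0.5)
        trace = make_trace(t, [np.exp(0.0231 * t)])
        fit = linear_phase_slope(trace, window=(0.0, 71.0), log_scale=True)
        assert doubling_time(fit, "exponential") == pytest.approx(np.log(2) / 0.0231,
                                                                  rel=1e-6)

    def test_non_positive_slope_rejected(self):
        t = np.arange(0.0, 30.0, 1.0)
        fit = linear_phase_slope(make_trace(t, [5.0 - 0.05 * t]))
        with pytest.raises(ComputationError):
            doubling_time(fit, "linear", ref_ci=1.0)

    def test_convention_mismatch_rejected(self):
        t = np.arange(0.0, 30.0, 1.0)
        fit = linear_phase_slope(make_trace(t, [1.0 + 0.05 * t]))
        with pytest.raises(ValidationError):
            doubling_time(fit, "exponential")


def _dose_traces(effects, sigma=0.0, n_wells=8, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 10.25, 0.25)
    out = {}
    for dose, eff in effects.items():
        base = 2.0 + 0.0 * t
        base = base + eff * np.clip(t - 5.0, 0.0, None) / 2.5  # reaches eff at t=7.5
        ci = base + rng.normal(0.0, sigma, (n_wells, t.size))
        out[dose] = RtcaTrace(t, ci, tuple(f"d{dose}w{i}" for i in range(n_wells)),
                              dose_uM=dose)
    return out


class TestDoseResponse:
    def test_no_effect_no_flags(self):
        traces = _dose_traces({0.0: 0.0, 6.0: 0.0, 20.0: 0.0}, sigma=0.01)
        summary = dose_response_summary(traces, t_eval=7.5, t_treat=5.0)
        assert not summary["significant"].any()

    def test_planted_monotone_effect_recovered(self):
        effects = {0.0: 0.0, 1.0: -0.04, 2.0: -0.08, 3.0: -0.12}
        traces = _dose_traces(effects, sigma=0.02)
        summary = dose_response_summary(traces, t_eval=7.5, t_treat=5.0)
        means = summary.sort_values("dose_uM")["mean_delta"].to_numpy()
        assert np.all(np.diff(means) < 0)
        top = summary.sort_values("dose_uM").iloc[-1]
        assert bool(top["significant"])

    def test_missing_vehicle_rejected(self):
        traces = _dose_traces({6.0: 0.0, 20.0: 0.0})
        with pytest.raises(ValidationError):
            dose_response_summary(traces, t_eval=7.5, t_treat=5.0)

    def test_single_well_group_rejected(self):
        traces = _dose_traces({0.0: 0.0})
        traces[6.0] = _dose_traces({6.0: 0.0}, n_wells=1)[6.0]
        with pytest.raises(ValidationError):
            dose_response_summary(traces, t_eval=7.5, t_treat=5.0)


class TestTgStorage:
    def test_fold_two_when_adipored_doubles(self):
        wells = [FluorWell("a", 0.0, 100.0, 50.0), FluorWell("b", 0.0, 100.0, 50.0),
                 FluorWell("c", 10.0, 200.0, 50.0), FluorWell("d", 10.0, 200.0, 50.0)]
        out = tg_storage(wells).set_index("dose_uM")
        assert out.loc[10.0, "fold_vs_vehicle"] == pytest.approx(2.0)

    def test_common_well_effect_cancels(self):
        wells = [FluorWell("a", 0.0, 100.0, 50.0),
                 FluorWell("b", 10.0, 200.0, 100.0)]  # both signals doubled
        out = tg_storage(wells).set_index("dose_uM")
        assert out.loc[10.0, "fold_vs_vehicle"] == pytest.approx(1.0)

    def test_dose_proportional_loading_recovered(self):
        rng = np.random.default_rng(2)
        wells = []
        for dose in (0.0, 5.0, 10.0, 20.0):
            for w in range(6):
                hoechst = rng.normal(100.0, 5.0)
                ratio_true = 1.0 + 0.05 * dose
                wells.append(FluorWell(f"{dose}_{w}", dose,
                                       ratio_true * hoechst * rng.normal(1.0, 0.02),
                                       hoechst))
        out = tg_storage(wells)
        slope = np.polyfit(out["dose_uM"], out["mean_ratio"], 1)[0]
        assert slope == pytest.approx(0.05, rel=0.10)

    def test_nonpositive_hoechst_rejected(self):
        with pytest.raises(ValidationError):
            FluorWell("a", 0.0, 1.0, 0.0)
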