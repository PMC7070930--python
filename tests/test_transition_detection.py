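"""Tg_F / Tg_Q / UFS-onset detectors and report assembly."""

import numpy as np
import pytest

from mta.deconvolution import deconvolve
from mta.transition_detection import (
    NoTransitionError,
    build_report,
    quality_transition,
    rs_maxima,
    ufs_onset_and_detuning,
)


def _gauss(t, center, width=1.0):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


class TestRsMaxima:
    def test_single_bump(self):
        t = np.linspace(30, 70, 4001)
        rs = 9.4 + 5.0 * _gauss(t, 45.0)
        maxima = rs_maxima(rs, t)
        assert len(maxima) == 1
        assert maxima[0][0] == pytest.approx(45.0, abs=0.05)

    def test_two_bumps_ordered_by_temperature(self):
        t = np.linspace(30, 70, 4001)
        rs = 9.4 + 4.0 * _gauss(t, 45.0) + 6.0 * _gauss(t, 50.0)
        maxima = rs_maxima(rs, t)
        assert len(maxima) == 2
        assert maxima[0][0] == pytest.approx(45.0, abs=0.1)
        assert maxima[1][0] == pytest.approx(50.0, abs=0.1)

    def test_subthreshold_noise_gives_empty_list(self):
        rng = np.random.default_rng(3)
        t = np.linspace(30, 70, 2001)
        rs = 9.4 + 0.01 * rng.normal(size=t.size)
        # any tiny wiggle has prominence comparable to the global span; demand
        # wide peaks so pure noise cannot qualify
        assert rs_maxima(rs, t, min_width=300) == []

    def test_translation_equivariance(self):
        t = np.linspace(30, 70, 4001)
        rs = 9.4 + 5.0 * _gauss(t, 45.0)
        base = rs_maxima(rs, t)
        shifted = rs_maxima(rs, t + 7.5)
        assert shifted[0][0] == pytest.approx(base[0][0] + 7.5, abs=1e-9)


class TestQualityTransition:
    def test_v_shape_minimum(self):
        t = np.linspace(30, 70, 2001)
        q = 2000 + 40 * np.abs(t - 50.0)
        temp, method = quality_transition(q, t, P=20.0, dt=(t[1] - t[0]) * 37.5)
        assert method == "minimum"
        assert temp == pytest.approx(50.0, abs=0.5)

    def test_pure_logistic_rise_onset(self):
        t = np.linspace(30, 70, 4001)
        w = 1.5
        q = 2000 + 600 / (1 + np.exp(-(t - 50.0) / w))
        temp, method = quality_transition(q, t, P=20.0, dt=(t[1] - t[0]) * 37.5)
        assert method == "rise-onset"
        # tangent onset of a logistic sits ~2*w below the center; in any case
        # within half the 10-90% transition width (~2.2*w) of the center
        assert abs(temp - 50.0) <= 2.2 * w

    def test_default_scenario_near_dynamic_tg(self, default_measurement, default_deconv):
        temp, method = quality_transition(
            default_measurement.quality["1"],
            default_measurement.temperature,
            P=20.0,
            dt=0.2,
            edge_samples=default_deconv.edge_samples,
        )
        assert method == "minimum"
        assert temp == pytest.approx(50.0, abs=1.0)

    def test_monotone_decrease_raises(self):
        t = np.linspace(30, 70, 1001)
        with pytest.raises(NoTransitionError):
            quality_transition(3000 - 10 * t, t, P=20.0, dt=(t[1] - t[0]) * 37.5)


class TestUfsOnset:
    def test_exact_piecewise_linear_breakpoint(self):
        t = np.linspace(30, 70, 4001)
        y = np.where(t < 45.0, -30.0 * (t - 30.0), -450.0 - 90.0 * (t - 45.0))
        onset, _ = ufs_onset_and_detuning(y, t)
        assert onset == pytest.approx(45.0, abs=0.05)

    def test_logistic_step_detuning_amplitude(self):
        t = np.linspace(30, 70, 4001)
        y = -30.0 * (t - 30.0) - 300.0 / (1 + np.exp(-(t - 45.0) / 1.0))
        onset, delta_f = ufs_onset_and_detuning(y, t)
        assert delta_f == pytest.approx(300.0, rel=0.02)
        assert onset is not None and onset < 45.0

    def test_pure_line_reports_absent(self):
        t = np.linspace(30, 70, 2001)
        onset, delta_f = ufs_onset_and_detuning(-30.0 * (t - 30.0), t)
        assert onset is None
        assert delta_f == pytest.approx(0.0, abs=1e-6)

    def test_translation_equivariance(self):
        t = np.linspace(30, 70, 4001)
        y = np.where(t < 45.0, -30.0 * (t - 30.0), -450.0 - 90.0 * (t - 45.0))
        base, _ = ufs_onset_and_detuning(y, t)
        shifted, _ = ufs_onset_and_detuning(y, t + 3.0)
        assert shifted == pytest.approx(base + 3.0, abs=1e-6)


class TestBuildReport:
    def test_default_scenario_report(self, default_measurement, default_deconv):
        report = build_report(default_deconv, default_measurement.quality["1"])
        assert report.tg_f == pytest.approx(45.0, abs=1.0)
        assert report.tg_q == pytest.approx(50.0, abs=1.0)
        assert report.delta_qf == pytest.approx(report.tg_q - report.tg_f)
        assert report.tg_f == report.rs_maxima[0][0]
        assert report.detuning == pytest.approx(300.0, rel=0.1)
        assert report.tg_q >= report.tg_f  # dynamic signature above the static one

    def test_two_step_flags_multiple_maxima(self):
        from mta import make_scenario

        b = make_scenario("two_step", 1)
        m = b.simulate()
        d = deconvolve(m, "1", P=20.0)
        report = build_report(d, m.quality["1"])
        assert "multiple-maxima" in report.flags
        assert len(report.rs_maxima) >= 2

    def test_replicates_recover_embedded_offset(self):
        from mta import make_scenario

        deltas = []
        for seed in range(1, 13):
            b = make_scenario("indomethacin_default", seed)
            m = b.simulate()
            d = deconvolve(m, "1", P=20.0)
            deltas.append(build_report(d, m.quality["1"]).delta_qf)
        # scenario embeds tg_dynamic - tg_static = 5 degC; the Q minimum sits
        # slightly below tg_dynamic where dip and rise balance
        assert np.mean(deltas) == pytest.approx(5.0, abs=1.0)

    def test_noise_free_recovery_of_ground_truth(self):
        from mta.signal_simulator import (
            StringModel,
            TemperatureProgram,
            TgScenario,
            simulate_measurement,
        )

        program = TemperatureProgram()
        scenario = TgScenario(noise_f=0.0, noise_q=0.0)
        m = simulate_measurement(StringModel(), scenario, program)
        d = deconvolve(m, "1", P=20.0)
        report = build_report(d, m.quality["1"])
        # one modulation period spans rate*P/60 ~ 0.53 degC of the ramp
        assert abs(report.tg_f - scenario.tg_static) <= 0.6
        assert abs(report.tg_q - scenario.tg_dynamic) <= scenario.step_width
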