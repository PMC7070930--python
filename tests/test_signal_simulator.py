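"""String physics, heating program, and measurement simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mta.deconvolution import dominant_period, underlying_signal, upper_envelope
from mta.signal_simulator import (
    AliasingError,
    InvalidProgramError,
    Particle,
    StringModel,
    TemperatureProgram,
    TgScenario,
    duty_cycle,
    estimate_sample_mass,
    generate_temperature,
    loaded_mode_frequency,
    quality_profile,
    simulate_measurement,
)


class TestDutyCycle:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, 0.10),                      # sin(0) = 0
            (20.0, 0.10 + 2e-4 * 20),         # sin(2*pi) = 0
            (5.0, 0.10 + 2e-4 * 5 + 0.01),    # sin(pi/2) = 1 at t = P/4
        ],
    )
    def test_known_points(self, t, expected):
        program = TemperatureProgram(ks=0.10, kl=2e-4, P=20.0, A_mod=0.01)
        assert duty_cycle(program, t) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(InvalidProgramError):
            TemperatureProgram(P=0.0)

    @given(st.floats(0, 1e4), st.floats(0, 0.5), st.floats(0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_clamped_to_unit_interval(self, t, ks, a_mod):
        program = TemperatureProgram(ks=ks, kl=1e-3, A_mod=a_mod)
        assert 0.0 <= duty_cycle(program, t) <= 1.0


class TestTemperatureProgram:
    def test_start_and_whole_period_values(self):
        program = TemperatureProgram()
        t, temp = generate_temperature(program, 600.0, 0.2)
        assert temp[0] == pytest.approx(30.0)
        # 600 s at 1.6 degC/min = +16 degC; modulation completes 30 full cycles
        assert temp[-1] == pytest.approx(46.0, abs=1e-9)

    def test_modulation_envelope_is_programmed_amplitude(self):
        program = TemperatureProgram()
        t, temp = generate_temperature(program, 1500.0, 0.2)
        linear = program.T0 + (program.rate / 60.0) * t
        env = upper_envelope(temp - linear, program.P, 0.2)
        interior = slice(200, -200)
        assert np.allclose(env[interior], 0.2, rtol=0.01)

    def test_aliasing_guard(self):
        with pytest.raises(AliasingError):
            generate_temperature(TemperatureProgram(P=20.0), 100.0, 10.0)


class TestLoadedModeFrequency:
    def test_unloaded_harmonic_ladder_is_exact(self):
        string = StringModel(f1=163_000.0)
        for n in range(1, 6):
            assert loaded_mode_frequency(string, [], n) == n * string.f1
        assert loaded_mode_frequency(string, [], 3) / loaded_mode_frequency(string, [], 1) == 3.0

    def test_particle_at_node_leaves_mode_untouched(self):
        string = StringModel()
        p = Particle(x=0.5, mass=2.0, diameter=10.0)
        assert loaded_mode_frequency(string, [p], 2) == pytest.approx(
            2 * string.f1, rel=1e-14
        )

    def test_loading_lowers_frequency(self):
        string = StringModel()
        p = Particle(x=0.3, mass=1.0, diameter=10.0)
        assert loaded_mode_frequency(string, [p], 1) < string.f1


class TestSampleMass:
    def test_zero_at_unshifted_resonance(self):
        assert estimate_sample_mass(200e3, 200e3, 10.0) == 0.0

    def test_known_evaluation(self):
        # pi*10*(200^2-190^2) / ((pi+2)*190^2) kHz^2 -> 0.6601 ng
        assert estimate_sample_mass(200e3, 190e3, 10.0) == pytest.approx(0.6601, abs=2e-4)

    def test_round_trips_forward_load_model(self):
        string = StringModel()
        for mass in (0.433, 0.494, 2.5):
            p = Particle(x=0.5, mass=mass, diameter=5.0)  # antinode: full weight
            f_loaded = loaded_mode_frequency(string, [p], 1)
            est = estimate_sample_mass(string.f1, f_loaded, string.m0)
            assert est == pytest.approx(mass, rel=1e-12)

    @given(st.floats(100e3, 199e3))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_frequency_shift(self, f_res):
        m_hi = estimate_sample_mass(200e3, f_res, 10.0)
        m_lo = estimate_sample_mass(200e3, f_res + 500.0, 10.0)
        assert m_hi > m_lo >= 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            estimate_sample_mass(200e3, 210e3, 10.0)
        with pytest.raises(ValueError):
            estimate_sample_mass(200e3, 0.0, 10.0)
        with pytest.raises(ValueError):
            estimate_sample_mass(200e3, 190e3, -1.0)


class TestSimulateMeasurement:
    def test_deterministic_under_seed(self):
        string, program = StringModel(), TemperatureProgram()
        scenario = TgScenario(seed=7)
        a = simulate_measurement(string, scenario, program, duration=300.0)
        b = simulate_measurement(string, scenario, program, duration=300.0)
        assert np.array_equal(a.freq["1"], b.freq["1"])
        assert np.array_equal(a.quality["1"], b.quality["1"])

    def test_pure_thermal_response_without_transition(self):
        string, program = StringModel(), TemperatureProgram()
        scenario = TgScenario(detune_total=0.0, noise_f=0.0, noise_q=0.0)
        m = simulate_measurement(string, scenario, program, duration=600.0)
        reconstructed = m.freq["1"] - string.c_T * (m.temperature - program.T0)
        assert np.allclose(reconstructed, string.f1, atol=1e-9)

    def test_modulation_transfers_into_frequency(self, default_measurement):
        f_peak = dominant_period(default_measurement.freq["1"], default_measurement.dt)
        assert f_peak == pytest.approx(0.050, abs=1.0 / 1500.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_quality_minimum_embeds_dynamic_tg(self, seed):
        string, program = StringModel(), TemperatureProgram()
        scenario = TgScenario(seed=seed)
        m = simulate_measurement(string, scenario, program)
        q = underlying_signal(m.quality["1"], program.P, m.dt)
        t_min = m.temperature[np.argmin(q)]
        assert abs(t_min - scenario.tg_dynamic) <= scenario.step_width

    def test_quality_profile_dips_then_rises(self):
        scenario = TgScenario()
        temp = np.linspace(30, 70, 2001)
        q = quality_profile(scenario, temp)
        assert q[0] == pytest.approx(scenario.q0, rel=1e-3)
        assert q.min() < scenario.q0 - 0.8 * scenario.q_dip
        assert q[-1] == pytest.approx(scenario.q0 + scenario.q_rise, rel=1e-3)
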