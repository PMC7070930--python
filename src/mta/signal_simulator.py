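"""Simulation of modulated micromechanical thermal analysis (MTA) measurements.

A silicon-rich nitride microstring resonator is heated with a slow linear
ramp carrying a small sinusoidal temperature modulation (mDSC-style).  The
string's resonance frequency follows temperature through tensile-stress
relaxation, and an amorphous sample deposited on the string detunes the
resonance when it passes its glass transition: effective mass redistribution
during viscous flow shifts the frequency, while viscoelastic damping produces
a dip followed by a sharp rise in the quality factor.

This module generates such measurements with known embedded ground truth so
that the deconvolution and detection stages can be validated quantitatively.
It also houses the string-physics helpers: the duty-cycle heating law, the
mode-shape-weighted load model and its exact inverse, the distributed-load
sample-mass approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

_PI = np.pi


class InvalidProgramError(ValueError):
    """Raised when a temperature program cannot be realized."""


class AliasingError(ValueError):
    """Raised when the sampling interval cannot resolve the modulation."""


@dataclass(frozen=True)
class TemperatureProgram:
    """Modulated heating program: a linear ramp plus a sinusoidal modulation.

    The Peltier heater is driven by a PWM duty cycle
    ``DC(t) = ks + kl*t + A_mod*sin(2*pi*t/P)``; since the duty-to-temperature
    map is close to linear over the narrow working range, the program is also
    expressed directly in temperature space through ``T0``, ``rate`` and
    ``amp_T``.

    Parameters
    ----------
    ks : dimensionless minimum duty constant (heater dependent).
    kl : duty increase per second (sets the underlying heating rate).
    P : modulation period, seconds.
    A_mod : modulation amplitude in duty space.
    T0 : start temperature, degC.
    rate : underlying heating rate, degC/min.
    amp_T : realized temperature modulation amplitude, degC.
    """

    ks: float = 0.10
    kl: float = 2.0e-4
    P: float = 20.0
    A_mod: float = 0.01
    T0: float = 30.0
    rate: float = 1.6
    amp_T: float = 0.2

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise InvalidProgramError(f"modulation period must be positive, got {self.P}")
        if self.rate <= 0:
            raise InvalidProgramError(f"heating rate must be positive, got {self.rate}")
        if self.amp_T < 0:
            raise InvalidProgramError(f"modulation amplitude must be >= 0, got {self.amp_T}")


@dataclass(frozen=True)
class StringModel:
    """Geometry-free description of one resonating microstring.

    ``f1`` is the fundamental resonance of the bare string at the start
    temperature; the unloaded harmonic ladder is exact, ``f_n = n * f1``.
    ``c_T`` is the linear temperature responsivity of frequency (negative:
    heating relaxes tensile stress and lowers the resonance).
    """

    L: float = 500.0          # string length, um
    m0: float = 10.0          # string mass, ng
    f1: float = 163_000.0     # fundamental at T0, Hz
    c_T: float = -30.0        # Hz per degC
    n_modes: int = 1

    def __post_init__(self) -> None:
        if self.f1 <= 0:
            raise ValueError("fundamental frequency must be positive")
        if self.m0 <= 0:
            raise ValueError("string mass must be positive")


@dataclass(frozen=True)
class Particle:
    """A sample particle sitting on the string."""

    x: float          # fractional position along the string, [0, 1]
    mass: float       # ng
    diameter: float   # um

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"particle position must be in [0, 1], got {self.x}")
        if self.mass <= 0:
            raise ValueError("particle mass must be positive")
        if self.diameter <= 0:
            raise ValueError("particle diameter must be positive")


@dataclass(frozen=True)
class TgScenario:
    """Ground-truth glass-transition scenario embedded in a simulation.

    ``tg_static`` is the quasi-static onset (first reversing-signal maximum);
    ``tg_dynamic`` is the liquefaction signature (quality-factor transition).
    The frequency detuning is a logistic step of total depth ``detune_total``
    centred at ``tg_static``; with ``two_step`` a second logistic of the same
    depth is added at ``tg_dynamic``, emulating the two-fold frequency change
    seen when effective-mass redistribution continues through liquefaction.
    """

    tg_static: float = 45.0
    tg_dynamic: float = 50.0
    detune_total: float = 300.0
    two_step: bool = False
    step_width: float = 1.0
    q0: float = 2000.0
    q_dip: float = 400.0
    q_rise: float = 600.0
    noise_f: float = 0.5
    noise_q: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tg_dynamic < self.tg_static:
            raise ValueError("tg_dynamic must be >= tg_static")
        if self.q0 <= 0 or self.q0 - self.q_dip <= 0:
            raise ValueError("baseline quality factor must stay positive through the dip")
        if self.noise_f < 0 or self.noise_q < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.step_width <= 0:
            raise ValueError("step width must be positive")


@dataclass(frozen=True)
class ModeSpec:
    """One tracked resonance mode of a simulated measurement.

    ``responsivity`` scales the glass-transition detuning of this mode
    relative to the scenario's ``detune_total`` (mixed/torsional modes couple
    more strongly to a given sample distribution than pure flexural ones).
    ``base_offset_hz`` shifts the baseline away from the exact harmonic
    ladder, used for mixed modes that sit near but not on a harmonic.
    """

    mode_id: str
    harmonic: int = 1
    responsivity: float = 1.0
    base_offset_hz: float = 0.0


@dataclass
class Measurement:
    """Synchronized time / temperature / frequency / quality-factor traces."""

    time: np.ndarray                    # s
    temperature: np.ndarray             # degC
    freq: dict[str, np.ndarray]         # Hz per tracked mode
    quality: dict[str, np.ndarray]      # dimensionless per tracked mode
    mode_ids: list[str]
    dt: float
    truth: Optional[TgScenario] = None
    program: Optional[TemperatureProgram] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.temperature) != n:
            raise ValueError("temperature and time series must have equal length")
        for mid in self.mode_ids:
            if len(self.freq[mid]) != n or len(self.quality[mid]) != n:
                raise ValueError(f"mode {mid!r} traces must match the time base")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")


# ---------------------------------------------------------------------------
# heating program


def duty_cycle(program: TemperatureProgram, t) -> np.ndarray | float:
    """PWM duty fraction at time ``t``: ks + kl*t + A_mod*sin(2*pi*t/P).

    Clamped to the physical range [0, 1].
    """
    t = np.asarray(t, dtype=float)
    dc = program.ks + program.kl * t + np.sin(2 * _PI * t / program.P) * program.A_mod
    out = np.clip(dc, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def generate_temperature(
    program: TemperatureProgram, duration: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Realized temperature trace of the modulated ramp.

    ``T(t) = T0 + (rate/60)*t + amp_T*sin(2*pi*t/P)`` sampled on
    ``t = 0, dt, ..., floor(duration/dt)*dt``.

    Returns ``(time, temperature)``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if dt >= program.P / 2:
        raise AliasingError(
            f"dt={dt} s cannot resolve a {program.P} s modulation (need dt < P/2)"
        )
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt
    temp = (
        program.T0
        + (program.rate / 60.0) * t
        + program.amp_T * np.sin(2 * _PI * t / program.P)
    )
    return t, temp


# ---------------------------------------------------------------------------
# string physics

_LOAD_COEF = (_PI + 2.0) / _PI  # distributed-load mass coefficient


def estimate_sample_mass(f0: float, f_res: float, m0: float) -> float:
    """Approximate sample mass from the resonance shift of a loaded string.

    For a string of mass ``m0`` whose bare resonance ``f0`` drops to
    ``f_res`` under a distributed sample load,

        m_sample = pi * m0 * (f0**2 - f_res**2) / ((pi + 2) * f_res**2)

    The estimate is zero at ``f_res == f0`` and grows monotonically as the
    loaded resonance falls.
    """
    if m0 <= 0:
        raise ValueError("string mass must be positive")
    if f_res <= 0:
        raise ValueError(f"loaded resonance must be positive, got {f_res}")
    if f_res > f0:
        raise ValueError(
            f"loaded resonance {f_res} Hz above bare resonance {f0} Hz implies negative mass"
        )
    return _PI * m0 * (f0**2 - f_res**2) / ((_PI + 2.0) * f_res**2)


def effective_load(particles: Sequence[Particle], n: int) -> float:
    """Mode-shape-weighted sample load for harmonic ``n``, in ng.

    Local mass responsivity scales with the square of the local vibrational
    amplitude, so each particle contributes ``mass * sin^2(n*pi*x)``.  A
    particle at an antinode therefore counts with full weight (the reference
    distribution used by the mass estimate), one at a node not at all.
    """
    if n < 1:
        raise ValueError("harmonic index must be >= 1")
    return float(sum(p.mass * np.sin(n * _PI * p.x) ** 2 for p in particles))


def loaded_mode_frequency(
    string: StringModel, particles: Sequence[Particle], n: int
) -> float:
    """Resonance frequency of harmonic ``n`` under a particle load.

    The unloaded ladder is exact (``n * f1``); loading scales it by the exact
    inverse of the distributed-load mass approximation so that
    ``estimate_sample_mass`` round-trips the effective load:

        f_n = n * f1 * sqrt( pi*m0 / (pi*m0 + (pi+2)*m_eff) )
    """
    m_eff = effective_load(particles, n)
    scale = np.sqrt(_PI * string.m0 / (_PI * string.m0 + (_PI + 2.0) * m_eff))
    return float(n * string.f1 * scale)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def detuning_profile(scenario: TgScenario, temperature: np.ndarray) -> np.ndarray:
    """Frequency detuning (Hz, negative = downward) as a function of temperature.

    One logistic step of depth ``detune_total`` centred at the static onset;
    ``two_step`` adds a second equal step at the dynamic transition.
    """
    temp = np.asarray(temperature, dtype=float)
    w = scenario.step_width
    d = -scenario.detune_total * _logistic((temp - scenario.tg_static) / w)
    if scenario.two_step:
        d = d - scenario.detune_total * _logistic((temp - scenario.tg_dynamic) / w)
    return d


def quality_profile(scenario: TgScenario, temperature: np.ndarray) -> np.ndarray:
    """Noise-free quality factor vs temperature: baseline, dip, sharp rise.

    The damping dip is a Gaussian centred at the dynamic transition; the
    subsequent rise (liquefied sample damps less) sets in two step widths
    later so the dip stays pronounced, giving a Q minimum within one step
    width of ``tg_dynamic`` followed by the sharp shift to higher values.
    """
    temp = np.asarray(temperature, dtype=float)
    w = scenario.step_width
    u = (temp - scenario.tg_dynamic) / w
    dip = scenario.q_dip * np.exp(-0.5 * u**2)
    rise = scenario.q_rise * _logistic(u - 2.0)
    return scenario.q0 - dip + rise


def simulate_measurement(
    string: StringModel,
    scenario: TgScenario,
    program: TemperatureProgram,
    duration: float = 1500.0,
    dt: float = 0.2,
    particles: Sequence[Particle] = (),
    modes: Optional[Sequence[ModeSpec]] = None,
) -> Measurement:
    """Simulate a full modulated-MTA measurement with embedded ground truth.

    Per tracked mode the frequency trace is the loaded baseline, plus the
    linear temperature response ``c_T * (T - T0)`` evaluated on the modulated
    temperature (which transfers the modulation into the frequency domain),
    plus the mode-responsivity-scaled glass-transition detuning, plus white
    Gaussian noise.  The quality factor follows the scenario's dip-and-rise
    profile with its own noise.  Identical (scenario.seed, config) give
    bit-identical output.
    """
    t, temp = generate_temperature(program, duration, dt)
    if scenario.tg_static < temp.min() or scenario.tg_dynamic > temp.max():
        log.warning(
            "glass-transition window [%s, %s] degC not fully inside the ramp "
            "[%s, %s] degC; traces produced anyway",
            scenario.tg_static, scenario.tg_dynamic, temp.min(), temp.max(),
        )

    if modes is None:
        modes = [ModeSpec(mode_id=str(n), harmonic=n) for n in range(1, string.n_modes + 1)]

    rng = np.random.default_rng(scenario.seed)
    freq: dict[str, np.ndarray] = {}
    quality: dict[str, np.ndarray] = {}
    detune = detuning_profile(scenario, temp)
    q_clean = quality_profile(scenario, temp)
    for spec in modes:
        base = loaded_mode_frequency(string, particles, spec.harmonic) + spec.base_offset_hz
        f = (
            base
            + string.c_T * (temp - program.T0)
            + spec.responsivity * detune
            + rng.normal(0.0, scenario.noise_f, size=t.shape)
        )
        q = q_clean + rng.normal(0.0, scenario.noise_q, size=t.shape)
        freq[spec.mode_id] = f
        quality[spec.mode_id] = q

    return Measurement(
        time=t,
        temperature=temp,
        freq=freq,
        quality=quality,
        mode_ids=[m.mode_id for m in modes],
        dt=dt,
        truth=scenario,
        program=program,
    )
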