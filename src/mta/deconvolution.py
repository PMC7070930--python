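"""Deconvolution of modulated resonance-frequency traces.

Mirrors the reversing/non-reversing separation of modulated DSC, applied to
resonance-frequency data: a first-order Savitzky-Golay filter with a window
of one modulation period extracts the underlying (non-periodic) frequency
signal (UFS); subtracting it leaves the periodic part, whose upper envelope
is obtained from the magnitude of the Fourier-constructed analytic signal;
the reversing signal (RS) is that envelope normalized by the temperature
modulation envelope and the period,

    RS(t) = P_ue(t) / ( TS_ue(t) * P / (2*pi) ).

RS peaks wherever the frequency response per degree of modulation exceeds its
baseline, which localizes the glass transition independently of slow drifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import detrend, hilbert, savgol_filter

from .signal_simulator import Measurement

log = logging.getLogger(__name__)


class FlatSignalError(ValueError):
    """Raised when a trace has no periodic component to analyze."""


def period_window(P: float, dt: float) -> int:
    """Savitzky-Golay window: the odd sample count nearest one period P/dt."""
    if P <= 0 or dt <= 0:
        raise ValueError("P and dt must be positive")
    ratio = P / dt
    if ratio < 5:
        raise ValueError(f"period must span at least 5 samples, got P/dt={ratio:.2f}")
    w = int(round(ratio))
    if w % 2 == 0:
        w += 1 if ratio >= w else -1
    return max(w, 5)


def underlying_signal(raw: np.ndarray, P: float, dt: float) -> np.ndarray:
    """Non-periodic part of a modulated trace (first-order SG, one-period window).

    An order-1 fit preserves constants and linear ramps exactly while
    attenuating the period-P sinusoid to about 1% of its amplitude; endpoints
    are handled by polynomial edge fitting so output length equals input.
    """
    raw = np.asarray(raw, dtype=float)
    window = period_window(P, dt)
    if raw.size <= window:
        raise ValueError(
            f"series of {raw.size} samples is shorter than the {window}-sample filter window"
        )
    return savgol_filter(raw, window_length=window, polyorder=1, mode="interp")


def upper_envelope(periodic: np.ndarray, P: float, dt: float) -> np.ndarray:
    """Amplitude envelope of a zero-mean periodic trace.

    Magnitude of the analytic signal (Hilbert transform via FFT), smoothed
    with the same one-period first-order filter to suppress the residual
    ripple of the magnitude; non-negative by construction.
    """
    periodic = np.asarray(periodic, dtype=float)
    mag = np.abs(hilbert(periodic))
    window = period_window(P, dt)
    if mag.size <= window:
        return mag
    smoothed = savgol_filter(mag, window_length=window, polyorder=1, mode="interp")
    return np.maximum(smoothed, 0.0)


def reversing_signal(p_ue: np.ndarray, ts_ue: np.ndarray, P: float) -> np.ndarray:
    """Reversing signal: periodic-frequency envelope per unit temperature cycle.

    ``RS = P_ue / (TS_ue * P / (2*pi))`` elementwise.  Samples where the
    temperature envelope is non-positive are undefined and returned as NaN.
    """
    p_ue = np.asarray(p_ue, dtype=float)
    ts_ue = np.asarray(ts_ue, dtype=float)
    bad = ts_ue <= 0
    if bad.any():
        log.warning("reversing signal undefined at %d samples (TS_ue <= 0); masked", bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = p_ue / (ts_ue * P / (2 * np.pi))
    rs = np.where(bad, np.nan, rs)
    return rs


def dominant_period(raw: np.ndarray, dt: float, min_cycles: int = 10) -> float:
    """Frequency (Hz) of the dominant periodic component after detrend.

    Linear detrend, unit-variance normalization, Hann taper, FFT magnitude;
    returns the frequency of the largest magnitude among components that
    complete at least ``min_cycles`` over the record.  A component must
    repeat to count as periodic — bins below the cycle floor belong to
    residual drift (e.g. the glass-transition detuning step), whose leakage
    would otherwise mask the modulation line.  Used to verify that the
    applied modulation period transfers into the measured trace.
    """
    raw = np.asarray(raw, dtype=float)
    x = detrend(raw, type="linear")
    sd = x.std()
    if sd <= 1e-10 * max(1.0, float(np.max(np.abs(raw)))):
        raise FlatSignalError("trace has no periodic component (zero variance after detrend)")
    x = x / sd
    mag = np.abs(np.fft.rfft(x * np.hanning(x.size)))
    freqs = np.fft.rfftfreq(x.size, d=dt)
    k0 = min(max(min_cycles, 1), mag.size - 1)
    k = int(np.argmax(mag[k0:])) + k0
    return float(freqs[k])


@dataclass
class DeconvolutionResult:
    """Output of the full deconvolution chain for one tracked mode.

    ``raw == ufs + periodic`` holds exactly by construction.  The first and
    last ``edge_samples`` points carry filter/envelope edge artifacts and are
    flagged as unreliable; detectors ignore them.
    """

    time: np.ndarray
    temperature: np.ndarray
    raw: np.ndarray
    ufs: np.ndarray
    periodic: np.ndarray
    p_ue: np.ndarray
    ts_ue: np.ndarray
    rs: np.ndarray
    P: float
    dt: float
    edge_samples: int

    @property
    def interior(self) -> slice:
        """Slice selecting the samples not flagged as edge artifacts."""
        return slice(self.edge_samples, len(self.time) - self.edge_samples)


def deconvolve(
    measurement: Measurement, mode_id: str, P: Optional[float] = None
) -> DeconvolutionResult:
    """Run the full deconvolution chain on one tracked mode.

    UFS extraction on the frequency trace, subtraction to get the periodic
    part, envelope extraction on the periodic part and on the temperature
    modulation, then the reversing signal.  When ``P`` is not given it is
    inferred from the dominant spectral component of the raw trace.
    """
    if mode_id not in measurement.freq:
        raise KeyError(
            f"mode {mode_id!r} not in measurement (has {measurement.mode_ids})"
        )
    raw = np.asarray(measurement.freq[mode_id], dtype=float)
    dt = measurement.dt
    if P is None:
        P = 1.0 / dominant_period(raw, dt)
        log.info("inferred modulation period P=%.3f s from the trace spectrum", P)

    ufs = underlying_signal(raw, P, dt)
    periodic = raw - ufs
    p_ue = upper_envelope(periodic, P, dt)

    temp = np.asarray(measurement.temperature, dtype=float)
    ts_und = underlying_signal(temp, P, dt)
    ts_per = temp - ts_und
    ts_ue = upper_envelope(ts_per, P, dt)

    rs = reversing_signal(p_ue, ts_ue, P)
    edge = period_window(P, dt)
    return DeconvolutionResult(
        time=measurement.time,
        temperature=temp,
        raw=raw,
        ufs=ufs,
        periodic=periodic,
        p_ue=p_ue,
        ts_ue=ts_ue,
        rs=rs,
        P=P,
        dt=dt,
        edge_samples=edge,
    )
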