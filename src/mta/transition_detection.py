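"""Glass-transition detection from deconvolved MTA signals.

Two complementary signatures are located: Tg_F, the quasi-static onset seen
as the first prominent local maximum of the reversing signal (coinciding
with the initial slope change of the underlying frequency signal), and Tg_Q,
the liquefaction signature seen as a quality-factor minimum or, when the dip
is not pronounced, as the onset of the sharp Q rise.  Tg_Q is consistently
recorded a few degrees above Tg_F, reflecting the static/dynamic duality of
the glass transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .deconvolution import DeconvolutionResult, period_window


class NoTransitionError(ValueError):
    """Raised when a quality-factor trace shows no transition signature."""


DEFAULT_PROMINENCE_FRAC = 0.2


def _smooth_one_period(x: np.ndarray, P: float, dt: float) -> np.ndarray:
    w = period_window(P, dt)
    if x.size <= w:
        return np.asarray(x, dtype=float)
    return savgol_filter(np.asarray(x, dtype=float), w, 1, mode="interp")


def rs_maxima(
    rs: np.ndarray,
    temperature: np.ndarray,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    edge_samples: int = 0,
    min_width: Optional[int] = None,
) -> list[tuple[float, float]]:
    """Prominent local maxima of the reversing signal, ordered by temperature.

    A peak qualifies when its prominence is at least
    ``prominence_frac * (max(rs) - median(rs))`` over the interior samples
    (the first/last ``edge_samples`` are filter-artifact zones and excluded)
    and, when ``min_width`` is given, when it is at least that many samples
    wide at half prominence — the reversing signal cannot resolve features
    shorter than the modulation period, so narrower bumps are noise.
    The first listed maximum is Tg_F.  Returns ``[(temp_degC, prominence), ...]``;
    an empty list means no qualifying maximum.
    """
    rs = np.asarray(rs, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if rs.shape != temperature.shape:
        raise ValueError("rs and temperature must have equal length")
    sl = slice(edge_samples, rs.size - edge_samples if edge_samples else rs.size)
    x = rs[sl].copy()
    t = temperature[sl]
    if x.size < 3:
        return []
    finite = np.isfinite(x)
    if not finite.any():
        return []
    x[~finite] = np.nanmedian(x)
    span = np.nanmax(x) - np.nanmedian(x)
    if span <= 0:
        return []
    thresh = prominence_frac * span
    kwargs = {"prominence": thresh}
    if min_width:
        kwargs["width"] = min_width
        kwargs["rel_height"] = 0.5
    idx, props = find_peaks(x, **kwargs)
    order = np.argsort(t[idx])
    return [(float(t[idx[i]]), float(props["prominences"][i])) for i in order]


def quality_transition(
    quality: np.ndarray,
    temperature: np.ndarray,
    P: float = 20.0,
    dt: float = 0.2,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    edge_samples: int = 0,
) -> tuple[float, str]:
    """Locate Tg_Q in a quality-factor trace.

    The trace is smoothed with the standard one-period first-order filter.
    If a prominent local minimum exists its temperature is returned with
    method ``"minimum"``.  Otherwise — the dip is not always pronounced, but
    the shift toward higher Q at the transition always is — Tg_Q is taken as
    the intersection of the pre-rise baseline tangent with the maximum-slope
    tangent of the rise, method ``"rise-onset"``.
    """
    q = _smooth_one_period(np.asarray(quality, dtype=float), P, dt)
    temp = np.asarray(temperature, dtype=float)
    if q.shape != temp.shape:
        raise ValueError("quality and temperature must have equal length")
    sl = slice(edge_samples, q.size - edge_samples if edge_samples else q.size)
    q = q[sl]
    temp = temp[sl]

    span = q.max() - q.min()
    if span <= 0:
        raise NoTransitionError("flat quality-factor trace")
    idx, props = find_peaks(-q, prominence=prominence_frac * span)
    if idx.size:
        best = idx[int(np.argmax(props["prominences"]))]
        return float(temp[best]), "minimum"

    # no pronounced minimum: tangent construction on the rise
    dq = np.gradient(q, temp)
    k_max = int(np.argmax(dq))
    slope = dq[k_max]
    if slope <= 0:
        raise NoTransitionError("quality factor never rises: no transition signature")
    # pre-rise baseline: fit over samples before the rise carries 10% of its slope
    pre = np.nonzero(dq[:k_max] < 0.1 * slope)[0]
    if pre.size < 2:
        pre = np.arange(max(2, k_max // 4))
    a0, b0 = np.polyfit(temp[pre], q[pre], 1)
    # tangent at the max-slope point: q = q[k] + slope*(T - T[k])
    if slope - a0 <= 0:
        raise NoTransitionError("rise slope does not exceed the baseline slope")
    t_cross = ((q[k_max] - slope * temp[k_max]) - b0) / (a0 - slope)
    return float(t_cross), "rise-onset"


def ufs_onset_and_detuning(
    ufs: np.ndarray,
    temperature: np.ndarray,
    slope_change_frac: float = 0.5,
    baseline_frac: float = 0.25,
    edge_samples: int = 0,
) -> tuple[Optional[float], float]:
    """Onset of the UFS slope change and the maximum detuning.

    The onset is the classical tangent construction of thermal analysis:
    the pre-transition baseline line (fit over the first ``baseline_frac``
    of the samples) intersected with the tangent at the point of strongest
    slope deviation.  Delta-f is the maximum absolute deviation of the UFS
    from the extrapolated baseline.  When the strongest local slope deviates
    from the baseline slope by less than ``slope_change_frac * |baseline
    slope|`` (plus a noise floor) no pronounced detuning is present and the
    onset is reported absent (None), with the deviation still returned.
    """
    y = np.asarray(ufs, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if y.shape != t.shape:
        raise ValueError("ufs and temperature must have equal length")
    sl = slice(edge_samples, y.size - edge_samples if edge_samples else y.size)
    y = y[sl]
    t = t[sl]
    n = y.size
    if n < 10:
        raise ValueError("too few samples for onset detection")

    # local slope series; a moderate smoothing window keeps derivative noise
    # well below the baseline slope without flattening the transition
    w = min(max(5, (n // 30) | 1), n - 1 if (n - 1) % 2 else n - 2)
    dt_samp = float(np.median(np.diff(t)))
    dy = savgol_filter(y, w, 1, deriv=1, delta=dt_samp, mode="interp")

    n_base = max(3, int(baseline_frac * n))
    a0, b0 = np.polyfit(t[:n_base], y[:n_base], 1)
    dev_line = y - (a0 * t + b0)
    delta_f = float(np.max(np.abs(dev_line)))

    slope_dev = dy - a0
    k_max = int(np.argmax(np.abs(slope_dev)))
    noise_floor = 5.0 * float(np.median(np.abs(slope_dev[:n_base] - np.median(slope_dev[:n_base])))) + 1e-12
    if np.abs(slope_dev[k_max]) < max(slope_change_frac * abs(a0), noise_floor):
        return None, delta_f

    # tangent at the max-slope-deviation point intersected with the baseline
    slope = dy[k_max]
    t_onset = (y[k_max] - slope * t[k_max] - b0) / (a0 - slope)
    return float(t_onset), delta_f


@dataclass
class TgReport:
    """Assembled glass-transition report for one measurement/mode."""

    tg_f: Optional[float]                      # degC, first RS maximum
    rs_maxima: list[tuple[float, float]]       # (degC, prominence), by temperature
    tg_q: Optional[float]                      # degC
    tg_q_method: Optional[str]                 # "minimum" | "rise-onset"
    ufs_onset: Optional[float]                 # degC
    delta_qf: Optional[float]                  # degC, tg_q - tg_f
    detuning: float                            # Hz, max deviation from pre-transition line
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tg_f_C": self.tg_f,
            "rs_maxima": [{"temp_C": t, "prominence": p} for t, p in self.rs_maxima],
            "tg_q_C": self.tg_q,
            "tg_q_method": self.tg_q_method,
            "ufs_onset_C": self.ufs_onset,
            "delta_qf_C": self.delta_qf,
            "detuning_Hz": self.detuning,
            "flags": list(self.flags),
        }


def build_report(
    deconv: DeconvolutionResult,
    quality: np.ndarray,
    temperature: Optional[np.ndarray] = None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> TgReport:
    """Run all detectors on one deconvolved mode and assemble the report."""
    temp = np.asarray(
        deconv.temperature if temperature is None else temperature, dtype=float
    )
    edge = deconv.edge_samples
    maxima = rs_maxima(
        deconv.rs, temp, prominence_frac,
        edge_samples=edge, min_width=period_window(deconv.P, deconv.dt),
    )
    flags: list[str] = []
    tg_f = maxima[0][0] if maxima else None
    if not maxima:
        flags.append("no-rs-maximum")
    elif len(maxima) > 1:
        flags.append("multiple-maxima")

    try:
        tg_q, method = quality_transition(
            quality, temp, deconv.P, deconv.dt,
            prominence_frac=prominence_frac, edge_samples=edge,
        )
    except NoTransitionError:
        tg_q, method = None, None
        flags.append("no-q-transition")

    onset, delta_f = ufs_onset_and_detuning(deconv.ufs, temp, edge_samples=edge)
    if onset is None:
        flags.append("no-pronounced-detuning")

    delta_qf = (tg_q - tg_f) if (tg_q is not None and tg_f is not None) else None
    # a distant second maximum with no matching Q feature can indicate a
    # prominent-mode switch; flagged, never interpreted
    if len(maxima) > 1 and tg_q is not None:
        if all(abs(t - tg_q) > 2.0 for t, _ in maxima[1:]):
            flags.append("mode-switch-suspected")
    return TgReport(
        tg_f=tg_f,
        rs_maxima=maxima,
        tg_q=tg_q,
        tg_q_method=method,
        ufs_onset=onset,
        delta_qf=delta_qf,
        detuning=delta_f,
        flags=flags,
    )
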