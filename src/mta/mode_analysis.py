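"""Mode-shape classification and prominent-mode bookkeeping.

Grid-overlay vibrometer measurements sample the complex vibrational
amplitude on a coarse grid over the string.  The harmonic order of a mode
is read off the number of sign changes of its width-averaged real profile
along the string; significant asymmetry between width rows marks torsional
involvement ("mixed" modes, which couple more strongly to a deposited
sample).  The prominent mode in a frequency band is simply the registered
mode nearest the highest spectral magnitude in that band; persistent
changes of the prominent label through the glass transition are reported as
mode switches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

MIXEDNESS_THRESHOLD = 0.3
DEBOUNCE_N = 3


@dataclass(frozen=True)
class ModeGrid:
    """Spatial amplitude grid of one resonance mode.

    ``points`` holds (x, y) as fractions of string length / width;
    ``amplitudes`` the complex vibrational amplitude at each point.
    """

    points: np.ndarray        # (n, 2) fractions
    amplitudes: np.ndarray    # (n,) complex
    frequency: float          # Hz

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=complex)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of fractions")
        if amps.shape != (pts.shape[0],):
            raise ValueError("one complex amplitude per grid point required")
        if pts.shape[0] < 6:
            raise ValueError("need at least 6 grid points")
        if not np.all(np.isfinite(amps)):
            raise ValueError("amplitudes must be finite")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "amplitudes", amps)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ModeLabel:
    harmonic: int
    torsional: bool
    descriptor: str                     # "flexural" | "mixed"
    torsional_indeterminate: bool = False

    def __post_init__(self) -> None:
        expected = "mixed" if self.torsional else "flexural"
        if self.descriptor != expected:
            raise ValueError("descriptor must be 'mixed' iff the torsional flag is set")


def _align_phase(amps: np.ndarray) -> np.ndarray:
    """Rotate a complex mode shape to the real axis (global-phase invariant)."""
    z2 = np.sum(amps**2)
    if abs(z2) == 0:
        return amps.real
    phi = 0.5 * np.angle(z2)
    rotated = amps * np.exp(-1j * phi)
    # fix the sign convention so results don't flip with the +-pi ambiguity
    if rotated.real[np.argmax(np.abs(rotated.real))] < 0:
        rotated = -rotated
    return rotated.real


def classify_mode(grid: ModeGrid, mixedness_threshold: float = MIXEDNESS_THRESHOLD) -> ModeLabel:
    """Classify a grid-overlay mode shape.

    Harmonic order = 1 + number of sign changes of the width-averaged real
    amplitude along the string (near-zero samples below 5% of the peak are
    ignored as noise).  The torsional flag is set when the largest
    normalized amplitude difference between width rows exceeds
    ``mixedness_threshold``; with a single width row torsional involvement
    cannot be assessed and is flagged indeterminate.
    """
    real = _align_phase(grid.amplitudes)
    x = grid.points[:, 0]
    y = grid.points[:, 1]
    xs = np.unique(np.round(x, 9))
    profile = np.array([real[np.isclose(x, xv)].mean() for xv in xs])

    peak = np.max(np.abs(profile))
    if peak == 0:
        raise ValueError("flat mode shape: cannot classify")
    signs = np.sign(profile[np.abs(profile) > 0.05 * peak])
    sign_changes = int(np.sum(signs[1:] != signs[:-1]))
    harmonic = 1 + sign_changes

    rows = np.unique(np.round(y, 9))
    if rows.size < 2:
        return ModeLabel(harmonic=harmonic, torsional=False, descriptor="flexural",
                         torsional_indeterminate=True)
    amax = np.max(np.abs(real))
    max_diff = 0.0
    for xv in xs:
        at_x = real[np.isclose(x, xv)]
        if at_x.size >= 2:
            max_diff = max(max_diff, float(at_x.max() - at_x.min()))
    torsional = bool(max_diff > mixedness_threshold * amax)
    return ModeLabel(
        harmonic=harmonic,
        torsional=torsional,
        descriptor="mixed" if torsional else "flexural",
    )


def prominent_mode(
    spectrum: Sequence[tuple[float, float]],
    band: tuple[float, float],
    mode_freqs: Mapping[str, float],
) -> str:
    """Mode of highest spectral magnitude within a frequency band.

    ``spectrum`` is an iterable of (frequency_Hz, magnitude) pairs; the peak
    within ``band`` is matched to the nearest registered mode frequency.
    """
    lo, hi = band
    if not hi > lo:
        raise ValueError(f"band ({lo}, {hi}) Hz is empty")
    in_band = [(f, m) for f, m in spectrum if lo <= f <= hi]
    if not in_band:
        raise ValueError(f"no spectral points inside the band ({lo}, {hi}) Hz")
    if not mode_freqs:
        raise ValueError("no registered modes to match against")
    f_peak, _ = max(in_band, key=lambda fm: fm[1])
    return min(mode_freqs, key=lambda mid: abs(mode_freqs[mid] - f_peak))


def detect_mode_switches(
    labels: Sequence[str], debounce_n: int = DEBOUNCE_N
) -> list[int]:
    """Indices where the prominent-mode label changes persistently.

    A change only counts when the new label holds for at least
    ``debounce_n`` consecutive samples, which suppresses flicker near
    magnitude crossings.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    if debounce_n < 1:
        raise ValueError("debounce_n must be >= 1")
    switches: list[int] = []
    current = labels[0]
    i = 1
    while i < len(labels):
        if labels[i] != current:
            run = labels[i : i + debounce_n]
            if len(run) == debounce_n and all(l == labels[i] for l in run):
                switches.append(i)
                current = labels[i]
                i += debounce_n
                continue
        i += 1
    return switches


def local_responsivity(x: float, n: int) -> float:
    """Normalized local mass responsivity of harmonic ``n`` at position ``x``.

    Scales with the square of the local vibrational amplitude: sin^2(n*pi*x).
    Maximal at antinodes, zero at nodes, symmetric about the string center.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("position must be a fraction of string length in [0, 1]")
    if n < 1:
        raise ValueError("harmonic index must be >= 1")
    return float(np.sin(n * np.pi * x) ** 2)


def make_grid(
    harmonic: int,
    torsion: float = 0.0,
    nx: int = 23,
    ny: int = 3,
    frequency: float = 163_000.0,
    phase: float = 0.0,
    scale: float = 1.0,
) -> ModeGrid:
    """Sample an idealized string mode shape on a regular overlay grid.

    The flexural profile is ``sin(harmonic*pi*x)``; ``torsion`` adds an
    antisymmetric across-width weighting ``1 + torsion*(2y - 1)`` that
    emulates the torsional involvement of mixed modes.
    """
    x = np.linspace(0.0, 1.0, nx + 2)[1:-1]  # interior points, clamped ends excluded
    y = np.linspace(0.0, 1.0, ny) if ny > 1 else np.array([0.5])
    xx, yy = np.meshgrid(x, y, indexing="ij")
    shape = np.sin(harmonic * np.pi * xx) * (1.0 + torsion * (2.0 * yy - 1.0))
    amps = scale * shape.ravel() * np.exp(1j * phase)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return ModeGrid(points=pts, amplitudes=amps, frequency=frequency)
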