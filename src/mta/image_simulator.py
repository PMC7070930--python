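"""Synthetic microscope frames of sample particles on a microstring.

Renders 8-bit grayscale frame stacks in which each particle is an
anti-aliased bright disk whose projected area first shrinks slightly
(relaxation/densification) and then spreads well past its initial size
(liquefaction) as temperature crosses the glass transition.  Larger
particles need longer to heat through, so their transition lags in
proportion to diameter — reproducing the size ordering of image-analysis
minima relative to the quality-factor response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameParticle:
    """One rendered particle: center in px, physical diameter, peak gray level."""

    cx: float
    cy: float
    diameter: float       # um
    brightness: int = 200


@dataclass(frozen=True)
class FrameScenario:
    """Rendering configuration for a synthetic particle movie.

    ``shrink_frac`` is the fractional 2D-area loss before spreading,
    ``spread_frac`` the fractional gain after liquefaction, and
    ``lag_per_um`` the heating lag in degC per um of particle diameter.
    """

    width: int = 512
    height: int = 128
    px_per_um: float = 1.5
    particles: tuple[FrameParticle, ...] = ()
    shrink_frac: float = 0.05
    spread_frac: float = 0.6
    lag_per_um: float = 0.2
    tg_dynamic: float = 50.0
    shrink_lead: float = 6.0     # degC the shrinkage precedes the spread
    shrink_width: float = 1.0    # degC
    spread_width: float = 0.75   # degC
    background: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.shrink_frac < 1:
            raise ValueError("shrink_frac must be in (0, 1)")
        if self.spread_frac <= 0:
            raise ValueError("spread_frac must be positive")
        for p in self.particles:
            if p.diameter <= 0:
                raise ValueError("particle diameters must be positive")
            if p.brightness <= self.background:
                raise ValueError("particle brightness must exceed the background")


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def area_factor(scenario: FrameScenario, theta) -> np.ndarray:
    """Relative 2D area of a particle vs lag-shifted temperature ``theta``.

    ``theta = T - tg_dynamic - lag_per_um * diameter``.  The factor dips by
    ``shrink_frac`` ahead of the transition, then recovers and overshoots to
    ``1 + spread_frac`` as the particle liquefies and wets the string.
    """
    theta = np.asarray(theta, dtype=float)
    s = scenario
    shrink = s.shrink_frac * _logistic((theta + s.shrink_lead) / s.shrink_width)
    spread = (s.shrink_frac + s.spread_frac) * _logistic(theta / s.spread_width)
    return 1.0 - shrink + spread


def _render_disk(frame: np.ndarray, cx: float, cy: float, r: float, peak: float) -> None:
    """Additively render one anti-aliased disk (coverage-weighted gray)."""
    h, w = frame.shape
    x0 = max(int(np.floor(cx - r - 1)), 0)
    x1 = min(int(np.ceil(cx + r + 2)), w)
    y0 = max(int(np.floor(cy - r - 1)), 0)
    y1 = min(int(np.ceil(cy + r + 2)), h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
    patch = frame[y0:y1, x0:x1]
    np.maximum(patch, peak * coverage, out=patch)


def render_frames(
    scenario: FrameScenario, temperature: Sequence[float]
) -> np.ndarray:
    """Render one 8-bit grayscale frame per temperature sample.

    Returns an array of shape ``(n_frames, height, width)``, dtype uint8.
    Particle radii follow ``sqrt(area_factor)``; particles reaching outside
    the frame are clipped with a warning.
    """
    temperature = np.asarray(temperature, dtype=float)
    if temperature.ndim != 1 or temperature.size < 1:
        raise ValueError("temperature must be a non-empty 1-D series")
    s = scenario
    stack = np.empty((temperature.size, s.height, s.width), dtype=np.uint8)
    max_spread = np.sqrt(1.0 + s.spread_frac)
    for p in s.particles:
        r_max = 0.5 * p.diameter * s.px_per_um * max_spread
        if (p.cx - r_max < 0 or p.cx + r_max > s.width
                or p.cy - r_max < 0 or p.cy + r_max > s.height):
            log.warning(
                "particle at (%.0f, %.0f) px may extend outside the %dx%d frame; clipped",
                p.cx, p.cy, s.width, s.height,
            )
    for i, temp in enumerate(temperature):
        frame = np.full((s.height, s.width), float(s.background))
        for p in s.particles:
            theta = temp - s.tg_dynamic - s.lag_per_um * p.diameter
            r = 0.5 * p.diameter * s.px_per_um * np.sqrt(area_factor(s, theta))
            peak = s.background + (p.brightness - s.background)
            _render_disk(frame, p.cx, p.cy, float(r), float(peak))
        stack[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    return stack


def default_frame_scenario(seed: int = 0, n_particles: int = 5) -> FrameScenario:
    """Random particle layout emulating the inertial-impaction sampling.

    Particles of 2-25 um diameter land predominantly between 1/4 and 3/4 of
    the string length; one particle per horizontal slot keeps the rendered
    disks from merging so that contour levels stay well defined.
    """
    rng = np.random.default_rng(seed)
    width, height, px_per_um = 512, 128, 1.5
    lo, hi = 0.25 * width, 0.75 * width
    slot_w = (hi - lo) / n_particles
    particles = []
    for i in range(n_particles):
        d = float(rng.uniform(2.0, 25.0))
        r_px = 0.5 * d * px_per_um * np.sqrt(1.6)  # fully spread radius
        margin = r_px + 2
        cx = lo + i * slot_w + float(rng.uniform(margin, max(slot_w - margin, margin + 1e-6)))
        cy = float(rng.uniform(margin, height - margin))
        particles.append(FrameParticle(cx=cx, cy=cy, diameter=d,
                                       brightness=int(rng.integers(180, 240))))
    return FrameScenario(particles=tuple(particles), seed=seed)
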