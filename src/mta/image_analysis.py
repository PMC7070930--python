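"""Multi-level contour analysis of particle movies.

Particles on the string are segmented from 8-bit grayscale frames at a
fixed intensity threshold and assigned to three contour levels by their
equivalent diameter (below 5 um, 5-10 um, above 10 um).  The pixel area
enclosed by each level's contours is tracked across the stack and smoothed
with the standard one-period first-order filter; the temperature of each
level's area minimum marks the crossover from particle shrinkage to
liquefaction-driven spreading, which approaches the quality-factor response
more closely the smaller the particles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .deconvolution import period_window
from scipy.signal import savgol_filter

DEFAULT_LEVEL_EDGES = (5.0, 10.0)  # um; levels are [0,5), [5,10), [10,inf)


def segmentation_threshold(frame: np.ndarray) -> float:
    """Fixed intensity threshold: background + 0.5*(median foreground - background).

    The background is the median gray level of the frame (particles are
    sparse); the foreground population is split off with Otsu's method on
    the first frame.  A featureless frame yields a threshold above its
    maximum, i.e. empty masks.
    """
    frame = np.asarray(frame)
    bg = float(np.median(frame))
    if frame.max() <= bg + 1:
        return float(frame.max()) + 1.0
    otsu = threshold_otsu(frame)
    fg = frame[frame > otsu]
    if fg.size == 0:
        return float(frame.max()) + 1.0
    med_fg = float(np.median(fg))
    return bg + 0.5 * (med_fg - bg)


def contour_levels(
    frame: np.ndarray,
    px_per_um: float,
    threshold: Optional[float] = None,
    level_edges: Sequence[float] = DEFAULT_LEVEL_EDGES,
) -> list[np.ndarray]:
    """Per-level boolean particle masks for one frame.

    Connected components of the thresholded foreground are hole-filled and
    assigned to a level by equivalent diameter ``2*sqrt(area/pi)/px_per_um``
    against half-open bins ``[0, e1), [e1, e2), [e2, inf)``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a single-channel 2-D image")
    if threshold is None:
        threshold = segmentation_threshold(frame)
    mask = ndimage.binary_fill_holes(frame > threshold)
    labels = label(mask)
    edges = [0.0, *level_edges, np.inf]
    masks = [np.zeros(frame.shape, dtype=bool) for _ in range(len(edges) - 1)]
    for region in regionprops(labels):
        d_um = 2.0 * np.sqrt(region.area / np.pi) / px_per_um
        for lev in range(len(masks)):
            if edges[lev] <= d_um < edges[lev + 1]:
                masks[lev][labels == region.label] = True
                break
    return masks


@dataclass
class ContourResult:
    """Per-level pixel-area tracking result for a frame stack."""

    level_edges: tuple[float, ...]
    areas_raw: np.ndarray        # (n_levels, n_frames) raw pixel counts
    areas: np.ndarray            # (n_levels, n_frames) one-period-smoothed
    px_per_um: float
    minima: Optional[list[Optional[tuple[int, float]]]] = None  # (frame, degC) per level

    @property
    def n_levels(self) -> int:
        return self.areas.shape[0]


def track_levels(
    frames: np.ndarray,
    px_per_um: float,
    P: float,
    dt: float,
    level_edges: Sequence[float] = DEFAULT_LEVEL_EDGES,
) -> ContourResult:
    """Track per-level enclosed pixel areas across a frame stack.

    Level detection happens once, on the first frame: the segmentation
    threshold and each particle's size class are fixed there.  In later
    frames every foreground component inherits the class of the first-frame
    component it overlaps, so a particle that spreads past a class edge
    during liquefaction keeps contributing to its own size class (re-binning
    per frame would let it migrate mid-transition and corrupt the series);
    components with no first-frame counterpart are classified by their own
    equivalent diameter.  The per-level series are smoothed with the
    one-period first-order filter when the stack is long enough; ``dt`` here
    is the frame interval.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least two single-channel frames")
    thresh = segmentation_threshold(frames[0])
    n_levels = len(level_edges) + 1
    ref_masks = contour_levels(frames[0], px_per_um, thresh, level_edges)
    areas = np.zeros((n_levels, frames.shape[0]))
    edges = [0.0, *level_edges, np.inf]
    for i, frame in enumerate(frames):
        fg = ndimage.binary_fill_holes(frame > thresh)
        labels = label(fg)
        for region in regionprops(labels):
            member = labels == region.label
            overlaps = [np.count_nonzero(member & ref) for ref in ref_masks]
            if any(overlaps):
                lev = int(np.argmax(overlaps))
            else:
                d_um = 2.0 * np.sqrt(region.area / np.pi) / px_per_um
                lev = next(
                    j for j in range(n_levels) if edges[j] <= d_um < edges[j + 1]
                )
            areas[lev, i] += region.area
    try:
        w = period_window(P, dt)
    except ValueError:
        w = 0
    if w and frames.shape[0] > w:
        smoothed = savgol_filter(areas, w, 1, axis=1, mode="interp")
    else:
        smoothed = areas.copy()
    return ContourResult(
        level_edges=tuple(level_edges),
        areas_raw=areas,
        areas=np.maximum(smoothed, 0.0),
        px_per_um=px_per_um,
    )


def area_minima(
    result: ContourResult,
    temperature: Sequence[float],
    central_frac: float = 0.9,
) -> list[Optional[tuple[int, float]]]:
    """Temperature of each level's global area minimum.

    The minimum is searched in the central window (edge frames carry filter
    artifacts); a level whose smoothed series is monotone — or empty — has
    no shrink-to-spread crossover and reports ``None``.  The result list is
    also stored on ``result.minima``.
    """
    temperature = np.asarray(temperature, dtype=float)
    n = result.areas.shape[1]
    if temperature.size != n:
        raise ValueError("temperature series must have one entry per frame")
    margin = max(1, int((1 - central_frac) / 2 * n))
    out: list[Optional[tuple[int, float]]] = []
    for series in result.areas:
        if series.max() == 0:
            out.append(None)
            continue
        d = np.diff(series)
        if np.all(d >= 0) or np.all(d <= 0):
            out.append(None)
            continue
        window = series[margin : n - margin]
        k = margin + int(np.argmin(window))
        # a "minimum" sitting on the window edge is just a monotone tail
        if k in (margin, n - margin - 1):
            out.append(None)
            continue
        out.append((k, float(temperature[k])))
    result.minima = out
    return out
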