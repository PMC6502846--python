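"""Pore detection by normalised 2D cross-correlation template matching.

A complete-pore template is slid over each frame; the zero-mean,
unit-energy (Pearson) correlation is computed in the valid overlap region,
so a score of 1 means a perfect contrast-invariant match and features
closer than half a template width to the border are never reported.
Local maxima above the detection threshold (default 0.6) survive
non-maximum suppression with an exclusion radius of half the template
width; ties at equal score are broken in raster order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .movie import MovieStack
from .synthetic import N_SUBUNITS, PoreGeometry, make_template, _render_feature

__all__ = [
    "Detection",
    "detect_pores",
    "count_pores",
    "detect_movie",
    "detectable_subunit_count",
    "first_detectable_frame",
]


@dataclass(frozen=True)
class Detection:
    """One template match: frame index, pixel-centre coordinates, score."""

    frame_index: int
    row: int
    col: int
    score: float

    @property
    def position(self) -> tuple[int, int]:
        return (self.row, self.col)


def _correlation_map(frame: np.ndarray, template: np.ndarray) -> np.ndarray:
    if template.shape[0] > frame.shape[0] or template.shape[1] > frame.shape[1]:
        raise ValueError("template larger than frame")
    corr = match_template(np.asarray(frame, float), np.asarray(template, float))
    return np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)


def detect_pores(
    frame: np.ndarray,
    template: np.ndarray,
    threshold: float = 0.6,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect pores in one frame.

    Returns detections sorted by descending score (raster order on ties),
    with coordinates of the feature centre in the full-frame pixel grid.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    corr = _correlation_map(frame, template)
    half = template.shape[0] // 2
    excl = max(half, 1)

    above = np.argwhere(corr >= threshold)
    if above.size == 0:
        return []
    # stable order: score descending, then raster (row, col)
    scores = corr[above[:, 0], above[:, 1]]
    order = np.lexsort((above[:, 1], above[:, 0], -scores))
    accepted: list[tuple[int, int, float]] = []
    for idx in order:
        r, c = above[idx]
        s = scores[idx]
        if all((r - ar) ** 2 + (c - ac) ** 2 >= excl**2 for ar, ac, _ in accepted):
            accepted.append((int(r), int(c), float(s)))
    return [
        Detection(frame_index, r + half, c + template.shape[1] // 2, s)
        for r, c, s in accepted
    ]


def count_pores(
    movie: MovieStack, template: np.ndarray, threshold: float = 0.6
) -> np.ndarray:
    """Number of detected pores in each frame."""
    return np.array(
        [
            len(detect_pores(movie.frames[k], template, threshold, frame_index=k))
            for k in range(movie.n_frames)
        ]
    )


def detect_movie(
    movie: MovieStack, template: np.ndarray, threshold: float = 0.6
) -> list[list[Detection]]:
    """Per-frame detection lists for the whole movie."""
    return [
        detect_pores(movie.frames[k], template, threshold, frame_index=k)
        for k in range(movie.n_frames)
    ]


def detectable_subunit_count(
    geometry: PoreGeometry,
    pixel_size: float,
    threshold: float = 0.6,
    smooth_fwhm_px: float | None = None,
) -> int:
    """Smallest subunit count whose rendered arc is detectable.

    A growing pore only correlates with the complete-ring template above
    the threshold once its arc is long enough; this measures that
    detectability fraction on noiseless renders rather than asserting a
    fixed count.  Returns ``N_SUBUNITS + 1`` if even the complete ring
    falls below the threshold (pathological template/threshold choices).
    """
    template = make_template(geometry, pixel_size, smooth_fwhm_px=smooth_fwhm_px)
    side = template.shape[0]
    for n in range(1, N_SUBUNITS + 1):
        frame = np.zeros((3 * side, 3 * side), dtype=np.float32)
        center = ((3 * side - 1) / 2, (3 * side - 1) / 2)
        _render_feature(frame, center, geometry, pixel_size, n, theta0=0.0)
        if smooth_fwhm_px:
            from .preprocess import gaussian_smooth

            frame = gaussian_smooth(frame, fwhm_px=smooth_fwhm_px)
        if _correlation_map(frame, template).max() >= threshold:
            return n
    return N_SUBUNITS + 1


def first_detectable_frame(
    trajectory,
    geometry: PoreGeometry,
    frame_times: np.ndarray,
    pixel_size: float,
    template: np.ndarray,
    threshold: float = 0.6,
    smooth_fwhm_px: float | None = None,
) -> int | None:
    """Ground-truth first frame at which one pore's render is detectable.

    Renders the pore in isolation — at its actual subpixel offset and
    growth-start angle — for each frame state and runs the detector, so
    per-pore variation in detectability (arc orientation, pixel phase) is
    accounted for exactly.  Returns None if the pore never becomes
    detectable within the movie.
    """
    side = template.shape[0]
    pad = 2 * side
    px = np.asarray(trajectory.position) / pixel_size
    frac = px - np.floor(px)
    center = (pad + frac[0], pad + frac[1])
    prev_n = -1
    for k, t in enumerate(np.asarray(frame_times)):
        n = trajectory.subunit_count(t)
        if n == 0:
            continue
        if n == prev_n:
            continue  # same rendered state: same correlation, same outcome
        prev_n = n
        frame = np.zeros((2 * pad + side, 2 * pad + side), dtype=np.float32)
        _render_feature(frame, center, geometry, pixel_size, n, trajectory.theta0)
        if smooth_fwhm_px:
            from .preprocess import gaussian_smooth

            frame = gaussian_smooth(frame, fwhm_px=smooth_fwhm_px)
        if detect_pores(frame, template, threshold):
            return k
    return None
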