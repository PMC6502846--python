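"""AFM image conditioning: plane subtraction, line flattening, smoothing.

Raw AFM height maps carry a first-order background tilt (scanner/sample
misalignment), per-scan-line offsets (feedback drift) and high-frequency
noise.  The conditioning chain applied here — least-squares plane
subtraction, then line-by-line flattening referenced to the lipid bilayer,
then an isotropic Gaussian of 2 px FWHM — mirrors standard AFM practice
for supported-bilayer movies.

The bilayer reference for flattening is selected automatically: pixels
below ``median + 3*MAD`` of the frame are treated as background, which
keeps protruding pores (10+ nm above a sub-nm-noise bilayer) out of the
per-line statistic.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .movie import MovieStack

__all__ = [
    "plane_level",
    "line_flatten",
    "gaussian_smooth",
    "background_mask",
    "preprocess_movie",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


def plane_level(frame: np.ndarray, background_mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the least-squares plane a*x + b*y + c.

    The plane is fitted to all pixels, or to ``background_mask`` (True =
    background) when given so that tall features do not bias the fit.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    rows, cols = frame.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    if background_mask is None:
        sel = np.ones(frame.shape, dtype=bool)
    else:
        sel = np.asarray(background_mask, dtype=bool)
        if sel.shape != frame.shape:
            raise ValueError("mask shape must match frame")
    if sel.sum() < 3:
        raise ValueError("need >= 3 background pixels to fit a plane")
    design = np.column_stack([xx[sel], yy[sel], np.ones(sel.sum())])
    # rank < 3 means the selected pixels are collinear (e.g. a single row)
    coef, _, rank, _ = np.linalg.lstsq(design, frame[sel], rcond=None)
    if rank < 3:
        raise ValueError("degenerate frame: background pixels are collinear")
    return frame - (coef[0] * xx + coef[1] * yy + coef[2])


def line_flatten(frame: np.ndarray, feature_mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the per-scan-line median of background pixels.

    ``feature_mask`` marks pixels to exclude (True = feature).  A line
    whose pixels are all masked inherits the previous line's offset (zero
    for the first line) rather than failing.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if feature_mask is None:
        feature_mask = np.zeros(frame.shape, dtype=bool)
    feature_mask = np.asarray(feature_mask, dtype=bool)
    out = frame.copy()
    prev_offset = 0.0
    for i in range(frame.shape[0]):
        bg = frame[i][~feature_mask[i]]
        offset = float(np.median(bg)) if bg.size else prev_offset
        out[i] -= offset
        prev_offset = offset
    return out


def gaussian_smooth(frame: np.ndarray, fwhm_px: float = 2.0) -> np.ndarray:
    """Isotropic Gaussian smoothing specified by its full width half maximum.

    Reflect padding at the borders avoids the edge dimming that would
    otherwise bias average-height traces of pores near the frame edge.
    """
    if fwhm_px <= 0:
        raise ValueError("fwhm_px must be > 0")
    return gaussian_filter(
        np.asarray(frame, dtype=float), sigma=fwhm_px * FWHM_TO_SIGMA, mode="reflect"
    )


def background_mask(frame: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """True where a pixel belongs to the bilayer background.

    Pixels above ``median + n_mad * MAD`` are treated as features.  With
    zero noise (MAD = 0) anything strictly above the median is a feature,
    which is the right limit for noiseless synthetic frames.
    """
    frame = np.asarray(frame, dtype=float)
    med = np.median(frame)
    mad = np.median(np.abs(frame - med))
    return frame <= med + n_mad * mad


def preprocess_movie(
    movie: MovieStack,
    fwhm_px: float = 2.0,
    n_mad: float = 3.0,
    smooth: bool = True,
) -> MovieStack:
    """Apply plane_level -> line_flatten -> gaussian_smooth to every frame.

    Pure: returns a new MovieStack with identical metadata.  The feature
    mask for both the plane fit and the flattening is re-estimated per
    frame from the raw heights.
    """
    out = movie.copy()
    for k in range(movie.n_frames):
        frame = movie.frames[k]
        bg = background_mask(frame, n_mad=n_mad)
        frame = plane_level(frame, background_mask=bg)
        frame = line_flatten(frame, feature_mask=~bg)
        if smooth:
            frame = gaussian_smooth(frame, fwhm_px=fwhm_px)
        out.frames[k] = frame
    return out
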