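"""Linking detections into per-pore tracks, cropping, and height traces.

Detections are linked frame-to-frame by greedy nearest-neighbour
assignment: a detection joins an existing track iff it lies within the
maximum linking distance of the track's last position and within the
maximum gap (frames of permitted absence) of its last detection;
otherwise it starts a new track.  Each detection belongs to exactly one
track and the assignment is deterministic (smallest distance first, ties
in raster order).

For each track a square sub-movie of radius 25 nm around the pore is
cropped, including a few frames before first appearance, and the mean
height of every cropped frame forms the track's height trace — the proxy
for pore completeness that the sigmoid transition fit consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Detection
from .movie import MovieStack

__all__ = [
    "PoreTrack",
    "CroppedSequence",
    "HeightTrace",
    "link_tracks",
    "filter_tracks",
    "crop_track",
    "height_trace",
]


@dataclass
class PoreTrack:
    """Linked detections of one pore across frames."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self):
        frames = [d.frame_index for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("detections must have strictly increasing frame indices")

    @property
    def birth_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.detections[-1].frame_index

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def positions(self) -> np.ndarray:
        return np.array([[d.row, d.col] for d in self.detections], dtype=float)

    @property
    def pre_existing(self) -> bool:
        """True when the pore was already present in frame 0."""
        return self.birth_frame == 0

    @property
    def median_position(self) -> tuple[int, int]:
        med = np.median(self.positions, axis=0)
        return (int(round(med[0])), int(round(med[1])))


def link_tracks(
    detections_by_frame: list[list[Detection]],
    max_link_dist_px: float = 30.0,
    max_gap_frames: int = 3,
) -> list[PoreTrack]:
    """Greedy frame-order linking of detections into tracks.

    A track may be absent for up to ``max_gap_frames`` consecutive frames
    and still be continued (gap closing); one frame longer and a
    re-appearing detection starts a new track.
    """
    tracks: list[PoreTrack] = []
    open_tracks: list[PoreTrack] = []
    next_id = 0
    for frame_dets in detections_by_frame:
        if not frame_dets:
            continue
        frame_index = frame_dets[0].frame_index
        # raster order for deterministic tie-breaks
        dets = sorted(frame_dets, key=lambda d: (d.row, d.col))
        open_tracks = [
            t for t in open_tracks
            if frame_index - t.last_frame - 1 <= max_gap_frames
        ]
        # candidate (distance, track raster order, det order) pairs
        pairs = []
        for ti, track in enumerate(open_tracks):
            last = np.array(track.detections[-1].position, dtype=float)
            for di, det in enumerate(dets):
                dist = float(np.hypot(det.row - last[0], det.col - last[1]))
                if dist <= max_link_dist_px:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            open_tracks[ti].detections.append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)
        for di, det in enumerate(dets):
            if di not in used_dets:
                track = PoreTrack(next_id, [det])
                next_id += 1
                tracks.append(track)
                open_tracks.append(track)
    return tracks


def filter_tracks(tracks: list[PoreTrack], min_detections: int = 3) -> list[PoreTrack]:
    """Automated stand-in for manual false-positive curation.

    Tracks supported by fewer than ``min_detections`` detections are
    discarded (noise-induced spurious matches rarely persist); everything
    else is kept.
    """
    return [t for t in tracks if t.n_detections >= min_detections]


@dataclass
class CroppedSequence:
    """Square sub-movie centred on one track."""

    track_id: int
    frames: np.ndarray  # (n, side, side) nm
    times: np.ndarray  # s
    start_frame: int
    center: tuple[int, int]
    padded: bool  # True when the crop ran over the frame border

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def crop_track(
    movie: MovieStack,
    track: PoreTrack,
    radius_nm: float = 25.0,
    pre_frames: int = 5,
    end_frame: int | None = None,
) -> CroppedSequence:
    """Crop a square sub-movie of half-width ``radius_nm`` around a track.

    The crop is centred on the track's median position and starts
    ``pre_frames`` before the birth frame (clamped at the movie start) so
    the pre-appearance baseline is recorded.  Pixels falling outside the
    frame are filled with the frame's background median and flagged.
    """
    if track.n_detections == 0:
        raise ValueError("cannot crop an empty track")
    half = int(round(radius_nm / movie.pixel_size))
    cr, cc = track.median_position
    start = max(0, track.birth_frame - pre_frames)
    stop = movie.n_frames if end_frame is None else min(end_frame + 1, movie.n_frames)
    rows, cols = movie.frame_shape
    r0, r1 = cr - half, cr + half + 1
    c0, c1 = cc - half, cc + half + 1
    padded = r0 < 0 or c0 < 0 or r1 > rows or c1 > cols
    side = 2 * half + 1
    out = np.empty((stop - start, side, side), dtype=np.float32)
    for i, k in enumerate(range(start, stop)):
        frame = movie.frames[k]
        if padded:
            fill = float(np.median(frame))
            patch = np.full((side, side), fill, dtype=np.float32)
            rs0, rs1 = max(r0, 0), min(r1, rows)
            cs0, cs1 = max(c0, 0), min(c1, cols)
            patch[rs0 - r0:rs1 - r0, cs0 - c0:cs1 - c0] = frame[rs0:rs1, cs0:cs1]
            out[i] = patch
        else:
            out[i] = frame[r0:r1, c0:c1]
    times = movie.frame_times[start:stop]
    return CroppedSequence(track.track_id, out, times, start, (cr, cc), padded)


@dataclass
class HeightTrace:
    """Average crop height per frame, the completeness proxy for one pore."""

    times: np.ndarray  # s
    mean_heights: np.ndarray  # nm
    normalized_heights: np.ndarray | None = None
    degenerate: bool = False
    track_id: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean_heights = np.asarray(self.mean_heights, dtype=float)
        if self.times.shape != self.mean_heights.shape:
            raise ValueError("times and mean_heights must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def height_trace(crop: CroppedSequence) -> HeightTrace:
    """Mean height over all crop pixels per frame, with robust normalisation.

    Normalised heights map the 5th/95th percentiles of the lightly
    smoothed trace to 0/1, so single-frame spikes do not set the scale.  A
    flat trace (no transition, e.g. all-background crop) is flagged
    degenerate and left unnormalised.
    """
    if crop.n_frames < 3:
        raise ValueError("need >= 3 frames for a height trace")
    means = crop.frames.reshape(crop.n_frames, -1).mean(axis=1)
    smoothed = means
    if means.size >= 7:
        from scipy.signal import savgol_filter

        smoothed = savgol_filter(means, 7, 2)
    lo, hi = np.percentile(smoothed, [5, 95])
    if hi - lo < 1e-12:
        return HeightTrace(crop.times, means, None, True, crop.track_id)
    norm = (means - lo) / (hi - lo)
    return HeightTrace(crop.times, means, norm, False, crop.track_id)
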