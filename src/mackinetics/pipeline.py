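"""End-to-end pipeline: movie -> preprocess -> detect -> track -> kinetics.

`run_all` wires the stages in the analysis order of the single-pore AFM
study: condition the frames, detect pores by template matching, link them
into tracks, fit each track's height trace with the tanh transition to
get oligomerisation times, fit the cumulative appearance curve for the
initiation time, and convert both characteristic times into the rate
constants k_init and k_+.  All intermediates are written as CSV/JSON with
a config hash for provenance, and reruns with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect import Detection, detect_movie, detectable_subunit_count
from .kinetics import estimate_kinetics, fit_appearance
from .movie import MovieStack, read_movie, write_movie
from .preprocess import preprocess_movie
from .synthetic import (
    PoreGeometry,
    SyntheticConfig,
    make_template,
    render_movie,
    simulate_assembly_events,
    write_ground_truth,
)
from .traces import aggregate_oligomerization, fit_sigmoid, qc_fit
from .tracking import PoreTrack, crop_track, filter_tracks, height_trace, link_tracks

log = logging.getLogger("mackinetics")

__all__ = ["PipelineConfig", "PipelineError", "run_all", "tracks_to_frame"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All tunables of the analysis chain, serialisable round-trip."""

    # detection / tracking
    threshold: float = 0.6
    max_link_dist_px: float = 30.0
    max_gap_frames: int = 3
    min_track_detections: int = 3
    # cropping / traces
    radius_nm: float = 25.0
    pre_frames: int = 5
    isolation_radius_nm: float | None = 50.0
    savgol_window: int = 7
    savgol_polyorder: int = 2
    # conditioning
    fwhm_px: float = 2.0
    n_mad: float = 3.0
    # kinetics
    c9_conc: float = 1.4e-3  # mM
    # synthetic input (used when simulate=True)
    simulate: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    geometry: PoreGeometry = field(default_factory=PoreGeometry)
    movie_path: str | None = None
    outdir: str = "mackinetics_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["image_shape"] = list(d["synthetic"]["image_shape"])
        d["synthetic"]["drift_per_frame"] = list(d["synthetic"]["drift_per_frame"])
        d["synthetic"]["tilt"] = list(d["synthetic"]["tilt"])
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        syn = dict(syn)
        for key in ("image_shape", "drift_per_frame", "tilt"):
            if key in syn:
                syn[key] = tuple(syn[key])
        geo = d.pop("geometry", {})
        return cls(synthetic=SyntheticConfig(**syn), geometry=PoreGeometry(**geo), **d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def tracks_to_frame(tracks: list[PoreTrack], frame_times: np.ndarray) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append(
                dict(
                    track_id=t.track_id,
                    frame=d.frame_index,
                    time_s=float(frame_times[d.frame_index]),
                    row_px=d.row,
                    col_px=d.col,
                    score=d.score,
                )
            )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "time_s", "row_px", "col_px", "score"]
    )


def _isolated_tracks(
    tracks: list[PoreTrack], radius_px: float
) -> list[PoreTrack]:
    """Tracks with no other track centre within ``radius_px``.

    Mirrors the restriction of the oligomerisation analysis to isolated
    pore-forming events: a neighbouring pore inside the crop window would
    contaminate the average-height trace with a second transition.
    """
    if radius_px is None:
        return tracks
    centers = np.array([t.median_position for t in tracks], dtype=float)
    keep = []
    for i, t in enumerate(tracks):
        d = np.hypot(*(centers - centers[i]).T)
        d[i] = np.inf
        if np.all(d >= radius_px):
            keep.append(t)
    return keep


def run_all(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute the full analysis; returns the summary report dict.

    Stages: (simulate|load) -> preprocess -> detect -> track ->
    fit-traces -> kinetics.  Any stage error raises PipelineError naming
    the stage; outputs written before the failure are retained.
    """
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_json(outdir / "config.json")
    chash = config.config_hash()
    report: dict = {"config_hash": chash, "version": __version__}

    # --- input movie ------------------------------------------------------
    trajectories = None
    try:
        if config.simulate:
            log.info("simulating movie: %s", config.synthetic)
            trajectories = simulate_assembly_events(config.synthetic, config.geometry)
            movie = render_movie(trajectories, config.geometry, config.synthetic)
            if write_outputs:
                write_movie(movie, outdir / "movie.tif", overwrite=True)
                write_ground_truth(trajectories, outdir / "ground_truth.csv")
        elif config.movie_path:
            movie = read_movie(config.movie_path)
        else:
            raise ValueError("either simulate=True or movie_path must be set")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'input': {e}") from e
    if movie.n_frames == 0 or not np.any(movie.frames):
        raise PipelineError("stage 'detect': movie is empty (no frames or all zero)")

    # --- preprocess -------------------------------------------------------
    try:
        log.info("preprocessing %d frames", movie.n_frames)
        pre = preprocess_movie(movie, fwhm_px=config.fwhm_px, n_mad=config.n_mad)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'preprocess': {e}") from e

    # --- detect -----------------------------------------------------------
    try:
        template = make_template(
            config.geometry, movie.pixel_size, smooth_fwhm_px=config.fwhm_px
        )
        detections = detect_movie(pre, template, threshold=config.threshold)
        counts = np.array([len(d) for d in detections])
        log.info("detected %d pore observations", int(counts.sum()))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'detect': {e}") from e

    # --- track ------------------------------------------------------------
    try:
        tracks = link_tracks(
            detections,
            max_link_dist_px=config.max_link_dist_px,
            max_gap_frames=config.max_gap_frames,
        )
        curated = filter_tracks(tracks, min_detections=config.min_track_detections)
        log.info("%d tracks (%d after curation)", len(tracks), len(curated))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'track': {e}") from e

    # --- fit traces -------------------------------------------------------
    try:
        iso_px = (
            config.isolation_radius_nm / movie.pixel_size
            if config.isolation_radius_nm
            else None
        )
        trace_tracks = _isolated_tracks(curated, iso_px)
        fits = []
        for track in trace_tracks:
            crop = crop_track(
                pre, track, radius_nm=config.radius_nm, pre_frames=config.pre_frames
            )
            trace = height_trace(crop)
            if trace.degenerate or len(trace) < max(6, config.savgol_window):
                continue
            fit = fit_sigmoid(
                trace,
                window_frames=config.savgol_window,
                polyorder=config.savgol_polyorder,
            )
            fits.append(qc_fit(fit, movie.duration))
        n_pass = sum(bool(f.qc_pass) for f in fits)
        log.info("fitted %d traces, %d pass QC", len(fits), n_pass)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'fit-traces': {e}") from e

    # --- kinetics ---------------------------------------------------------
    try:
        births = np.sort([t.birth_frame for t in curated])
        cumulative = np.searchsorted(births, np.arange(movie.n_frames), side="right")
        appearance = fit_appearance(movie.frame_times, cumulative)
        olig = aggregate_oligomerization(fits) if n_pass else None
        params = (
            estimate_kinetics(appearance, olig, config.c9_conc) if olig else None
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'kinetics': {e}") from e

    report.update(
        n_frames=movie.n_frames,
        n_tracks=len(tracks),
        n_tracks_curated=len(curated),
        n_traces_fit=len(fits),
        n_traces_pass=n_pass,
        appearance={
            "a_sat": appearance.a_sat,
            "tau_init_s": appearance.tau_init,
            "bse": appearance.bse.tolist(),
        },
    )
    if olig:
        report["oligomerization"] = {
            "n": olig.n,
            "tau_olig_mean_s": olig.mean,
            "tau_olig_sd_s": olig.sd,
            "tau_olig_sem_s": olig.sem,
        }
    if params:
        report["kinetics"] = {
            "c9_conc_mM": params.c9_conc,
            "tau_init_s": params.tau_init,
            "tau_olig_s": params.tau_olig,
            "tau_plus_s": params.tau_plus,
            "k_init_per_s_mM": params.k_init,
            "k_plus_per_s_mM": params.k_plus,
            "timescale_ratio": params.timescale_ratio,
        }
    if trajectories is not None:
        report["ground_truth"] = {
            "n_initiated": sum(t.initiated for t in trajectories),
            "n_completed": sum(t.completed for t in trajectories),
        }

    if write_outputs:
        pd.DataFrame(
            {"frame": np.arange(movie.n_frames), "time_s": movie.frame_times,
             "count": counts, "cumulative_tracks": cumulative}
        ).to_csv(outdir / "counts.csv", index=False)
        tracks_to_frame(curated, movie.frame_times).to_csv(
            outdir / "tracks.csv", index=False
        )
        pd.DataFrame(
            [
                dict(
                    track_id=f.track_id, A=f.A, B=f.B, t0_s=f.t0, tau_s=f.tau,
                    tau_olig_s=f.tau_olig, qc_pass=bool(f.qc_pass),
                    reject_reason=f.reject_reason,
                )
                for f in fits
            ],
            columns=["track_id", "A", "B", "t0_s", "tau_s", "tau_olig_s",
                     "qc_pass", "reject_reason"],
        ).to_csv(outdir / "fits.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report
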