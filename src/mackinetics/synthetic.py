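"""Synthetic time-lapse AFM movies of MAC pore assembly.

The membrane attack complex (MAC) completes its transmembrane pore by
sequential addition of C9 subunits to a membrane-bound C5b-8 initiator:
a slow first insertion (rate constant ``k_init``) followed by 17 fast
additions (rate constant ``k_plus``), both pseudo-first-order in the excess
C9 concentration.  This module samples those stochastic assembly
trajectories and renders them as AFM height-map movies — a flat bilayer
background plus growing annular pore features and instrument-like noise —
so the whole downstream analysis (detection, tracking, transition fitting,
kinetic estimation) can be exercised against known ground truth.

Scales follow the single-pore AFM literature: an ~11 nm lumen inside a
~22 nm outer ring, ring protruding ~10 nm above the bilayer, imaged at
2 nm/px and 6.5 s/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .movie import MovieStack

__all__ = [
    "PoreGeometry",
    "SyntheticConfig",
    "AssemblyTrajectory",
    "InvalidParameterError",
    "PlacementError",
    "RenderError",
    "N_SUBUNITS",
    "N_ADDITIONS",
    "simulate_assembly_events",
    "render_movie",
    "make_template",
    "simulate_height_traces",
    "trajectories_to_frame",
    "write_ground_truth",
    "read_ground_truth",
    "appearance_counts",
]

#: stoichiometry of the complete pore: 18 C9 copies, i.e. 17 additions
#: after the first insertion
N_SUBUNITS = 18
N_ADDITIONS = N_SUBUNITS - 1


class InvalidParameterError(ValueError):
    """A rate, concentration or interval is outside its physical domain."""


class PlacementError(RuntimeError):
    """The image cannot hold the requested complexes at the required separation."""


class RenderError(ValueError):
    """The pore geometry does not fit into the image."""


@dataclass(frozen=True)
class PoreGeometry:
    """Rendered shape of a complete MAC pore.

    All lengths in nm.  The ring is an annulus of height ``ring_height``
    between ``lumen_diameter`` and ``ring_outer_diameter``; the optional
    stalk is a small taller disc (the protruding C5b stalk) sitting just
    outside the ring at the growth-start angle.
    """

    lumen_diameter: float = 11.0
    ring_outer_diameter: float = 22.0
    ring_height: float = 10.0
    stalk_height: float = 16.0
    stalk_radius: float = 3.0
    stalk_enabled: bool = False

    def __post_init__(self):
        if not 0 < self.lumen_diameter < self.ring_outer_diameter:
            raise InvalidParameterError(
                "need 0 < lumen_diameter < ring_outer_diameter"
            )
        if self.ring_height < 0 or self.stalk_height < 0 or self.stalk_radius <= 0:
            raise InvalidParameterError("heights must be >= 0, stalk_radius > 0")

    @property
    def stalk_offset(self) -> float:
        """Radial distance of the stalk centre from the pore centre (nm)."""
        return self.ring_outer_diameter / 2 + self.stalk_radius

    def extent(self) -> float:
        """Radius (nm) of the smallest disc containing the rendered feature."""
        r = self.ring_outer_diameter / 2
        if self.stalk_enabled:
            r = max(r, self.stalk_offset + self.stalk_radius)
        return r


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic assembly movie.

    Rates are s⁻¹ mM⁻¹, the concentration mM (so the defaults reproduce
    the measured MAC constants k_init ≈ 0.78 and k_+ ≈ 108 s⁻¹ mM⁻¹ at
    [C9] = 1.4 µM); times s, lengths nm.
    """

    n_complexes: int = 50
    k_init: float = 0.78
    k_plus: float = 108.0
    c9_conc: float = 1.4e-3
    t_max: float = 3250.0
    frame_interval: float = 6.5
    pixel_size: float = 2.0
    image_shape: tuple[int, int] = (256, 256)
    noise_sd: float = 0.3
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    tilt: tuple[float, float] = (0.0, 0.0)  # nm per px along (rows, cols)
    seed: int = 0

    def __post_init__(self):
        if self.k_init < 0 or self.k_plus < 0:
            raise InvalidParameterError("rate constants must be >= 0")
        if self.c9_conc <= 0:
            raise InvalidParameterError("c9_conc must be > 0")
        if self.t_max <= 0 or self.frame_interval <= 0 or self.pixel_size <= 0:
            raise InvalidParameterError("t_max, frame_interval, pixel_size must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_complexes < 0:
            raise InvalidParameterError("n_complexes must be >= 0")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise InvalidParameterError("image_shape must be (rows, cols) >= 8 px")

    @property
    def n_frames(self) -> int:
        return int(round(self.t_max / self.frame_interval))

    @property
    def field_nm(self) -> tuple[float, float]:
        return (
            self.image_shape[0] * self.pixel_size,
            self.image_shape[1] * self.pixel_size,
        )


@dataclass
class AssemblyTrajectory:
    """Event times of one complex: first C9 insertion plus 17 additions.

    ``t_init`` is None when the complex never initiated within the
    simulated window; ``t_additions`` holds only the additions that
    occurred before ``t_max`` (later events are truncated).
    """

    complex_id: int
    position: tuple[float, float]  # (row, col) in nm
    t_init: float | None
    t_additions: np.ndarray
    theta0: float = 0.0  # growth start angle (rad), fixed per pore
    completed: bool = False

    @property
    def initiated(self) -> bool:
        return self.t_init is not None

    @property
    def completion_time(self) -> float | None:
        """Time from first insertion to the 17th addition, if completed."""
        if not self.completed:
            return None
        return float(self.t_additions[-1] - self.t_init)

    def subunit_count(self, t: float) -> int:
        """Number of inserted C9 copies displayed at time ``t``.

        Events are shown from the first frame at or after they occur, so
        the count at ``t`` is the number of events with time <= t.
        """
        if self.t_init is None or t < self.t_init:
            return 0
        return 1 + int(np.searchsorted(self.t_additions, t, side="right"))


def _substreams(seed: int) -> dict[str, np.random.SeedSequence]:
    """Independent named substreams so geometry changes never perturb event times."""
    children = np.random.SeedSequence(seed).spawn(4)
    return dict(zip(("positions", "events", "angles", "noise"), children))


def _template_side_px(geometry: PoreGeometry, pixel_size: float) -> int:
    """Next odd pixel count >= feature diameter / pixel_size + 4."""
    side = int(np.ceil(2 * geometry.extent() / pixel_size)) + 4
    return side + 1 if side % 2 == 0 else side


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    field_nm: tuple[float, float],
    min_sep_nm: float,
    margin_nm: float,
) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise separation."""
    lo = np.array([margin_nm, margin_nm])
    hi = np.array(field_nm) - margin_nm
    if np.any(hi <= lo):
        raise PlacementError("image too small for the required edge margin")
    accepted = np.empty((n, 2))
    count = 0
    tries = 0
    max_tries = max(10_000, 2_000 * n)
    while count < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could only place {count}/{n} complexes at "
                f"separation >= {min_sep_nm:.1f} nm"
            )
        cand = lo + rng.random(2) * (hi - lo)
        if count == 0 or np.min(
            np.hypot(*(accepted[:count] - cand).T)
        ) >= min_sep_nm:
            accepted[count] = cand
            count += 1
    return accepted


def simulate_assembly_events(
    config: SyntheticConfig, geometry: PoreGeometry | None = None
) -> list[AssemblyTrajectory]:
    """Sample stochastic assembly trajectories under ``config``.

    The first insertion time of each complex is exponential with rate
    ``k_init * c9_conc``; each of the 17 subsequent inter-addition waits is
    an independent exponential with rate ``k_plus * c9_conc``.  Events
    after ``t_max`` are truncated.  Zero rates are valid degenerate limits
    (the corresponding event never happens).  Positions are uniform with a
    minimum pairwise separation of one template width, so every rendered
    pore is unambiguously attributable.
    """
    geometry = geometry or PoreGeometry()
    streams = _substreams(config.seed)
    rng_pos = np.random.default_rng(streams["positions"])
    rng_ev = np.random.default_rng(streams["events"])
    rng_ang = np.random.default_rng(streams["angles"])

    side_nm = _template_side_px(geometry, config.pixel_size) * config.pixel_size
    positions = _draw_positions(
        rng_pos, config.n_complexes, config.field_nm, min_sep_nm=side_nm,
        margin_nm=side_nm / 2 + config.pixel_size,
    )

    lam_init = config.k_init * config.c9_conc
    lam_plus = config.k_plus * config.c9_conc

    trajectories = []
    for i in range(config.n_complexes):
        # always draw the full event set so truncation never shifts the stream
        t_init = rng_ev.exponential(1 / lam_init) if lam_init > 0 else np.inf
        waits = (
            rng_ev.exponential(1 / lam_plus, N_ADDITIONS)
            if lam_plus > 0
            else np.full(N_ADDITIONS, np.inf)
        )
        theta0 = rng_ang.uniform(0, 2 * np.pi)
        if t_init > config.t_max:
            traj = AssemblyTrajectory(i, tuple(positions[i]), None,
                                      np.empty(0), theta0, False)
        else:
            additions = t_init + np.cumsum(waits)
            additions = additions[additions <= config.t_max]
            traj = AssemblyTrajectory(
                i, tuple(positions[i]), float(t_init), additions, theta0,
                completed=len(additions) == N_ADDITIONS,
            )
        trajectories.append(traj)
    return trajectories


def _render_feature(
    frame: np.ndarray,
    center_px: tuple[float, float],
    geometry: PoreGeometry,
    pixel_size: float,
    n_subunits: int,
    theta0: float,
) -> None:
    """Paint one pore (arc fraction n/18 of the annulus) into ``frame`` in place."""
    if n_subunits <= 0:
        return
    r_ext = geometry.extent() / pixel_size + 1
    cr, cc = center_px
    r0 = max(int(np.floor(cr - r_ext)), 0)
    r1 = min(int(np.ceil(cr + r_ext)) + 1, frame.shape[0])
    c0 = max(int(np.floor(cc - r_ext)), 0)
    c1 = min(int(np.ceil(cc + r_ext)) + 1, frame.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_grid = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dy = (rr - cr) * pixel_size
    dx = (cc_grid - cc) * pixel_size
    rad = np.hypot(dy, dx)
    annulus = (rad >= geometry.lumen_diameter / 2) & (
        rad <= geometry.ring_outer_diameter / 2
    )
    frac = min(n_subunits / N_SUBUNITS, 1.0)
    if frac < 1.0:
        ang = np.mod(np.arctan2(dy, dx) - theta0, 2 * np.pi)
        annulus &= ang <= 2 * np.pi * frac
    patch = frame[r0:r1, c0:c1]
    np.maximum(patch, np.where(annulus, geometry.ring_height, -np.inf), out=patch)
    if geometry.stalk_enabled:
        sr = cr + geometry.stalk_offset / pixel_size * np.sin(theta0)
        sc = cc + geometry.stalk_offset / pixel_size * np.cos(theta0)
        stalk = np.hypot((rr - sr), (cc_grid - sc)) * pixel_size <= geometry.stalk_radius
        np.maximum(patch, np.where(stalk, geometry.stalk_height, -np.inf), out=patch)


def render_movie(
    trajectories: list[AssemblyTrajectory],
    geometry: PoreGeometry,
    config: SyntheticConfig,
    time_offset: float = 0.0,
) -> MovieStack:
    """Render trajectories into a height-map movie.

    Each frame is a flat 0 nm background plus optional global tilt,
    additive Gaussian noise of sd ``config.noise_sd``, and one annular
    feature per initiated pore whose arc fraction is (subunit count)/18 at
    full ring height.  Frame ``k`` shows the state at
    ``time_offset + k * frame_interval``.
    """
    if 2 * geometry.extent() >= min(config.field_nm):
        raise RenderError("pore geometry larger than the image")
    rows, cols = config.image_shape
    rng_noise = np.random.default_rng(_substreams(config.seed)["noise"])
    tilt = (
        config.tilt[0] * np.arange(rows)[:, None]
        + config.tilt[1] * np.arange(cols)[None, :]
    ).astype(np.float32)
    drift = np.asarray(config.drift_per_frame)

    frames = np.empty((config.n_frames, rows, cols), dtype=np.float32)
    times = time_offset + config.frame_interval * np.arange(config.n_frames)
    for k, t in enumerate(times):
        frame = np.zeros((rows, cols), dtype=np.float32)
        for traj in trajectories:
            n = traj.subunit_count(t)
            if n == 0:
                continue
            pos_nm = np.asarray(traj.position) + k * drift
            center_px = tuple(pos_nm / config.pixel_size)
            _render_feature(frame, center_px, geometry, config.pixel_size, n,
                            traj.theta0)
        frame += tilt
        if config.noise_sd > 0:
            frame += rng_noise.normal(0, config.noise_sd, frame.shape).astype(
                np.float32
            )
        frames[k] = frame
    return MovieStack(
        frames=frames,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        time_offset=time_offset,
        meta={"synthetic_config": _config_to_dict(config)},
    )


def make_template(
    geometry: PoreGeometry, pixel_size: float, smooth_fwhm_px: float | None = None
) -> np.ndarray:
    """Noiseless image patch of one complete pore, centred.

    Side length is the next odd pixel count >= feature diameter /
    pixel_size + 4.  ``smooth_fwhm_px`` optionally applies the same
    Gaussian smoothing as the preprocessing chain so the template matches
    smoothed movies.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    side = _template_side_px(geometry, pixel_size)
    patch = np.zeros((side, side), dtype=np.float32)
    center = ((side - 1) / 2, (side - 1) / 2)
    _render_feature(patch, center, geometry, pixel_size, N_SUBUNITS, theta0=0.0)
    if smooth_fwhm_px:
        from scipy.ndimage import gaussian_filter

        patch = gaussian_filter(patch, sigma=smooth_fwhm_px / 2.3548, mode="reflect")
    return patch


def simulate_height_traces(
    n_traces: int,
    amplitude: float = 0.5,
    baseline: float = 0.5,
    t0: float = 300.0,
    tau: float = 37.33,
    frame_interval: float = 6.5,
    duration: float = 650.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Noisy tanh transition traces with known parameters.

    Emulates the normalised average-height trace of a single pore-forming
    event: ``amplitude * tanh((t - t0)/tau) + baseline`` plus Gaussian
    noise, sampled on the AFM frame grid.  Returns (times, heights) pairs.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, frame_interval)
    clean = amplitude * np.tanh((t - t0) / tau) + baseline
    return [
        (t.copy(), clean + rng.normal(0, noise_sd, t.size)) for _ in range(n_traces)
    ]


# ---------------------------------------------------------------------------
# ground-truth serialisation

def trajectories_to_frame(trajectories: list[AssemblyTrajectory]) -> pd.DataFrame:
    """Flatten trajectories to (complex_id, event_index, time_s, row_nm, col_nm).

    Event index 0 is the first insertion; 1..17 the subsequent additions.
    Complexes that never initiated contribute no rows.
    """
    rows = []
    for traj in trajectories:
        if not traj.initiated:
            continue
        events = np.concatenate([[traj.t_init], traj.t_additions])
        for j, t in enumerate(events):
            rows.append(
                dict(
                    complex_id=traj.complex_id,
                    event_index=j,
                    time_s=float(t),
                    row_nm=traj.position[0],
                    col_nm=traj.position[1],
                )
            )
    return pd.DataFrame(
        rows, columns=["complex_id", "event_index", "time_s", "row_nm", "col_nm"]
    )


def write_ground_truth(trajectories: list[AssemblyTrajectory], path: str | Path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def appearance_counts(
    trajectories: list[AssemblyTrajectory], times: np.ndarray
) -> np.ndarray:
    """Ground-truth cumulative number of initiated complexes at each time."""
    t_inits = np.sort([t.t_init for t in trajectories if t.initiated])
    return np.searchsorted(t_inits, np.asarray(times), side="right")


def _config_to_dict(config: SyntheticConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["image_shape"] = list(d["image_shape"])
    d["drift_per_frame"] = list(d["drift_per_frame"])
    d["tilt"] = list(d["tilt"])
    return d
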