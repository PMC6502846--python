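"""Oligomerisation-time measurement by sigmoid transition fitting.

The average-height trace of a growing pore rises smoothly from the bare
bilayer baseline to the complete-pore plateau.  The transition is
described by the generic sigmoid

    f(t) = A * tanh((t - t0) / tau) + B

with amplitude A, offset B, transition centre t0 and scale tau.  The
oligomerisation time is defined as the width 3*tau of the transition,
which covers tanh(1.5) ~ 90% of the full amplitude 2A — the time for the
17 C9 additions that complete the pore after first insertion.

Fits whose centre precedes the movie start (t0 < 0) or whose width
exceeds the movie duration are quality-control rejections: the transition
was not actually observed.

The fit is exposed statsmodels-style: :class:`SigmoidTransitionModel`
holds the data, ``fit()`` returns a :class:`SigmoidFit` results object
with estimates, standard errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .tracking import HeightTrace

__all__ = [
    "SigmoidTransitionModel",
    "SigmoidFit",
    "OligSummary",
    "sigmoid",
    "savgol_smooth",
    "fit_sigmoid",
    "qc_fit",
    "transition_width",
    "transition_coverage",
    "aggregate_oligomerization",
]

#: multiple of tau defining the transition width
WIDTH_FACTOR = 3.0


def sigmoid(t, A, B, t0, tau):
    """The transition model A*tanh((t - t0)/tau) + B."""
    return A * np.tanh((t - t0) / tau) + B


def savgol_smooth(
    trace: HeightTrace, window_frames: int = 7, polyorder: int = 2
) -> HeightTrace:
    """Savitzky–Golay smoothing of a height trace.

    Polynomial-preserving: traces that are exactly a polynomial of degree
    <= ``polyorder`` pass through unchanged.
    """
    if window_frames % 2 == 0 or window_frames <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if len(trace) < window_frames:
        raise ValueError(
            f"trace has {len(trace)} points < window {window_frames}; "
            "use a smaller window"
        )
    smoothed = savgol_filter(trace.mean_heights, window_frames, polyorder)
    norm = None
    if trace.normalized_heights is not None:
        norm = savgol_filter(trace.normalized_heights, window_frames, polyorder)
    return HeightTrace(trace.times, smoothed, norm, trace.degenerate, trace.track_id)


@dataclass
class SigmoidFit:
    """Results of a sigmoid transition fit.

    ``tau_olig = 3 * tau`` is the oligomerisation time; ``bse`` are the
    standard errors from the fit covariance.  ``qc_pass`` is None until
    :func:`qc_fit` has been applied.
    """

    A: float
    B: float
    t0: float
    tau: float
    cov: np.ndarray | None
    residual_rms: float
    converged: bool
    qc_pass: bool | None = None
    reject_reason: str = "none"  # t0_negative | width_exceeds_movie | fit_failed | none
    track_id: int | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.A, self.B, self.t0, self.tau])

    @property
    def bse(self) -> np.ndarray:
        if self.cov is None:
            return np.full(4, np.nan)
        return np.sqrt(np.diag(self.cov))

    @property
    def tau_olig(self) -> float:
        return WIDTH_FACTOR * self.tau

    def predict(self, t) -> np.ndarray:
        return sigmoid(np.asarray(t, float), self.A, self.B, self.t0, self.tau)

    def summary(self) -> str:
        lines = ["Sigmoid transition fit  f(t) = A*tanh((t-t0)/tau) + B"]
        lines.append("-" * 54)
        for name, val, se in zip(["A", "B", "t0", "tau"], self.params, self.bse):
            lines.append(f"{name:>4s}  {val:12.4f}  (se {se:.4f})")
        lines.append(f"tau_olig = 3*tau = {self.tau_olig:.2f} s")
        lines.append(f"residual rms = {self.residual_rms:.4g}")
        lines.append(f"qc_pass = {self.qc_pass}  reject_reason = {self.reject_reason}")
        return "\n".join(lines)

    def plot(self, trace: HeightTrace | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if trace is not None:
            ax.plot(trace.times, trace.mean_heights, ".", color="0.5", label="trace")
            tt = np.linspace(trace.times[0], trace.times[-1], 200)
        else:
            tt = np.linspace(self.t0 - 5 * self.tau, self.t0 + 5 * self.tau, 200)
        ax.plot(tt, self.predict(tt), "r-", label="tanh fit")
        for x in (self.t0 - 1.5 * self.tau, self.t0 + 1.5 * self.tau):
            ax.axvline(x, color="g", ls="--", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("average height")
        ax.legend()
        return ax


class SigmoidTransitionModel:
    """Nonlinear least-squares tanh transition model for one height trace.

    Parameters
    ----------
    times, heights : array_like
        The (optionally smoothed) average-height trace.
    """

    def __init__(self, times, heights):
        self.times = np.asarray(times, dtype=float)
        self.heights = np.asarray(heights, dtype=float)
        if self.times.size != self.heights.size:
            raise ValueError("times and heights must have equal length")
        if self.times.size < 6:
            raise ValueError("need >= 6 points spanning the transition")

    @classmethod
    def from_trace(
        cls,
        trace: HeightTrace,
        smooth: bool = True,
        window_frames: int = 7,
        polyorder: int = 2,
    ) -> "SigmoidTransitionModel":
        if smooth and len(trace) >= window_frames:
            trace = savgol_smooth(trace, window_frames, polyorder)
        model = cls(trace.times, trace.mean_heights)
        model._track_id = trace.track_id
        return model

    _track_id: int | None = None

    def _initial_guess(self) -> list[float]:
        h, t = self.heights, self.times
        A0 = max((h.max() - h.min()) / 2, 1e-9)
        B0 = float(h.mean())
        t00 = float(t[np.argmax(np.gradient(h))])
        tau0 = max((t[-1] - t[0]) / 4, 1e-6)
        return [A0, B0, t00, tau0]

    def fit(self, p0=None, maxfev: int = 10_000) -> SigmoidFit:
        """Fit (A, B, t0, tau) with bounds A > 0, tau > 0.

        Non-convergence yields a SigmoidFit flagged ``fit_failed`` rather
        than an exception, so batch processing can continue.
        """
        p0 = p0 or self._initial_guess()
        bounds = ([1e-12, -np.inf, -np.inf, 1e-12], [np.inf] * 4)
        try:
            popt, pcov = curve_fit(
                sigmoid, self.times, self.heights, p0=p0, bounds=bounds, maxfev=maxfev
            )
        except (RuntimeError, ValueError):
            return SigmoidFit(
                np.nan, np.nan, np.nan, np.nan, None, np.nan,
                converged=False, qc_pass=False, reject_reason="fit_failed",
                track_id=self._track_id,
            )
        resid = self.heights - sigmoid(self.times, *popt)
        return SigmoidFit(
            *map(float, popt),
            cov=pcov,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            converged=True,
            track_id=self._track_id,
        )


def fit_sigmoid(
    trace: HeightTrace, smooth: bool = True, window_frames: int = 7, polyorder: int = 2
) -> SigmoidFit:
    """Convenience wrapper: smooth a trace and fit the tanh transition."""
    return SigmoidTransitionModel.from_trace(
        trace, smooth=smooth, window_frames=window_frames, polyorder=polyorder
    ).fit()


def qc_fit(fit: SigmoidFit, movie_duration: float) -> SigmoidFit:
    """Apply the quality-control rejection rules.

    Rejects fits whose transition centre is negative (before C9 addition)
    or whose width 3*tau exceeds the movie duration; anything else passes.
    """
    if not fit.converged:
        return replace(fit, qc_pass=False, reject_reason="fit_failed")
    if fit.t0 < 0:
        return replace(fit, qc_pass=False, reject_reason="t0_negative")
    if fit.tau_olig > movie_duration:
        return replace(fit, qc_pass=False, reject_reason="width_exceeds_movie")
    return replace(fit, qc_pass=True, reject_reason="none")


def transition_width(fit: SigmoidFit) -> float:
    """The oligomerisation time 3*tau of a QC-passing fit."""
    if not fit.qc_pass:
        raise ValueError(f"fit did not pass QC ({fit.reject_reason})")
    return fit.tau_olig


def transition_coverage() -> float:
    """Fraction of the full amplitude 2A traversed on [t0-1.5tau, t0+1.5tau].

    Equals tanh(1.5) ~ 0.905, the '~90% of the transition' that motivates
    the 3*tau width definition.
    """
    return math.tanh(WIDTH_FACTOR / 2)


@dataclass
class OligSummary:
    """Aggregate of oligomerisation times over QC-passing events."""

    n: int
    mean: float
    sd: float
    sem: float
    tau_oligs: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def summary(self) -> str:
        sem = "n/a" if math.isnan(self.sem) else f"{self.sem:.1f}"
        return (
            f"oligomerisation time over n = {self.n} events: "
            f"{self.mean:.1f} s (sd {self.sd:.1f}, sem {sem})"
        )


def aggregate_oligomerization(
    fits: list[SigmoidFit], bin_width: float | None = None
) -> OligSummary:
    """Summarise tau_olig over QC-passing fits.

    With a single event the sem is undefined and reported as NaN.
    """
    passing = [f for f in fits if f.qc_pass]
    if not passing:
        raise ValueError("no QC-passing fits to aggregate")
    taus = np.array([f.tau_olig for f in passing])
    n = taus.size
    mean = float(taus.mean())
    sd = float(taus.std(ddof=1)) if n > 1 else float("nan")
    sem = sd / math.sqrt(n) if n > 1 else float("nan")
    if bin_width is None:
        bin_width = max(np.ptp(taus) / 10, 1e-9)
    edges = np.arange(taus.min(), taus.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([taus.min(), taus.min() + bin_width])
    counts, edges = np.histogram(taus, bins=edges)
    return OligSummary(n, mean, sd, sem, taus, counts, edges)
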