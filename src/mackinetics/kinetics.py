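"""Two-rate kinetic model of MAC assembly: initiation and propagation.

Because the first C9 insertion is orders of magnitude slower than the
subsequent additions, assembly splits into two pseudo-first-order
reactions in the excess C9 concentration:

* initiation, C5b-8 + C9 -> C5b-8(C9)_1 with rate constant ``k_init``;
  per complex the initiation probability is
  ``p_init(t) = 1 - exp(-k_init [C9] t)``, so the number of pores on the
  membrane follows the appearance curve ``A (1 - exp(-t / tau_init))``
  with ``tau_init = 1/(k_init [C9])``;
* propagation, C5b-8(C9)_n + C9 -> C5b-8(C9)_{n+1} for 1 <= n < 18 with
  rate constant ``k_plus``; the occupancy distribution p_n(t) obeys a
  linear birth chain with absorbing state n = 18, and the mean oligomer
  size grows at the constant rate ``k_plus [C9]`` while the absorbing
  state is still nearly empty.

Characteristic times convert to rate constants as ``k = 1/(tau [C9])``
(rates in s⁻¹ mM⁻¹, concentration in mM, times in s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .synthetic import N_ADDITIONS, N_SUBUNITS

__all__ = [
    "AppearanceCurveModel",
    "AppearanceFit",
    "KineticParameters",
    "OccupancyDistribution",
    "fit_appearance",
    "p_init",
    "rate_constant",
    "tau_plus_from_olig",
    "solve_occupancy",
    "mean_oligomer_size",
    "growth_slope",
    "estimate_kinetics",
]


def _appearance(t, a_sat, tau):
    return a_sat * (1 - np.exp(-t / tau))


@dataclass
class AppearanceFit:
    """Saturating-exponential fit of the cumulative pore count."""

    a_sat: float
    tau_init: float
    cov: np.ndarray | None
    residual_rms: float
    boundary: bool = False  # initiation faster than the sampling resolves

    @property
    def bse(self) -> np.ndarray:
        if self.cov is None:
            return np.full(2, np.nan)
        return np.sqrt(np.diag(self.cov))

    def predict(self, t) -> np.ndarray:
        return _appearance(np.asarray(t, float), self.a_sat, self.tau_init)

    def summary(self) -> str:
        se_a, se_tau = self.bse
        lines = [
            "Appearance curve fit  N(t) = A (1 - exp(-t/tau_init))",
            "-" * 54,
            f"A_sat    = {self.a_sat:10.2f}  (se {se_a:.2f})",
            f"tau_init = {self.tau_init:10.1f} s  (se {se_tau:.1f})",
            f"residual rms = {self.residual_rms:.3g}",
        ]
        if self.boundary:
            lines.append("warning: boundary fit (appearance saturated immediately)")
        return "\n".join(lines)

    def plot(self, times=None, counts=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if times is not None and counts is not None:
            ax.plot(times, counts, "s", ms=3, color="0.5", label="pore count")
            tt = np.linspace(0, np.max(times), 300)
        else:
            tt = np.linspace(0, 5 * self.tau_init, 300)
        ax.plot(tt, self.predict(tt), "r-",
                label=rf"fit, $\tau_\mathrm{{init}}$ = {self.tau_init:.0f} s")
        ax.set_xlabel("time after C9 addition (s)")
        ax.set_ylabel("number of pores")
        ax.legend()
        return ax


class AppearanceCurveModel:
    """Least-squares model for the pore appearance curve.

    Fits ``A (1 - exp(-t/tau))`` to per-frame cumulative pore counts;
    ``tau`` estimates the characteristic initiation time of the first C9
    insertion.
    """

    def __init__(self, times, counts):
        self.times = np.asarray(times, dtype=float)
        self.counts = np.asarray(counts, dtype=float)
        if self.times.size != self.counts.size:
            raise ValueError("times and counts must have equal length")
        if self.times.size < 5:
            raise ValueError("need >= 5 time points")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def fit(self, maxfev: int = 10_000) -> AppearanceFit:
        if np.all(self.counts == 0):
            raise ValueError("degenerate fit: all counts are zero")
        a0 = float(self.counts.max())
        target = (1 - 1 / math.e) * a0
        reached = self.times[self.counts >= target]
        tau0 = float(reached[0]) if reached.size and reached[0] > 0 else float(
            max(self.times[-1] / 4, self.times[1] - self.times[0])
        )
        popt, pcov = curve_fit(
            _appearance, self.times, self.counts, p0=[a0, tau0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=maxfev,
        )
        resid = self.counts - _appearance(self.times, *popt)
        dt = np.min(np.diff(self.times)) if self.times.size > 1 else 0.0
        return AppearanceFit(
            a_sat=float(popt[0]),
            tau_init=float(popt[1]),
            cov=pcov,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            boundary=bool(popt[1] < dt),
        )


def fit_appearance(times, counts) -> AppearanceFit:
    """Fit the appearance curve; see :class:`AppearanceCurveModel`."""
    return AppearanceCurveModel(times, counts).fit()


def p_init(t, k_init: float, c9: float):
    """Probability that a single C5b-8 complex has initiated by time ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if k_init < 0 or c9 <= 0:
        raise ValueError("k_init must be >= 0 and c9 > 0")
    out = 1.0 - np.exp(-k_init * c9 * t)
    return float(out) if out.ndim == 0 else out


def rate_constant(tau: float, c9: float) -> float:
    """Convert a characteristic time to a rate constant, k = 1/(tau [C9])."""
    if tau <= 0 or c9 <= 0:
        raise ValueError("tau and c9 must be > 0")
    return 1.0 / (tau * c9)


def tau_plus_from_olig(tau_olig: float, n_additions: int = N_ADDITIONS) -> float:
    """Average time per single C9 addition: tau_olig / 17."""
    if tau_olig <= 0:
        raise ValueError("tau_olig must be > 0")
    if n_additions < 1:
        raise ValueError("n_additions must be >= 1")
    return tau_olig / n_additions


@dataclass
class OccupancyDistribution:
    """p_n(t) of the C9 birth chain on a time grid, n = 1..n_max."""

    times: np.ndarray  # (T,)
    p: np.ndarray  # (T, n_max)

    @property
    def n_max(self) -> int:
        return self.p.shape[1]

    @property
    def n_values(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def mean_n(self) -> np.ndarray:
        """Mean oligomer size <n>(t)."""
        return self.p @ self.n_values

    def plot(self, ax=None, states=(1, 6, 12, 18)):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for n in states:
            ax.plot(self.times, self.p[:, n - 1], label=f"n = {n}")
        ax.set_xlabel("time after first insertion (s)")
        ax.set_ylabel(r"$p_n(t)$")
        ax.legend()
        return ax


def solve_occupancy(
    k_plus: float, c9: float, times, n_max: int = N_SUBUNITS
) -> OccupancyDistribution:
    """Solve the linear birth chain dp_n/dt with absorbing state n_max.

    dp_1/dt = -lam p_1;  dp_n/dt = lam (p_{n-1} - p_n) for 1 < n < n_max;
    dp_{n_max}/dt = lam p_{n_max - 1}, with lam = k_plus * [C9] and
    initial condition p_1(0) = 1.  Propagated by the matrix exponential
    of the chain generator, so probability is conserved to machine
    precision.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a 1D non-empty grid")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if k_plus < 0 or c9 <= 0:
        raise ValueError("k_plus must be >= 0 and c9 > 0")
    lam = k_plus * c9
    gen = np.zeros((n_max, n_max))
    for n in range(n_max - 1):
        gen[n, n] = -lam
        gen[n + 1, n] = lam
    p0 = np.zeros(n_max)
    p0[0] = 1.0
    p = np.empty((times.size, n_max))
    for i, t in enumerate(times):
        p[i] = expm(gen * t) @ p0
    return OccupancyDistribution(times, p)


def mean_oligomer_size(occ: OccupancyDistribution) -> np.ndarray:
    """Mean number of inserted C9 copies <n>(t) = sum_n n p_n(t)."""
    return occ.mean_n


def growth_slope(occ: OccupancyDistribution, p_absorbed_max: float = 0.01):
    """Linear-regression slope of <n>(t) while the absorbing state is empty.

    Restricted to times where p_{n_max} < ``p_absorbed_max``, where the
    chain predicts a constant growth rate d<n>/dt = k_plus [C9].
    """
    mask = occ.p[:, -1] < p_absorbed_max
    if mask.sum() < 2:
        raise ValueError("not enough early-time points below the absorption cut")
    res = linregress(occ.times[mask], occ.mean_n[mask])
    return res.slope


@dataclass
class KineticParameters:
    """The assembled two-rate description of MAC formation."""

    c9_conc: float  # mM
    tau_init: float  # s
    tau_plus: float  # s
    k_init: float  # s^-1 mM^-1
    k_plus: float  # s^-1 mM^-1
    tau_olig: float  # s
    n_max: int = N_SUBUNITS
    n_additions: int = N_ADDITIONS

    @property
    def timescale_ratio(self) -> float:
        """tau_init / tau_plus — the separation justifying the two-step model."""
        return self.tau_init / self.tau_plus

    def summary(self) -> str:
        return "\n".join(
            [
                "MAC assembly kinetics",
                "-" * 54,
                f"[C9]       = {self.c9_conc * 1e3:.2f} uM",
                f"tau_init   = {self.tau_init:8.1f} s",
                f"tau_olig   = {self.tau_olig:8.1f} s "
                f"({self.n_additions} additions)",
                f"tau_+      = {self.tau_plus:8.2f} s per C9 addition",
                f"k_init     = {self.k_init:8.3g} s^-1 mM^-1",
                f"k_+        = {self.k_plus:8.4g} s^-1 mM^-1",
                f"tau_init / tau_+ = {self.timescale_ratio:.0f}",
            ]
        )


def estimate_kinetics(appearance: AppearanceFit, olig_summary, c9: float) -> KineticParameters:
    """Assemble kinetic parameters from the two fitted characteristic times.

    ``olig_summary`` is an :class:`~mackinetics.traces.OligSummary` (its
    mean tau_olig is used) or a plain float tau_olig in seconds.
    """
    if appearance is None or olig_summary is None:
        raise ValueError("need both an appearance fit and an oligomerisation summary")
    tau_olig = getattr(olig_summary, "mean", olig_summary)
    tau_init = appearance.tau_init
    tau_plus = tau_plus_from_olig(tau_olig)
    return KineticParameters(
        c9_conc=c9,
        tau_init=tau_init,
        tau_plus=tau_plus,
        k_init=rate_constant(tau_init, c9),
        k_plus=rate_constant(tau_plus, c9),
        tau_olig=float(tau_olig),
    )
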