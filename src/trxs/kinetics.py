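"""Two-component kinetic decomposition of time-resolved difference scattering.

Each time point's curve is expressed as a linear combination of two fixed
basis patterns — an early (microsecond) pattern and a late (steady-state)
pattern — by per-time linear least squares. The amplitude trace of the slow
component is then fit with a half-time parameterized exponential,

.. math::

    A(t) = A_\\infty \\left(1 - 2^{-t/t_{1/2}}\\right)
    \\quad\\text{(rise)},\\qquad
    A(t) = A_0 \\, 2^{-t/t_{1/2}} \\quad\\text{(decay)},

so the reported parameter is directly the half-time in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .models import DifferenceCurve, require_same_grid

__all__ = [
    "TimeSeriesSet",
    "BasisSet",
    "AmplitudeTraces",
    "HalftimeFit",
    "extract_basis",
    "decompose",
    "fit_halftime",
    "singular_value_report",
]


@dataclass
class TimeSeriesSet:
    """Time-stamped difference curves on one common q grid."""

    times: np.ndarray  # seconds, strictly increasing
    curves: list[DifferenceCurve]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.curves) != self.times.size:
            raise ValueError("one curve per time point required")
        q0 = self.curves[0].q
        for c in self.curves[1:]:
            require_same_grid(q0, c.q, "time-series curves")

    @property
    def q(self) -> np.ndarray:
        return self.curves[0].q

    def data_matrix(self) -> np.ndarray:
        """(n_times, n_q) matrix of ΔS values."""
        return np.stack([c.delta for c in self.curves])


@dataclass
class BasisSet:
    """Two basis patterns on the series grid (early and late components)."""

    early: DifferenceCurve
    late: DifferenceCurve
    labels: tuple[str, str] = ("early", "late")

    def __post_init__(self) -> None:
        require_same_grid(self.early.q, self.late.q, "basis patterns")
        b = self.matrix()
        cond = np.linalg.cond(b)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                f"basis patterns are linearly dependent (condition number {cond:.3g})"
            )

    def matrix(self) -> np.ndarray:
        """(n_q, 2) design matrix."""
        return np.column_stack([self.early.delta, self.late.delta])


@dataclass
class AmplitudeTraces:
    """Per-time basis amplitudes and residual norms."""

    times: np.ndarray
    amplitudes: np.ndarray  # (n_times, 2) — columns follow BasisSet order
    residual_norms: np.ndarray
    labels: tuple[str, str] = ("early", "late")

    @property
    def early(self) -> np.ndarray:
        return self.amplitudes[:, 0]

    @property
    def late(self) -> np.ndarray:
        return self.amplitudes[:, 1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                f"amp_{self.labels[0]}": self.amplitudes[:, 0],
                f"amp_{self.labels[1]}": self.amplitudes[:, 1],
                "resid_norm": self.residual_norms,
            }
        )


def extract_basis(
    series: TimeSeriesSet,
    early_time: float,
    late_window: tuple[float, float],
) -> BasisSet:
    """Basis from the series itself: nearest-time early pattern, windowed mean
    late pattern (e.g. the 3 µs curve and the 100 ms–2000 ms average)."""
    idx = int(np.argmin(np.abs(series.times - early_time)))
    early = series.curves[idx]
    lo, hi = late_window
    sel = (series.times >= lo) & (series.times <= hi)
    if not np.any(sel):
        raise ValueError(f"late window {late_window} contains no time points")
    late_mean = np.mean([series.curves[i].delta for i in np.where(sel)[0]], axis=0)
    return BasisSet(
        early=DifferenceCurve(q=series.q.copy(), delta=early.delta.copy(),
                              time_s=float(series.times[idx]),
                              provenance="basis:early"),
        late=DifferenceCurve(q=series.q.copy(), delta=late_mean,
                             provenance="basis:late"),
    )


def decompose(series: TimeSeriesSet, basis: BasisSet,
              sigma_weighted: bool = False) -> AmplitudeTraces:
    """Per-time least-squares amplitudes of the two basis patterns.

    Solves ``min_a ||ΔS(t) − B a||₂`` for each time point (the pseudo-inverse
    applied to the data matrix). Optional 1/σ weighting uses the per-curve
    sigma when present.
    """
    require_same_grid(series.q, basis.early.q, "series and basis")
    B = basis.matrix()
    Y = series.data_matrix().T  # (n_q, n_times)
    if sigma_weighted:
        sig = np.stack([
            c.sigma if c.sigma is not None else np.ones_like(c.delta)
            for c in series.curves
        ]).T
        amps = np.empty((series.times.size, 2))
        resid = np.empty(series.times.size)
        for t in range(series.times.size):
            w = 1.0 / sig[:, t]
            a, *_ = np.linalg.lstsq(B * w[:, None], Y[:, t] * w, rcond=None)
            amps[t] = a
            resid[t] = float(np.linalg.norm(Y[:, t] - B @ a))
        return AmplitudeTraces(series.times.copy(), amps, resid, basis.labels)
    a, _, rank, _ = np.linalg.lstsq(B, Y, rcond=None)
    if rank < 2:
        raise ValueError(
            f"rank-deficient basis (rank {rank}, cond {np.linalg.cond(B):.3g})"
        )
    resid = np.linalg.norm(Y - B @ a, axis=0)
    return AmplitudeTraces(series.times.copy(), a.T, resid, basis.labels)


@dataclass
class HalftimeFit:
    """Half-time fit result with Jacobian-based standard errors."""

    halftime_s: float
    amplitude: float
    halftime_stderr: float
    amplitude_stderr: float
    model: str  # "rise" or "decay"
    sse: float

    def __repr__(self) -> str:  # compact, report-friendly
        return (
            f"HalftimeFit(model={self.model!r}, t_half={self.halftime_s:.4g} s "
            f"± {self.halftime_stderr:.2g}, A={self.amplitude:.4g})"
        )


def _shape(t: np.ndarray, t_half: float, model: str) -> np.ndarray:
    decay = np.exp2(-t / t_half)
    return 1.0 - decay if model == "rise" else decay


def fit_halftime(
    times: np.ndarray,
    trace: np.ndarray,
    model: str = "rise",
    n_grid: int = 40,
) -> HalftimeFit:
    """Nonlinear least squares of A·(1 − 2^(−t/t½)) or A·2^(−t/t½).

    Initialization scans a log-spaced half-time grid spanning the sampled
    time range (closed-form amplitude per grid point), then refines the best
    grid point with ``scipy.optimize.curve_fit``.
    """
    if model not in ("rise", "decay"):
        raise ValueError("model must be 'rise' or 'decay'")
    t = np.asarray(times, dtype=float)
    y = np.asarray(trace, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.ptp(y) == 0.0:
        raise ValueError("trace constant — no kinetics to fit")
    t_pos = t[t > 0]
    if t_pos.size == 0:
        raise ValueError("no positive time points")

    # multistart over log-spaced t_half with closed-form amplitude
    grid = np.geomspace(t_pos.min() / 10.0, t.max() * 10.0, n_grid)
    best = None
    for th in grid:
        g = _shape(t, th, model)
        gg = float(np.dot(g, g))
        if gg == 0.0:
            continue
        a = float(np.dot(g, y)) / gg
        sse = float(np.sum((y - a * g) ** 2))
        if best is None or sse < best[0]:
            best = (sse, th, a)
    if best is None:
        raise ValueError("half-time grid search failed (degenerate trace)")
    _, th0, a0 = best

    def f(tt, a, th):
        return a * _shape(tt, th, model)

    try:
        popt, pcov = curve_fit(
            f, t, y, p0=[a0, th0],
            bounds=([-np.inf, grid[0] / 10.0], [np.inf, grid[-1] * 10.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(
            f"half-time fit did not converge (best grid point t_half={th0:.3g} s, "
            f"sse={best[0]:.3g})"
        ) from exc
    a_fit, th_fit = popt
    perr = np.sqrt(np.diag(pcov))
    sse = float(np.sum((y - f(t, *popt)) ** 2))
    return HalftimeFit(
        halftime_s=float(th_fit),
        amplitude=float(a_fit),
        halftime_stderr=float(perr[1]),
        amplitude_stderr=float(perr[0]),
        model=model,
        sse=sse,
    )


def singular_value_report(series: TimeSeriesSet, n: int = 5) -> np.ndarray:
    """Leading singular values of the data matrix (component-count diagnostic)."""
    s = np.linalg.svd(series.data_matrix(), compute_uv=False)
    return s[:n]
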