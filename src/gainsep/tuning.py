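"""Contrast response functions and response-timing metrics.

The contrast tuning curve is the Naka-Rushton function

    R(c) = R_max · c^n / (c^n + c50^n) + R0

with maximum response ``R_max``, semi-saturation contrast ``c50``, slope
exponent ``n`` and offset ``R0``. Divisive normalization predicts that
scaling a family of responses by their maximum at 100% contrast collapses
the curves onto a common shape (``c50`` and ``n`` unchanged) — a common
multiplicative factor moves only ``R_max`` and ``R0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "NakaRushtonFit",
    "ResponseTiming",
    "naka_rushton",
    "fit_naka_rushton",
    "normalize_and_refit",
    "response_latency",
    "response_duration",
]


@dataclass
class NakaRushtonFit:
    r_max: float
    c50: float
    n: float
    r0: float
    r_squared: float  # NaN when residual dof <= 2 or variance degenerate
    converged: bool
    n_points: int
    degenerate: bool = False

    @property
    def params(self):
        return (self.r_max, self.c50, self.n, self.r0)

    def __call__(self, c):
        return naka_rushton(c, self.params)


@dataclass
class ResponseTiming:
    latency: float | None  # None = threshold never crossed
    duration_t50: float
    peak_time: float


def naka_rushton(c, params):
    """Evaluate the Naka-Rushton function; ``params = (R_max, c50, n, R0)``."""
    r_max, c50, n, r0 = params
    c = np.asarray(c, dtype=float)
    cn = c**n
    return r_max * cn / (cn + c50**n) + r0


def _residuals(theta, contrasts, peaks):
    return naka_rushton(contrasts, theta) - peaks


def fit_naka_rushton(contrasts, peaks, multistart_n=(1.0, 2.0, 4.0)) -> NakaRushtonFit:
    """Bounded nonlinear least-squares fit with multi-start over the slope
    exponent.

    Initialization: ``R0 = min(peaks)``, ``R_max = range``, ``c50 = median
    contrast``; bounds ``R_max ∈ [0, 10·range]``, ``c50 ∈ (0.01, 1]``,
    ``n ∈ (0.1, 10]``, ``R0`` free. All-equal peaks are a degenerate case
    reported with ``r_squared = NaN`` and a flag.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    if contrasts.size < 4:
        raise ValueError(f"need >= 4 (contrast, peak) pairs, got {contrasts.size}")
    if np.unique(contrasts).size != contrasts.size:
        raise ValueError("contrasts must be distinct")

    rng_span = float(peaks.max() - peaks.min())
    degenerate = rng_span == 0.0
    span = rng_span if rng_span > 0 else max(abs(peaks.max()), 1.0)
    lo = np.array([0.0, 0.01, 0.1, -np.inf])
    hi = np.array([10.0 * span, 1.0, 10.0, np.inf])
    c50_init = float(np.clip(np.median(contrasts), 0.011, 1.0))

    best = None
    converged = False
    for n0 in multistart_n:
        theta0 = np.clip(
            np.array([rng_span if rng_span > 0 else span, c50_init, n0,
                      float(peaks.min())]),
            lo, np.where(np.isinf(hi), np.inf, hi),
        )
        try:
            sol = least_squares(
                _residuals, theta0, bounds=(lo, hi), args=(contrasts, peaks),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        converged = converged or sol.success
    if best is None:
        raise RuntimeError("Naka-Rushton optimization failed from every start")

    resid = _residuals(best.x, contrasts, peaks)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((peaks - peaks.mean()) ** 2))
    # R^2 is reported whenever the response range is non-degenerate; the
    # five-contrast design leaves one residual dof, which is the standard
    # usage for these curves.
    r2 = np.nan if (degenerate or ss_tot == 0) else 1.0 - ss_res / ss_tot
    return NakaRushtonFit(
        r_max=float(best.x[0]),
        c50=float(best.x[1]),
        n=float(best.x[2]),
        r0=float(best.x[3]),
        r_squared=r2,
        converged=bool(converged),
        n_points=int(contrasts.size),
        degenerate=degenerate,
    )


def normalize_and_refit(peaks_by_contrast: dict, multistart_n=(1.0, 2.0, 4.0)):
    """Scale a condition's peak values by its own 100%-contrast maximum and
    refit.

    ``peaks_by_contrast`` maps contrast fraction → peak value and must
    contain contrast 1.0. Returns ``(normalized peaks dict, NakaRushtonFit)``.
    Used to test whether suppressed tuning collapses onto control tuning
    under pure response gain.
    """
    if 1.0 not in peaks_by_contrast:
        raise ValueError("100%-contrast condition required for normalization")
    ref = float(peaks_by_contrast[1.0])
    if ref == 0:
        raise ValueError("zero maximum at 100% contrast; cannot normalize")
    scaled = {c: v / ref for c, v in peaks_by_contrast.items()}
    contrasts = np.array(sorted(scaled))
    vals = np.array([scaled[c] for c in contrasts])
    return scaled, fit_naka_rushton(contrasts, vals, multistart_n=multistart_n)


def response_latency(
    trace: np.ndarray,
    onset: float,
    rate: float,
    baseline_window: float = 0.7,
    n_consecutive: int = 2,
) -> float | None:
    """Time after ``onset`` at which activity first exceeds baseline mean +
    2·SD for at least ``n_consecutive`` samples; ``None`` if never crossed.

    The baseline is the ``baseline_window`` seconds immediately before onset.
    """
    trace = np.asarray(trace, dtype=float)
    i_on = int(round(onset * rate))
    i0 = max(0, i_on - int(round(baseline_window * rate)))
    base = trace[i0:i_on]
    if base.size < 2:
        raise ValueError("baseline window too short before onset")
    thresh = base.mean() + 2.0 * base.std(ddof=0)
    above = trace[i_on:] >= thresh
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_consecutive:
            return (i - n_consecutive + 1) / rate
    return None


def response_duration(
    trace: np.ndarray,
    window: tuple[float, float],
    rate: float,
) -> tuple[float, bool]:
    """Total time within ``window`` during which activity exceeds 50% of the
    in-window peak (half-open sample counting × frame period).

    Returns ``(duration_s, ok)``; a nonpositive peak yields duration 0 with
    ``ok=False``.
    """
    from .protocol import time_to_frames

    trace = np.asarray(trace, dtype=float)
    i0, i1 = time_to_frames(window[0], window[1], rate, len(trace))
    seg = trace[i0:i1]
    if seg.size == 0:
        return 0.0, False
    peak = seg.max()
    if peak <= 0:
        return 0.0, False
    return float(np.count_nonzero(seg > 0.5 * peak)) / rate, True
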