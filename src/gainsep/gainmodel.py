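"""Gain decomposition of photostimulated visual responses.

The model treats the control response as the photostimulated response scaled
back up by the serotonergically induced gain ``g``:

    V = g · (E_ph + S_ph),    g = magnitude(V) / magnitude(V_ph) > 1
                              whenever photostimulation is net-suppressive,

where ``E_ph`` is the evoked component (V_ph − S_ph, trialwise) and the
baseline component is approximated by the spontaneous-with-photostimulation
trace ``S_ph``. Expanding,

    V = g·E_ph + g·S_ph

so ``g`` sets the relative weights of the evoked (``g·E_ph``) and baseline
(``g·S_ph``) components. The magnitude — baseline-independent by
construction — isolates the evoked gain, so ``g`` is estimated from
magnitude ratios; the 100%-contrast peak ratio is reported as a pooled
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import ComponentMetrics, StimulusWindows, _window_mean
from .protocol import ProtocolSpec

__all__ = [
    "GainDecomposition",
    "estimate_gain",
    "component_weights",
    "reconstruct",
    "compare_states",
]


@dataclass
class GainDecomposition:
    """Per-contrast gain and component weights for one state."""

    contrasts: np.ndarray
    g: np.ndarray  # per-contrast gain (NaN where V_ph magnitude <= 0)
    g_pooled: float  # from the 100%-contrast peak ratio
    evoked_weight: np.ndarray  # g × magnitude(E_ph)
    baseline_weight_peak: np.ndarray  # g × S_ph at the control peak time
    baseline_weight_window: np.ndarray  # g × mean S_ph over w_ph
    reconstruction: np.ndarray  # evoked_weight + baseline_weight_peak
    state: str = "anesthetized"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.state,
                "contrast": self.contrasts,
                "g": self.g,
                "evoked_weight": self.evoked_weight,
                "baseline_weight_peak": self.baseline_weight_peak,
                "baseline_weight_window": self.baseline_weight_window,
                "reconstruction": self.reconstruction,
            }
        )


def estimate_gain(
    control_metrics: dict,
    ph_metrics: dict,
    stimulus_index: int = 0,
):
    """Per-contrast gain ``g = magnitude(V)/magnitude(V_ph)`` plus the pooled
    estimate from the 100%-contrast amplitude-peak ratio.

    ``control_metrics``/``ph_metrics`` map contrast → ComponentMetrics (one
    stimulus per trial in the contrast design; ``stimulus_index`` selects the
    stimulus otherwise). Contrasts with nonpositive V_ph magnitude yield NaN.
    """
    contrasts = sorted(control_metrics, reverse=True)
    g = {}
    for c in contrasts:
        mv = control_metrics[c].magnitude[stimulus_index]
        if mv <= 0:
            raise ValueError(f"control magnitude at contrast {c} is not positive")
        mph = ph_metrics[c].magnitude[stimulus_index]
        g[c] = mv / mph if mph > 0 else np.nan
    if 1.0 in control_metrics:
        a = control_metrics[1.0].amplitude[stimulus_index]
        b = ph_metrics[1.0].amplitude[stimulus_index]
        pooled = a / b if b > 0 else np.nan
    else:
        pooled = np.nan
    return g, float(pooled)


def component_weights(
    g: dict,
    eph_metrics: dict,
    sph_trace: np.ndarray,
    windows_by_contrast: dict,
    protocol: ProtocolSpec,
    g_pooled: float = np.nan,
    state: str = "anesthetized",
    stimulus_index: int = 0,
) -> GainDecomposition:
    """Evoked and baseline component weights per contrast.

    ``evoked_weight = g·magnitude(E_ph)``; the baseline weight is
    ``g·S_ph`` sampled at the control peak time (and, as the alternative
    report, averaged over the photostimulation window). The reconstruction
    ``evoked_weight + baseline_weight_peak`` approximates the control
    amplitude at the peak.
    """
    sph_trace = np.asarray(sph_trace, dtype=float)
    rate = protocol.frame_rate
    contrasts = sorted(g, reverse=True)
    gv, ev, bp, bw, rec = [], [], [], [], []
    for c in contrasts:
        gc = g[c]
        win = windows_by_contrast[c]
        t_pk = win.peak_times[stimulus_index]
        i_pk = min(int(round(t_pk * rate)), len(sph_trace) - 1)
        sph_at_pk = float(sph_trace[i_pk])
        sph_win = _window_mean(sph_trace, win.w_ph, rate)
        me = eph_metrics[c].magnitude[stimulus_index]
        gv.append(gc)
        ev.append(gc * me)
        bp.append(gc * sph_at_pk)
        bw.append(gc * sph_win)
        rec.append(gc * me + gc * sph_at_pk)
    return GainDecomposition(
        contrasts=np.asarray(contrasts, dtype=float),
        g=np.asarray(gv),
        g_pooled=float(g_pooled),
        evoked_weight=np.asarray(ev),
        baseline_weight_peak=np.asarray(bp),
        baseline_weight_window=np.asarray(bw),
        reconstruction=np.asarray(rec),
        state=state,
    )


def reconstruct(g: float, eph_trace: np.ndarray, sph_trace: np.ndarray):
    """Trace-level reconstruction ``V̂(t) = g·(E_ph(t) + S_ph(t))``."""
    return g * (np.asarray(eph_trace, dtype=float) + np.asarray(sph_trace, dtype=float))


def compare_states(
    awake: GainDecomposition,
    anesthetized: GainDecomposition,
    awake_samples: dict | None = None,
    anesthetized_samples: dict | None = None,
    awake_peak_times: np.ndarray | None = None,
    anesthetized_peak_times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-contrast awake-vs-anesthetized comparison table.

    Columns: gain, magnitude-suppression difference (via 1/g), baseline
    weights, and optionally two-sample t tests on per-subject samples
    (``{contrast: 1-D array}`` per state) and a peak-time comparison.
    """
    from .stats import t_tests

    if not np.array_equal(awake.contrasts, anesthetized.contrasts):
        raise ValueError("states analyzed with different contrast sets")
    rows = []
    for i, c in enumerate(awake.contrasts):
        row = {
            "contrast": c,
            "g_awake": awake.g[i],
            "g_anesthetized": anesthetized.g[i],
            "g_diff": awake.g[i] - anesthetized.g[i],
            "suppression_awake": 1.0 / awake.g[i] if awake.g[i] else np.nan,
            "suppression_anesthetized": (
                1.0 / anesthetized.g[i] if anesthetized.g[i] else np.nan
            ),
            "baseline_weight_awake": awake.baseline_weight_peak[i],
            "baseline_weight_anesthetized": anesthetized.baseline_weight_peak[i],
        }
        if awake_samples is not None and anesthetized_samples is not None:
            res = t_tests(
                awake_samples[c],
                anesthetized_samples[c],
                kind="two_sample",
                side="two-sided",
            )
            row["p_two_sample"] = res.p_raw
        rows.append(row)
    df = pd.DataFrame(rows)
    if awake_peak_times is not None and anesthetized_peak_times is not None:
        df.attrs["peak_time_diff_s"] = float(
            np.mean(awake_peak_times) - np.mean(anesthetized_peak_times)
        )
    return df
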