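"""Stimulus windows, amplitude/baseline/magnitude metrics, and isolation of
the evoked component by trialwise subtraction.

Definitions (all on normalized ROI traces or unit-averaged rate traces):

* **amplitude** — mean over ``w1``, a 400 ms window centered on the response
  peak of each stimulus;
* **baseline** — mean over ``w2``, the 200 ms window immediately before each
  stimulus onset;
* **magnitude** — ``|amplitude − baseline|``, a baseline-independent measure
  of response gain.

Peak times are located once on the control (no-photostimulation) condition
and reused for photostimulated conditions of the same dataset, so ``w1`` is
identical across conditions — a requirement for paired comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import SpikeCountMatrix
from .protocol import ConditionLabel, ProtocolSpec, time_to_frames

__all__ = [
    "StimulusWindows",
    "ComponentMetrics",
    "normalize_to_first_peak",
    "locate_windows",
    "compute_metrics",
    "evoked_component",
    "normalize_mua",
]

PEAK_SEARCH_WINDOW = 1.0  # s after onset; responses peak at ~0.3-0.45 s
W1_HALF = 0.2  # s on each side of the peak
W2_LEN = 0.2  # s before onset


@dataclass
class StimulusWindows:
    """Per-stimulus analysis windows (seconds, half-open)."""

    peak_times: list  # t_pk per stimulus
    w1: list  # [t_pk - 0.2, t_pk + 0.2)
    w2: list  # [onset - 0.2, onset)
    w_ph: tuple  # photostimulation window
    w_red: tuple | None = None  # early significant-suppression window

    def __post_init__(self):
        for (a, b), t in zip(self.w1, self.peak_times):
            assert b - a <= 2 * W1_HALF + 1e-9
        if self.w_red is not None:
            on, off = self.w_ph
            if not (on <= self.w_red[0] and self.w_red[1] <= off):
                raise ValueError("w_red must lie within the photostimulation window")


@dataclass
class ComponentMetrics:
    """Per-stimulus amplitude/baseline/magnitude/peak-time table."""

    amplitude: np.ndarray
    baseline: np.ndarray
    magnitude: np.ndarray
    peak_time: np.ndarray
    condition: ConditionLabel | str | None = None

    def __post_init__(self):
        n = len(self.amplitude)
        if not (len(self.baseline) == len(self.magnitude) == len(self.peak_time) == n):
            raise ValueError("metric arrays must share length")

    def to_frame(self):
        import pandas as pd

        name = getattr(self.condition, "name", self.condition)
        return pd.DataFrame(
            {
                "condition": name,
                "stimulus_index": np.arange(len(self.amplitude)),
                "amplitude": self.amplitude,
                "baseline": self.baseline,
                "magnitude": self.magnitude,
                "peak_time_s": self.peak_time,
            }
        )


def normalize_to_first_peak(
    traces: dict,
    protocol: ProtocolSpec,
    control: str = "V",
):
    """Divide every trace by the control condition's first-stimulus peak.

    The peak is the maximum of the control trial-averaged trace within
    ``[onset_0, onset_0 + 1 s)``. Returns ``(normalized dict, scale factor)``.
    """
    if control not in traces:
        raise ValueError(f"control condition {control!r} missing")
    avg = np.atleast_2d(np.asarray(traces[control])).mean(axis=0)
    onset = protocol.stim_onsets[0]
    i0, i1 = time_to_frames(
        onset, onset + PEAK_SEARCH_WINDOW, protocol.frame_rate, len(avg)
    )
    peak = float(avg[i0:i1].max())
    if peak <= 0:
        raise ValueError(f"nonpositive first-stimulus peak ({peak}); cannot normalize")
    return {c: np.asarray(v) / peak for c, v in traces.items()}, 1.0 / peak


def locate_windows(
    trace: np.ndarray,
    protocol: ProtocolSpec,
    significance_mask: np.ndarray | None = None,
) -> StimulusWindows:
    """Locate per-stimulus peak times and windows on a control trace.

    ``t_pk`` is the time of the maximum within ``[onset, onset + 1 s)``,
    earliest-sample tie-break; flat segments produce a warning. ``w_red``,
    when a per-frame corrected-significance mask is given, is the longest
    contiguous significant run starting at the first significant frame after
    photostimulation onset.
    """
    trace = np.asarray(trace)
    rate = protocol.frame_rate
    n = len(trace)
    peak_times, w1, w2 = [], [], []
    for onset in protocol.stim_onsets:
        i0, i1 = time_to_frames(onset, onset + PEAK_SEARCH_WINDOW, rate, n)
        seg = trace[i0:i1]
        if seg.size == 0:
            warnings.warn(f"stimulus at {onset} s beyond trace end; skipped window")
            peak_times.append(onset)
            w1.append((onset, onset))
            w2.append((max(onset - W2_LEN, 0.0), onset))
            continue
        if np.allclose(seg, seg[0]):
            warnings.warn(
                f"flat trace in peak window of stimulus at {onset} s; "
                "using onset as peak time"
            )
            t_pk = onset
        else:
            t_pk = (i0 + int(np.argmax(seg))) / rate
        peak_times.append(t_pk)
        a, b = t_pk - W1_HALF, t_pk + W1_HALF
        if b > protocol.trial_duration:
            warnings.warn(f"w1 for stimulus at {onset} s truncated at trial end")
            b = protocol.trial_duration
        w1.append((max(a, 0.0), b))
        w2.append((max(onset - W2_LEN, 0.0), onset))

    w_red = None
    if significance_mask is not None:
        m = np.asarray(significance_mask, dtype=bool)
        ph0, ph1 = protocol.photostim_window
        j0, j1 = time_to_frames(ph0, ph1, rate, len(m))
        idx = np.flatnonzero(m[j0:j1])
        if idx.size:
            start = j0 + idx[0]
            run = start
            while run + 1 < j1 and m[run + 1]:
                run += 1
            w_red = (start / rate, (run + 1) / rate)
    return StimulusWindows(
        peak_times=peak_times,
        w1=w1,
        w2=w2,
        w_ph=protocol.photostim_window,
        w_red=w_red,
    )


def _window_mean(trace, window, rate):
    i0, i1 = time_to_frames(window[0], window[1], rate, len(trace))
    if i1 <= i0:
        return np.nan
    return float(np.mean(trace[i0:i1]))


def compute_metrics(
    trace: np.ndarray,
    windows: StimulusWindows,
    rate: float,
    condition=None,
) -> ComponentMetrics:
    """Amplitude (mean over w1), baseline (mean over w2), and magnitude
    ``|amplitude − baseline|`` per stimulus."""
    trace = np.asarray(trace)
    amp = np.array([_window_mean(trace, w, rate) for w in windows.w1])
    base = np.array([_window_mean(trace, w, rate) for w in windows.w2])
    return ComponentMetrics(
        amplitude=amp,
        baseline=base,
        magnitude=np.abs(amp - base),
        peak_time=np.asarray(windows.peak_times, dtype=float),
        condition=condition,
    )


def evoked_component(
    vph_trials: np.ndarray,
    sph_trials: np.ndarray,
    pairing: str = "index",
):
    """Isolate the evoked component ``E_ph = V_ph − S_ph`` trialwise.

    With equal trial counts and ``pairing="index"`` (conditions interleaved,
    trial i paired with trial i) the shared ongoing fluctuation cancels
    exactly; otherwise, or with ``pairing="mean"``, each V_ph trial has the
    S_ph trial mean subtracted. Returns ``(per-trial E_ph, trial average,
    pairing used)``.
    """
    vph = np.atleast_2d(np.asarray(vph_trials, dtype=float))
    sph = np.atleast_2d(np.asarray(sph_trials, dtype=float))
    if sph.shape[0] == 0:
        raise ValueError("no S_ph trials to subtract")
    if pairing == "index" and vph.shape[0] == sph.shape[0]:
        eph = vph - sph
        used = "index"
    else:
        eph = vph - sph.mean(axis=0, keepdims=True)
        used = "mean"
    return eph, eph.mean(axis=0), used


# -- MUA normalization path -------------------------------------------------


def normalize_mua(
    counts: SpikeCountMatrix,
    protocol: ProtocolSpec,
    condition: ConditionLabel | None = None,
    first_stim_amplitude: float | None = None,
    norm_window: float = 1.0,
):
    """Normalize binned spike counts the way the imaging traces are treated.

    Trial-averaged per-unit traces are divided by the unit's mean over the
    first second of recording (spontaneous conditions), or have that mean
    subtracted and are then divided by the control first-stimulus response
    amplitude (evoked conditions). Units with a zero 1-s baseline are flagged
    and excluded from ratio-normalized output.

    Returns ``(unit_traces, kept_unit_ids, flagged_unit_ids)`` where
    ``unit_traces`` is (kept units, n_bins).
    """
    cond = condition or counts.condition
    if cond is None:
        raise ValueError("condition required")
    rates = counts.rates().mean(axis=2)  # (unit, bin), Hz, trial-averaged
    n_norm = int(round(norm_window / counts.bin_width))
    base = rates[:, :n_norm].mean(axis=1)
    evoked_path = cond.stimulus == "V"
    if evoked_path:
        out = rates - base[:, None]
        if first_stim_amplitude is not None:
            if first_stim_amplitude <= 0:
                raise ValueError("first-stimulus amplitude must be positive")
            out = out / first_stim_amplitude
        return out, list(counts.unit_ids), []
    flagged = [uid for uid, b in zip(counts.unit_ids, base) if b == 0]
    keep = base != 0
    out = rates[keep] / base[keep, None]
    kept = [uid for uid, k in zip(counts.unit_ids, keep) if k]
    return out, kept, flagged
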