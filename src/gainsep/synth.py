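"""Synthetic trial movies and spike counts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* an ongoing ("spontaneous") activity process — an Ornstein-Uhlenbeck-style
  low-pass Gaussian process with configurable standard deviation and
  correlation time, shared across simultaneously recorded conditions of the
  same trial (conditions were interleaved in the experiments, so trialwise
  subtraction of the blank-photostimulation condition removes the shared
  ongoing fluctuation);
* evoked calcium transients — a fixed kernel convolved with the stimulus
  onset train, scaled by the Naka-Rushton value at the trial's contrast;
* multiplicative gain factors ``g_s`` (spontaneous) and ``g_e`` (evoked) plus
  an additive offset, all switching on during the photostimulation window —
  the ground truth that the suppression regression and gain model must
  recover;
* a slow late calcium ramp (imaging only — the spiking path never carries
  it, mirroring the dissociation between calcium signal and spiking);
* heartbeat / respiration sinusoids, a 20 Hz photostimulation artifact
  confined to a corner block of the frame, smooth illumination vignetting and
  per-pixel Gaussian noise.

Setting artifacts, late rise and noise to zero makes the ROI-averaged trace
an exact affine function of the injected signal, which the closed-form
helpers below expose for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SpikeCountMatrix, TrialStack, write_spike_counts, write_trial_stack
from .protocol import (
    CORE_CONDITIONS,
    ConditionLabel,
    ProtocolSpec,
    write_protocol,
)

__all__ = [
    "GroundTruth",
    "anesthetized_ground_truth",
    "awake_ground_truth",
    "naka_rushton_value",
    "evoked_waveform",
    "roi_signal",
    "ou_process",
    "generate_trial_stack",
    "generate_spike_counts",
    "generate_roi_traces",
    "generate_cohort",
    "simulate_prepost_cohort",
    "roi_affine_coefficients",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters for one synthetic subject.

    Gains are multiplicative factors applied during the photostimulation
    window; ``evoked_gain``/``spont_gain`` in [0, 1] are suppressive,
    1 reproduces control statistics. ``spont_offset`` is an additive shift
    (Δf/f for imaging, Hz for spike counts). ``tuning`` is
    ``(R_max, c50, n, R0)`` of the contrast response; ``kernel`` is
    ``(rise_tau, decay_tau, peak_delay)`` in seconds; ``late_rise`` is
    ``(onset_s_after_photostim, slope_per_s)`` and applies to imaging only.
    """

    evoked_gain: float = 0.52
    spont_gain: float = 0.6
    spont_offset: float = -0.05
    tuning: tuple[float, float, float, float] = (1.0, 0.25, 2.0, 0.0)
    kernel: tuple[float, float, float] = (0.05, 0.35, 0.44)
    late_rise: tuple[float, float] = (4.0, 0.02)
    spont_process: tuple[float, float] = (0.05, 1.0)  # (std, correlation_time s)
    artifacts: tuple[float, float, float, float] = (10.0, 3.0, 0.0, 0.25)
    # (heartbeat_hz, respiration_hz, photostim_artifact_amp, corner_fraction)
    heartbeat_amp: float = 0.0
    respiration_amp: float = 0.0
    illumination: tuple[float, float] = (1000.0, 0.3)  # (base, vignette)
    noise_std: float = 0.0
    image_shape: tuple[int, int] = (64, 64)
    roi_sigma_frac: float = 0.15
    base_rate_range: tuple[float, float] = (0.5, 25.0)  # Hz, spiking units
    evoked_rate_scale: float = 1.0
    paired_spontaneous: bool = True
    state: str = "anesthetized"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.evoked_gain) or not (0 <= self.spont_gain):
            raise ValueError("gains must be nonnegative")
        if self.evoked_gain > 1 or self.spont_gain > 1:
            import warnings

            warnings.warn(
                "gain > 1 is outside the suppressive regime", stacklevel=2
            )
        if self.state not in ("awake", "anesthetized"):
            raise ValueError(f"unknown state {self.state!r}")

    def with_drug(self, drug: str) -> "GroundTruth":
        """Parameter regime under receptor antagonists.

        MDL (2A antagonist) moves the evoked gain close to 1 and attenuates
        the late calcium ramp; WAY (1A antagonist) abolishes the spontaneous
        suppression (gain 1, offset 0).
        """
        if drug in ("none", "vehicle"):
            return self
        if drug == "MDL":
            onset, slope = self.late_rise
            return replace(self, evoked_gain=0.9, late_rise=(onset, slope * 0.25))
        if drug == "WAY":
            return replace(self, spont_gain=1.0, spont_offset=0.0)
        raise ValueError(f"unknown drug {drug!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


def anesthetized_ground_truth(seed: int = 0, **overrides) -> GroundTruth:
    """Anesthetized-state defaults: stronger gain suppression, larger and
    slower ongoing fluctuations, later evoked peak (~440 ms)."""
    kw: dict = dict(state="anesthetized", seed=seed)
    kw.update(overrides)
    return GroundTruth(**kw)


def awake_ground_truth(seed: int = 0, **overrides) -> GroundTruth:
    """Awake-state defaults: weaker gain suppression (magnitude ratio ~0.78),
    smaller ongoing fluctuations, earlier evoked peak (~310 ms)."""
    kw: dict = dict(
        state="awake",
        evoked_gain=0.78,
        spont_offset=-0.02,
        spont_process=(0.03, 1.0),
        kernel=(0.05, 0.35, 0.31),
        seed=seed,
    )
    kw.update(overrides)
    return GroundTruth(**kw)


# -- deterministic building blocks ------------------------------------------


def naka_rushton_value(c, tuning) -> float:
    """Contrast response ``R_max c^n / (c^n + c50^n) + R0``."""
    r_max, c50, n, r0 = tuning
    c = np.asarray(c, dtype=float)
    return r_max * c**n / (c**n + c50**n) + r0


def _kernel(t, rise_tau, decay_tau, peak_delay):
    """Difference-of-exponentials transient, unit peak exactly at
    ``peak_delay`` seconds after stimulus onset."""
    if decay_tau <= rise_tau:
        raise ValueError("decay_tau must exceed rise_tau")
    # natural peak time of exp(-t/d) - exp(-t/r), then shift to peak_delay
    t_nat = np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (
        decay_tau - rise_tau
    )
    shift = peak_delay - t_nat
    ts = np.maximum(np.asarray(t) - shift, 0.0)
    k = np.exp(-ts / decay_tau) - np.exp(-ts / rise_tau)
    peak = np.exp(-t_nat / decay_tau) - np.exp(-t_nat / rise_tau)
    return k / peak


def evoked_waveform(gt: GroundTruth, protocol: ProtocolSpec, contrast: float):
    """Noise-free evoked trace: kernel summed over stimulus onsets, scaled by
    the Naka-Rushton value at ``contrast``. Gain not applied."""
    t = protocol.time_axis()
    amp = float(naka_rushton_value(contrast, gt.tuning))
    rise, decay, delay = gt.kernel
    out = np.zeros_like(t)
    for onset in protocol.stim_onsets:
        rel = t - onset
        m = rel >= 0
        out[m] += _kernel(rel[m], rise, decay, delay)
    return amp * out


def _late_rise(gt: GroundTruth, protocol: ProtocolSpec):
    """Slow calcium ramp: starts ``onset`` s after photostimulation onset,
    grows linearly during photostimulation, holds afterwards."""
    onset_after, slope = gt.late_rise
    t = protocol.time_axis()
    on, off = protocol.photostim_window
    t0 = on + onset_after
    return slope * np.clip(t - t0, 0.0, max(off - t0, 0.0))


def ou_process(n, dt, std, correlation_time, rng):
    """Stationary Ornstein-Uhlenbeck sample path (exact discretization)."""
    phi = np.exp(-dt / correlation_time)
    x = np.empty(n)
    x[0] = rng.normal(0.0, std)
    innov = rng.normal(0.0, std * np.sqrt(1.0 - phi**2), size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i - 1]
    return x


def _trial_rng(gt: GroundTruth, purpose: str, trial: int, condition_name: str = ""):
    """Deterministic per-trial generator; the spontaneous stream depends only
    on (seed, trial) so interleaved conditions share one ongoing realization."""
    import zlib

    entropy = [gt.seed, trial, zlib.crc32(purpose.encode())]
    if condition_name:
        entropy.append(zlib.crc32(condition_name.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def roi_signal(
    gt: GroundTruth,
    protocol: ProtocolSpec,
    condition: ConditionLabel,
    spont: np.ndarray | None = None,
):
    """The injected ROI signal ``s(t)``:

    ``s = spont·G_s + offset·1_ph + evoked·G_e + late``, where the gain
    profiles equal 1 outside the photostimulation window and
    (``spont_gain``, ``evoked_gain``) inside it (photostim-off conditions:
    identically 1).
    """
    n = protocol.n_frames
    ph = condition.photostim == "on"
    mask = protocol.photostim_mask() if ph else np.zeros(n, dtype=bool)
    g_s = np.where(mask, gt.spont_gain, 1.0)
    g_e = np.where(mask, gt.evoked_gain, 1.0)
    s = np.zeros(n)
    if spont is not None:
        s += np.asarray(spont) * g_s
    if ph:
        s += gt.spont_offset * mask
    if condition.stimulus == "V":
        contrast = condition.contrast if condition.contrast is not None else 1.0
        s += evoked_waveform(gt, protocol, contrast) * g_e
    if ph and condition.modality == "imaging":
        s += _late_rise(gt, protocol)
    return s


def _spont_realization(gt, protocol, condition, trial):
    std, tau = gt.spont_process
    if std == 0:
        return np.zeros(protocol.n_frames)
    cond_key = "" if gt.paired_spontaneous else condition.name
    rng = _trial_rng(gt, "spont", trial, cond_key)
    return ou_process(protocol.n_frames, 1.0 / protocol.frame_rate, std, tau, rng)


# -- spatial model ----------------------------------------------------------


def illumination_map(gt: GroundTruth):
    """Smooth spatial gain: base level with radial vignetting."""
    h, w = gt.image_shape
    base, vignette = gt.illumination
    y, x = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r2 = ((y - cy) / h) ** 2 + ((x - cx) / w) ** 2
    return base * (1.0 - vignette * r2 / 0.5)


def roi_profile(gt: GroundTruth):
    """Soft Gaussian responsive-region profile in [0, 1] (slightly off-center
    so row-major tie-breaks are never exercised by accident)."""
    h, w = gt.image_shape
    y, x = np.mgrid[0:h, 0:w]
    cy, cx = 0.45 * (h - 1), 0.55 * (w - 1)
    sig = gt.roi_sigma_frac * min(h, w)
    return np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2 * sig**2)))


def roi_affine_coefficients(gt: GroundTruth, mask: np.ndarray):
    """With artifacts/noise off, the ROI average of a raw stack is
    ``a + b·s(t)``; returns ``(a, b)`` for a boolean pixel mask."""
    illum = illumination_map(gt)
    prof = roi_profile(gt)
    a = float(illum[mask].mean())
    b = float((illum * prof)[mask].mean())
    return a, b


def generate_trial_stack(
    gt: GroundTruth,
    protocol: ProtocolSpec,
    condition: ConditionLabel,
    trial: int,
) -> TrialStack:
    """One synthetic trial movie.

    ``pixels = illum·(1 + roi_profile·s(t)) + heartbeat + respiration +
    corner photostimulation artifact + noise``, clipped at zero.
    """
    t = protocol.time_axis()
    spont = _spont_realization(gt, protocol, condition, trial)
    s = roi_signal(gt, protocol, condition, spont)
    illum = illumination_map(gt)
    prof = roi_profile(gt)
    stack = illum[None] * (1.0 + prof[None] * s[:, None, None])

    hb_hz, resp_hz, ph_amp, corner_frac = gt.artifacts
    if gt.heartbeat_amp or gt.respiration_amp:
        rng = _trial_rng(gt, "phase", trial, condition.name)
        phases = rng.uniform(0, 2 * np.pi, size=2)
        wave = gt.heartbeat_amp * np.sin(
            2 * np.pi * hb_hz * t + phases[0]
        ) + gt.respiration_amp * np.sin(2 * np.pi * resp_hz * t + phases[1])
        stack += wave[:, None, None]
    if ph_amp and condition.photostim == "on":
        # 20 Hz square wave confined to the lower-left corner block
        sq = (np.sin(2 * np.pi * protocol.photostim_freq * t) >= 0).astype(float)
        sq *= protocol.photostim_mask()
        h, w = gt.image_shape
        by, bx = max(1, int(h * corner_frac)), max(1, int(w * corner_frac))
        stack[:, h - by :, :bx] += ph_amp * sq[:, None, None]
    if gt.noise_std:
        rng = _trial_rng(gt, "noise", trial, condition.name)
        stack = stack + rng.normal(0.0, gt.noise_std, size=stack.shape)
    np.clip(stack, 0.0, None, out=stack)
    return TrialStack(pixels=stack, condition=condition, trial=trial)


def generate_roi_traces(
    gt: GroundTruth,
    protocol: ProtocolSpec,
    condition: ConditionLabel,
    n_trials: int,
    noise_std: float = 0.0,
):
    """ROI-level shortcut: per-trial signal traces ``s(t)`` (plus optional
    white noise), bypassing the spatial model. Shares the spontaneous stream
    with other conditions exactly like the movie path."""
    out = np.empty((n_trials, protocol.n_frames))
    for i in range(n_trials):
        spont = _spont_realization(gt, protocol, condition, i)
        out[i] = roi_signal(gt, protocol, condition, spont)
        if noise_std:
            rng = _trial_rng(gt, "trace-noise", i, condition.name)
            out[i] += rng.normal(0.0, noise_std, size=protocol.n_frames)
    return out


# -- spiking path -----------------------------------------------------------


def generate_spike_counts(
    gt: GroundTruth,
    protocol: ProtocolSpec,
    condition: ConditionLabel,
    n_units: int,
    n_trials: int = 10,
    bin_width: float = 0.2,
) -> SpikeCountMatrix:
    """Inhomogeneous-Poisson spike counts.

    ``rate(t) = base·G_s(t)·(1 + scale·evoked(t)·G_e(t)) + offset_Hz``,
    clipped at zero; no late-rise term ever enters the spiking path.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    cond = replace(condition, modality="mua")
    n_bins = int(round(protocol.trial_duration / bin_width))
    t = (np.arange(n_bins) + 0.5) * bin_width
    ph = cond.photostim == "on"
    on, off = protocol.photostim_window
    mask = ph & (t >= on) & (t < off) if ph else np.zeros(n_bins, dtype=bool)
    g_s = np.where(mask, gt.spont_gain, 1.0)
    g_e = np.where(mask, gt.evoked_gain, 1.0)
    if cond.stimulus == "V":
        contrast = cond.contrast if cond.contrast is not None else 1.0
        bin_proto = replace(protocol, frame_rate=1.0 / bin_width)
        ev = evoked_waveform(gt, bin_proto, contrast)[:n_bins]
    else:
        ev = np.zeros(n_bins)

    rng = _trial_rng(gt, "units", 0, cond.name)
    base = rng.uniform(*gt.base_rate_range, size=n_units)
    rate = base[:, None] * g_s[None, :] * (
        1.0 + gt.evoked_rate_scale * ev[None, :] * g_e[None, :]
    )
    rate = rate + gt.spont_offset * mask[None, :]
    np.clip(rate, 0.0, None, out=rate)
    counts = np.empty((n_units, n_bins, n_trials), dtype=np.int64)
    for trial in range(n_trials):
        trng = _trial_rng(gt, "spikes", trial, cond.name)
        counts[:, :, trial] = trng.poisson(rate * bin_width)
    return SpikeCountMatrix(
        counts=counts, bin_width=bin_width, unit_ids=tuple(range(n_units)),
        condition=cond,
    )


# -- cohort on disk ---------------------------------------------------------


def generate_cohort(
    ground_truths: list[GroundTruth],
    protocol: ProtocolSpec,
    out,
    n_trials: int = 10,
    conditions: tuple[ConditionLabel, ...] = CORE_CONDITIONS,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a full synthetic dataset: per-subject trial TIFFs + sidecars, a
    manifest CSV, the protocol, and a ground-truth JSON per subject."""
    if not ground_truths:
        raise ValueError("need at least one subject")
    out = Path(out)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)
    write_protocol(protocol, out / "protocol.json")
    rows = []
    for si, gt in enumerate(ground_truths):
        sub = out / f"sub-{si + 1:02d}"
        sub.mkdir(exist_ok=True)
        gt.to_json(sub / "ground_truth.json")
        for cond in conditions:
            for trial in range(n_trials):
                stack = generate_trial_stack(gt, protocol, cond, trial)
                fname = f"{cond.name}_trial{trial:03d}.tif"
                write_trial_stack(stack, sub / fname)
                rows.append(
                    {
                        "subject": sub.name,
                        "condition": cond.name,
                        "trial": trial,
                        "contrast": cond.contrast,
                        "path": str(Path(sub.name) / fname),
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# -- normalized-scale cohort simulator for the suppression regression -------


def simulate_prepost_cohort(
    g_s: float,
    offset: float,
    n_subjects: int = 8,
    n_units: int = 30,
    noise_std: float = 0.05,
    rng: np.random.Generator | int | None = None,
):
    """Pre/post mean-rate records on the normalized-rate scale.

    For each unit, ``fr_pre ~ U(0.1, 1)`` (rates normalized by the maximum
    pre-rate); without photostimulation ``fr_post = fr_pre + ε`` and with it
    ``fr_post = g_s·fr_pre + offset + ε``, ``ε ~ N(0, noise_std²)``. This is
    the generative model whose regression coefficients identify the ground
    truth exactly: ``b4 → g_s − 1`` and ``b2 → offset``.

    Returns a list of per-subject DataFrames with columns
    ``unit_id, fr_pre, fr_post, ph, subject_id``.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cohort = []
    for s in range(n_subjects):
        pre = rng.uniform(0.1, 1.0, size=n_units)
        rows = []
        for ph in (0, 1):
            mult = g_s if ph else 1.0
            add = offset if ph else 0.0
            post = mult * pre + add + rng.normal(0, noise_std, size=n_units)
            rows.append(
                pd.DataFrame(
                    {
                        "unit_id": np.arange(n_units),
                        "fr_pre": pre,
                        "fr_post": post,
                        "ph": ph,
                        "subject_id": s,
                    }
                )
            )
        cohort.append(pd.concat(rows, ignore_index=True))
    return cohort
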