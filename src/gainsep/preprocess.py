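"""Raw movie → artifact-reduced, ROI-averaged Δf/f traces.

Order of operations: Δf/f conversion (pre-stimulus division, blank
subtraction, blank-mean division) → optional ICA artifact rejection →
frame-wise spatial filtering (Gaussian smooth then Butterworth high-pass) →
ROI selection and spatial averaging. Each stage appends to a stage log so
downstream code can assert the order actually run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .protocol import ProtocolSpec, time_to_frames

__all__ = [
    "PreprocessError",
    "RoiTraceSet",
    "blank_normalized_mean",
    "compute_dff",
    "remove_artifacts_ica",
    "spatial_filter",
    "select_roi",
    "spatial_average",
    "preprocess_trials",
]

#: default artifact bands (Hz): heartbeat, respiration, photostimulation
DEFAULT_BANDS = (10.0, 3.0, 20.0)


class PreprocessError(ValueError):
    pass


@dataclass
class RoiTraceSet:
    """Per-condition ROI traces: trials × time arrays plus trial averages."""

    traces: dict  # condition name -> (n_trials, n_time) Δf/f
    roi_mask: np.ndarray
    sampling_rate: float
    normalization_record: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)

    def average(self, condition: str) -> np.ndarray:
        return np.asarray(self.traces[condition]).mean(axis=0)

    def __post_init__(self):
        lengths = {np.asarray(v).shape[-1] for v in self.traces.values()}
        if len(lengths) > 1:
            raise PreprocessError(f"trace length mismatch across conditions: {lengths}")


# -- Δf/f -------------------------------------------------------------------


def _prestim_normalize(pixels: np.ndarray, protocol: ProtocolSpec) -> np.ndarray:
    """Divide each pixel by its mean over the pre-stimulus normalization
    window (the first ``pre_record_norm_window`` seconds of recording)."""
    i0, i1 = time_to_frames(
        0.0, protocol.pre_record_norm_window, protocol.frame_rate, pixels.shape[0]
    )
    if i1 <= i0:
        raise PreprocessError("empty pre-stimulus normalization window")
    pre = pixels[i0:i1].mean(axis=0)
    bad = np.argwhere(pre == 0)
    if bad.size:
        y, x = bad[0]
        raise PreprocessError(
            f"zero pre-stimulus mean at pixel (y={y}, x={x}); cannot normalize"
        )
    return pixels / pre[None]


def blank_normalized_mean(blank_stacks, protocol: ProtocolSpec) -> np.ndarray:
    """Average of blank (spontaneous) trials, each pre-stimulus-normalized by
    the same rule applied to every other stack."""
    stacks = [s.pixels if hasattr(s, "pixels") else np.asarray(s) for s in blank_stacks]
    if not stacks:
        raise PreprocessError("no blank trials supplied")
    return np.mean([_prestim_normalize(s, protocol) for s in stacks], axis=0)


def compute_dff(stack, blank_mean: np.ndarray, protocol: ProtocolSpec) -> np.ndarray:
    """Relative fluorescence change.

    Per pixel: ``d = F / mean(F_pre)``; ``Δf/f = (d − blank) / mean_t(blank)``
    where ``blank`` is the pre-stimulus-normalized blank average. Identical
    stack and blank give exactly zero.
    """
    pixels = stack.pixels if hasattr(stack, "pixels") else np.asarray(stack)
    blank_mean = np.asarray(blank_mean)
    if pixels.shape != blank_mean.shape:
        raise PreprocessError(
            f"stack shape {pixels.shape} != blank shape {blank_mean.shape}"
        )
    d = _prestim_normalize(pixels, protocol)
    denom = blank_mean.mean(axis=0)
    if np.any(denom == 0):
        raise PreprocessError("blank temporal mean is zero at some pixel")
    return (d - blank_mean) / denom[None]


# -- ICA artifact rejection -------------------------------------------------


def _band_power_fraction(source: np.ndarray, rate: float, band_hz: float,
                         half_width: float = 0.5, floor_hz: float = 1.0) -> float:
    """Fraction of the source's oscillatory power (above ``floor_hz``) inside
    ``band_hz ± half_width``. Sub-floor power is excluded from the total so
    that slow signal content mixed into a component (e.g. the onset step of a
    gated artifact) does not mask a narrowband concentration."""
    freqs, psd = signal.periodogram(source, fs=rate)
    osc = freqs >= floor_hz
    total = psd[osc].sum()
    if total == 0:
        return 0.0
    sel = (freqs >= band_hz - half_width) & (freqs <= band_hz + half_width)
    return float(psd[sel & osc].sum() / total)


def remove_artifacts_ica(
    trial_stacks: list,
    protocol: ProtocolSpec,
    bands=DEFAULT_BANDS,
    threshold: float = 0.5,
    n_components: int = 8,
    seed: int = 0,
):
    """Temporal-ICA rejection of oscillatory artifacts.

    Each trial is decomposed into temporal independent components (FastICA on
    the time × pixel matrix); components whose power spectral density
    concentrates ≥ ``threshold`` of total power within ±0.5 Hz of any target
    band are zeroed before back-projection. Returns
    ``(cleaned_stacks, report)``; on decomposition failure the trial passes
    through unchanged with a warning flag in the report.
    """
    if len(trial_stacks) < 2:
        raise PreprocessError("ICA artifact removal needs at least 2 trials")
    bands = tuple(bands)
    report = {"bands": bands, "threshold": threshold, "trials": []}
    cleaned = []
    if not bands:
        for s in trial_stacks:
            cleaned.append(np.asarray(s.pixels if hasattr(s, "pixels") else s))
            report["trials"].append({"rejected": [], "passthrough": False})
        return cleaned, report

    from sklearn.decomposition import FastICA

    for ti, s in enumerate(trial_stacks):
        pixels = np.asarray(s.pixels if hasattr(s, "pixels") else s)
        nt = pixels.shape[0]
        flat = pixels.reshape(nt, -1)
        mean = flat.mean(axis=0, keepdims=True)
        x = flat - mean
        k = min(n_components, nt, x.shape[1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ica = FastICA(
                    n_components=k, random_state=seed, max_iter=1000,
                    tol=1e-3, whiten="unit-variance",
                )
                sources = ica.fit_transform(x)  # (time, k)
            rejected = []
            for ci in range(sources.shape[1]):
                for band in bands:
                    frac = _band_power_fraction(
                        sources[:, ci], protocol.frame_rate, band
                    )
                    if frac >= threshold:
                        rejected.append({"component": ci, "band_hz": band,
                                         "power_fraction": frac})
                        break
            keep = sources.copy()
            for r in rejected:
                keep[:, r["component"]] = 0.0
            recon = ica.inverse_transform(keep) + mean
            cleaned.append(recon.reshape(pixels.shape))
            report["trials"].append({"rejected": rejected, "passthrough": False})
        except Exception as exc:  # decomposition failure → pass-through
            warnings.warn(f"ICA failed on trial {ti}: {exc}; passing through")
            cleaned.append(pixels)
            report["trials"].append(
                {"rejected": [], "passthrough": True, "error": str(exc)}
            )
    return cleaned, report


# -- spatial filtering ------------------------------------------------------


def _butterworth_highpass_2d(frame: np.ndarray, cutoff_wavelength: float,
                             order: int) -> np.ndarray:
    """Frame-wise spatial high-pass with Butterworth magnitude response
    ``|H(f)| = [1 + (f_c/f)^(2·order)]^(−1/2)``, ``f_c = 1/cutoff_wavelength``
    cycles/px; the DC component is removed exactly."""
    h, w = frame.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    fc = 1.0 / cutoff_wavelength
    with np.errstate(divide="ignore"):
        hmag = 1.0 / np.sqrt(1.0 + (fc / np.where(f == 0, np.inf, f)) ** (2 * order))
    hmag.flat[0] = 0.0  # kill DC
    return np.real(np.fft.ifft2(np.fft.fft2(frame) * hmag))


def spatial_filter(
    stack: np.ndarray,
    smooth_sigma: float = 20.0,
    butter_order: int = 4,
    cutoff_wavelength: float | None = 33.0,
) -> np.ndarray:
    """Gaussian smoothing (σ in px) then Butterworth spatial high-pass,
    applied frame-wise. ``smooth_sigma=0`` and ``cutoff_wavelength=None``
    is the identity."""
    stack = np.asarray(stack, dtype=float)
    if cutoff_wavelength is not None and cutoff_wavelength <= 2:
        raise PreprocessError(
            f"cutoff wavelength {cutoff_wavelength} px is at or below the "
            "2 px Nyquist limit"
        )
    out = stack
    if smooth_sigma > 0:
        out = np.stack(
            [ndimage.gaussian_filter(f, smooth_sigma) for f in out]
        )
    if cutoff_wavelength is not None:
        out = np.stack(
            [_butterworth_highpass_2d(f, cutoff_wavelength, butter_order)
             for f in out]
        )
    return out


# -- ROI --------------------------------------------------------------------


def select_roi(evoked_map: np.ndarray, threshold_frac: float = 0.7) -> np.ndarray:
    """Automated responsive-region selection.

    The mask is the largest 4-connected component of pixels ≥
    ``threshold_frac`` × map maximum; size ties are broken in favor of the
    component containing the first row-major maximum pixel.
    """
    evoked_map = np.asarray(evoked_map)
    peak = evoked_map.max()
    if peak <= 0:
        raise PreprocessError("no responsive region: map maximum is not positive")
    thresh = evoked_map >= threshold_frac * peak
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n = ndimage.label(thresh, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    max_size = sizes.max()
    argmax_label = labels.flat[np.argmax(evoked_map)]
    if argmax_label > 0 and sizes[argmax_label - 1] == max_size:
        chosen = argmax_label
    else:
        chosen = int(np.argmax(sizes)) + 1  # first label among ties (row-major)
    return labels == chosen


def spatial_average(stack: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Unweighted per-frame mean over masked pixels."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise PreprocessError("empty ROI mask")
    pixels = stack.pixels if hasattr(stack, "pixels") else np.asarray(stack)
    return pixels[:, roi_mask].mean(axis=1)


# -- assembled stage --------------------------------------------------------


def preprocess_trials(
    stacks_by_condition: dict,
    protocol: ProtocolSpec,
    blank_condition: str = "S",
    control_condition: str = "V",
    use_ica: bool = False,
    ica_bands=DEFAULT_BANDS,
    smooth_sigma: float = 20.0,
    butter_order: int = 4,
    cutoff_wavelength: float | None = 33.0,
    roi_threshold: float = 0.7,
    response_window: float = 1.0,
    seed: int = 0,
) -> RoiTraceSet:
    """Full preprocessing on a dict ``{condition name: [TrialStack, ...]}``.

    The ROI is selected on the control condition's trial-averaged Δf/f,
    averaged over a response window after each stimulus onset.
    """
    if blank_condition not in stacks_by_condition:
        raise PreprocessError(f"missing blank condition {blank_condition!r}")
    stage_log = []
    blank = blank_normalized_mean(stacks_by_condition[blank_condition], protocol)

    dff = {}
    for cond, stacks in stacks_by_condition.items():
        dff[cond] = [compute_dff(s, blank, protocol) for s in stacks]
    stage_log.append("dff")

    ica_report = None
    if use_ica:
        for cond in dff:
            dff[cond], ica_report = remove_artifacts_ica(
                dff[cond], protocol, bands=ica_bands, seed=seed
            )
        stage_log.append("ica")

    if smooth_sigma > 0 or cutoff_wavelength is not None:
        for cond in dff:
            dff[cond] = [
                spatial_filter(s, smooth_sigma, butter_order, cutoff_wavelength)
                for s in dff[cond]
            ]
        stage_log.append("spatial_filter")

    if control_condition not in dff:
        raise PreprocessError(f"missing control condition {control_condition!r}")
    mean_control = np.mean(dff[control_condition], axis=0)
    resp = np.zeros(mean_control.shape[1:])
    for onset in protocol.stim_onsets:
        i0, i1 = time_to_frames(
            onset, onset + response_window, protocol.frame_rate,
            mean_control.shape[0],
        )
        resp += mean_control[i0:i1].mean(axis=0)
    mask = select_roi(resp, roi_threshold)
    stage_log.append("select_roi")

    traces = {
        cond: np.stack([spatial_average(s, mask) for s in stacks])
        for cond, stacks in dff.items()
    }
    stage_log.append("spatial_average")

    record = {"blank_condition": blank_condition, "roi_pixels": int(mask.sum())}
    if ica_report is not None:
        record["ica_report"] = ica_report
    return RoiTraceSet(
        traces=traces,
        roi_mask=mask,
        sampling_rate=protocol.frame_rate,
        normalization_record=record,
        stage_log=stage_log,
    )
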