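"""Trial protocol description and time/frame conventions.

A trial is a fixed-duration recording containing a train of brief visual
stimuli (drifting gratings) and, in photostimulated conditions, a window of
20 Hz blue-light pulses driving serotonergic neurons in the dorsal raphe.
Two protocol modes exist:

``train``
    the stimulus-train design: ten 200 ms gratings at 3 s intervals inside a
    30 s trial, photostimulation from 2.5 s to 18.5 s.
``single_contrast``
    the contrast-series design: one 200 ms grating per trial, one trial per
    contrast, photostimulation starting 700 ms before the grating and lasting
    until the end of the trial.

Time is in seconds (float); frames are 0-based. Every analysis window is
half-open ``[t0, t1)`` and maps to frames as ``[floor(t0*rate),
ceil(t1*rate))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

__all__ = [
    "ProtocolSpec",
    "ConditionLabel",
    "ProtocolError",
    "read_protocol",
    "write_protocol",
    "default_train_protocol",
    "default_contrast_protocol",
    "time_to_frames",
]

#: contrast fractions used in the contrast-series experiments (100 .. 6.25 %)
DEFAULT_CONTRASTS = (1.0, 0.5, 0.25, 0.125, 0.0625)


class ProtocolError(ValueError):
    """Raised when a protocol file is malformed or violates an invariant."""


def time_to_frames(t0: float, t1: float, rate: float, n_frames: int | None = None):
    """Convert a half-open time window ``[t0, t1)`` to frame indices.

    Returns ``(i0, i1)`` with ``i0 = floor(t0*rate)`` and ``i1 = ceil(t1*rate)``,
    optionally clipped to ``[0, n_frames]``.
    """
    import math

    if t1 < t0:
        raise ValueError(f"window end {t1} precedes start {t0}")
    eps = 1e-9  # guard against float representation of t*rate
    i0 = math.floor(t0 * rate + eps)
    i1 = math.ceil(t1 * rate - eps)
    if n_frames is not None:
        i0 = max(0, min(i0, n_frames))
        i1 = max(0, min(i1, n_frames))
    return i0, i1


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and contrast description of one trial.

    Defaults reproduce the stimulus-train design: 100 samples/s acquisition,
    30 s trials with a 200 ms pre-stimulus normalization window, ten 200 ms
    stimuli at 3 s intervals (onsets 0.2 + 3k s, so stimuli #2-7 fall inside
    the photostimulation window), and 20 Hz / 25 ms-pulse photostimulation
    from 2.5 s to 18.5 s.
    """

    frame_rate: float = 100.0
    trial_duration: float = 30.0
    stim_onsets: tuple[float, ...] = tuple(0.2 + 3.0 * k for k in range(10))
    stim_duration: float = 0.2
    photostim_onset: float = 2.5
    photostim_duration: float = 16.0
    photostim_freq: float = 20.0
    pulse_width: float = 25.0  # ms
    contrasts: tuple[float, ...] = (1.0,)
    pre_record_norm_window: float = 0.2
    inter_condition_interval: float = 60.0
    mode: Literal["train", "single_contrast"] = "train"

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ProtocolError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.stim_duration <= 0:
            raise ProtocolError(f"stim_duration must be > 0, got {self.stim_duration}")
        if self.trial_duration <= 0:
            raise ProtocolError("trial_duration must be > 0")
        for t in self.stim_onsets:
            if not (0 <= t < self.trial_duration):
                raise ProtocolError(
                    f"stim_onset {t} s outside [0, {self.trial_duration}) s"
                )
        if not (0 <= self.photostim_onset < self.trial_duration):
            raise ProtocolError(
                f"photostim_onset {self.photostim_onset} s outside "
                f"[0, {self.trial_duration}) s"
            )
        if self.photostim_onset + self.photostim_duration > self.trial_duration:
            raise ProtocolError(
                "photostimulation window extends past trial end: "
                f"{self.photostim_onset} + {self.photostim_duration} > "
                f"{self.trial_duration}"
            )
        if len(set(self.contrasts)) != len(self.contrasts):
            raise ProtocolError(f"duplicate contrasts in {self.contrasts}")
        for c in self.contrasts:
            if not (0 < c <= 1):
                raise ProtocolError(f"contrast {c} outside (0, 1]")
        if self.mode == "single_contrast":
            if any(
                a <= b for a, b in zip(self.contrasts, self.contrasts[1:])
            ):
                raise ProtocolError(
                    "contrasts must be strictly decreasing in single_contrast "
                    f"mode, got {self.contrasts}"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))

    @property
    def photostim_window(self) -> tuple[float, float]:
        """The photostimulation window ``w_ph`` as ``[on, off)`` in seconds."""
        return (self.photostim_onset, self.photostim_onset + self.photostim_duration)

    def time_axis(self):
        import numpy as np

        return np.arange(self.n_frames) / self.frame_rate

    def photostim_mask(self):
        """Boolean per-frame mask of the photostimulation window."""
        import numpy as np

        i0, i1 = time_to_frames(*self.photostim_window, self.frame_rate, self.n_frames)
        m = np.zeros(self.n_frames, dtype=bool)
        m[i0:i1] = True
        return m

    def stimuli_in_photostim(self) -> list[int]:
        """0-based indices of stimuli whose onset lies inside ``w_ph``."""
        on, off = self.photostim_window
        return [i for i, t in enumerate(self.stim_onsets) if on <= t < off]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stim_onsets"] = list(self.stim_onsets)
        d["contrasts"] = list(self.contrasts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ProtocolError(f"unknown protocol field(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("stim_onsets", "contrasts"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:  # wrong type of a field
            raise ProtocolError(str(exc)) from exc


def default_train_protocol(**overrides) -> ProtocolSpec:
    """The stimulus-train protocol (10 gratings at 100% contrast)."""
    return ProtocolSpec(**overrides)


def default_contrast_protocol(**overrides) -> ProtocolSpec:
    """The contrast-series protocol: one 200 ms grating at 3.2 s, photostim
    onset 700 ms before the grating, lasting to the end of the trial."""
    kw = dict(
        trial_duration=10.0,
        stim_onsets=(3.2,),
        photostim_onset=2.5,
        photostim_duration=7.5,
        contrasts=DEFAULT_CONTRASTS,
        mode="single_contrast",
    )
    kw.update(overrides)
    return ProtocolSpec(**kw)


def read_protocol(path) -> ProtocolSpec:
    """Read and validate a protocol from a JSON file."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ProtocolError(f"malformed protocol file {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ProtocolError(f"protocol file {path} must contain a JSON object")
    return ProtocolSpec.from_dict(d)


def write_protocol(spec: ProtocolSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionLabel:
    """Label of one experimental condition.

    ``stimulus`` is ``"V"`` (grating) or ``"S"`` (blank / spontaneous);
    ``photostim`` marks concurrent raphe photostimulation. Drug labels are
    carried through to support antagonist parameter regimes in the generator.
    """

    modality: Literal["imaging", "mua"] = "imaging"
    stimulus: Literal["V", "S"] = "V"
    photostim: Literal["on", "off"] = "off"
    drug: Literal["none", "MDL", "WAY", "vehicle"] = "none"
    contrast: float | None = None

    def __post_init__(self):
        if self.stimulus == "S" and self.contrast is not None:
            raise ValueError("blank (S) conditions carry no contrast")
        if self.contrast is not None and not (0 < self.contrast <= 1):
            raise ValueError(f"contrast {self.contrast} outside (0, 1]")

    @property
    def name(self) -> str:
        """Condition shorthand: V, V_ph, S, S_ph (plus contrast suffix)."""
        base = self.stimulus + ("_ph" if self.photostim == "on" else "")
        if self.contrast is not None:
            base += f"_c{self.contrast:g}"
        if self.drug != "none":
            base += f"_{self.drug}"
        return base

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionLabel":
        return cls(**d)


#: the four core conditions of the trial-train design
CORE_CONDITIONS = (
    ConditionLabel(stimulus="V", photostim="off"),
    ConditionLabel(stimulus="V", photostim="on"),
    ConditionLabel(stimulus="S", photostim="off"),
    ConditionLabel(stimulus="S", photostim="on"),
)
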