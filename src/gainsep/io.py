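"""On-disk dataset layout and readers/writers.

Movies are stored one multi-frame grayscale TIFF per trial+condition with a
JSON sidecar (same stem, ``.json``) holding the condition label and trial
index. Spike counts, traces and metrics travel as long-format UTF-8 CSV;
protocols, ground truth, fits and statistics as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocol import ConditionLabel, ProtocolSpec

__all__ = [
    "TrialStack",
    "SpikeCountMatrix",
    "IOError_",
    "read_trial_stack",
    "write_trial_stack",
    "write_spike_counts",
    "read_spike_counts",
    "traces_to_frame",
    "frame_to_traces",
]


class IOError_(ValueError):
    """Raised for malformed or inconsistent dataset files."""


@dataclass
class TrialStack:
    """One trial's raw fluorescence movie: ``pixels[t, y, x] >= 0``."""

    pixels: np.ndarray  # (time, height, width), nonnegative
    condition: ConditionLabel
    trial: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise IOError_(f"expected a (time, y, x) stack, got {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise IOError_("negative pixel values in trial stack")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SpikeCountMatrix:
    """Binned spike counts, ``counts[unit, bin, trial]`` nonnegative integers."""

    counts: np.ndarray  # (unit, time-bin, trial)
    bin_width: float = 0.2
    unit_ids: tuple | None = None
    condition: ConditionLabel | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise IOError_(
                f"expected (unit, bin, trial) counts, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise IOError_("negative spike counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise IOError_("spike counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.unit_ids is None:
            self.unit_ids = tuple(range(self.counts.shape[0]))

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    def rates(self) -> np.ndarray:
        """Counts converted to rates in Hz, same shape."""
        return self.counts / self.bin_width


# -- TIFF + sidecar ---------------------------------------------------------


def write_trial_stack(stack: TrialStack, path) -> Path:
    """Write a trial movie as float32 TIFF plus JSON sidecar; returns the path."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels.astype(np.float32), photometric="minisblack")
    sidecar = {
        "condition": stack.condition.to_dict(),
        "trial": int(stack.trial),
        "n_frames": int(stack.n_frames),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_trial_stack(path, protocol: ProtocolSpec | None = None) -> TrialStack:
    """Read a trial movie (TIFF + sidecar), optionally validating the frame
    count against a protocol."""
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:  # single-frame edge case
        pixels = pixels[None]
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise IOError_(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if np.any(pixels < 0):
        raise IOError_(f"negative pixel values in {path}")
    if protocol is not None and pixels.shape[0] != protocol.n_frames:
        raise IOError_(
            f"{path}: {pixels.shape[0]} frames, protocol expects "
            f"{protocol.n_frames}"
        )
    return TrialStack(
        pixels=pixels,
        condition=ConditionLabel.from_dict(sidecar["condition"]),
        trial=int(sidecar["trial"]),
    )


# -- spike-count CSV --------------------------------------------------------


def write_spike_counts(mat: SpikeCountMatrix, path) -> Path:
    """Long-format CSV: condition, trial, unit, time_s, value."""
    path = Path(path)
    n_units, n_bins, n_trials = mat.counts.shape
    cond = mat.condition.name if mat.condition is not None else ""
    unit = np.repeat(np.asarray(mat.unit_ids), n_bins * n_trials)
    t = np.tile(np.repeat(np.arange(n_bins) * mat.bin_width, n_trials), n_units)
    trial = np.tile(np.arange(n_trials), n_units * n_bins)
    df = pd.DataFrame(
        {
            "condition": cond,
            "trial": trial,
            "unit": unit,
            "time_s": t,
            "value": mat.counts.reshape(-1),
        }
    )
    df.to_csv(path, index=False)
    # sidecar for bin width / condition round-trip
    meta = {
        "bin_width": mat.bin_width,
        "condition": mat.condition.to_dict() if mat.condition else None,
        "shape": list(mat.counts.shape),
    }
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_spike_counts(path) -> SpikeCountMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    with open(path.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    shape = tuple(meta["shape"])
    counts = df["value"].to_numpy().reshape(shape)
    cond = (
        ConditionLabel.from_dict(meta["condition"]) if meta["condition"] else None
    )
    unit_ids = tuple(pd.unique(df["unit"]))
    return SpikeCountMatrix(
        counts=counts, bin_width=meta["bin_width"], unit_ids=unit_ids, condition=cond
    )


# -- trace CSV helpers ------------------------------------------------------


def traces_to_frame(traces: dict, rate: float) -> pd.DataFrame:
    """Pack ``{condition name: (n_trials, n_time) array}`` into long format."""
    rows = []
    for cond, arr in traces.items():
        arr = np.atleast_2d(np.asarray(arr))
        n_trials, n_time = arr.shape
        t = np.arange(n_time) / rate
        rows.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "trial": np.repeat(np.arange(n_trials), n_time),
                    "time_s": np.tile(t, n_trials),
                    "value": arr.reshape(-1),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> dict:
    """Inverse of :func:`traces_to_frame` (condition → (trials, time))."""
    out = {}
    for cond, sub in df.groupby("condition", sort=False):
        n_trials = sub["trial"].nunique()
        out[cond] = (
            sub.sort_values(["trial", "time_s"])["value"]
            .to_numpy()
            .reshape(n_trials, -1)
        )
    return out
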