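"""End-to-end pipeline: simulate → preprocess → components → regress →
tuning → gain → report.

A JSON config names the dataset root, the stages to run, and the seed; every
stage writes deterministic CSV/JSON outputs plus a run log (package and
library versions, seed, parameters, stage order). The movie path runs the
trial-train design; the contrast-series design runs at ROI-trace level so a
multi-subject cohort completes in seconds.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .components import (
    compute_metrics,
    evoked_component,
    locate_windows,
    normalize_mua,
    normalize_to_first_peak,
)
from .gainmodel import component_weights, estimate_gain
from .io import read_trial_stack, traces_to_frame, write_spike_counts
from .preprocess import preprocess_trials
from .protocol import (
    CORE_CONDITIONS,
    ConditionLabel,
    ProtocolSpec,
    default_contrast_protocol,
    default_train_protocol,
    read_protocol,
)
from .suppression import (
    FILTER_PRESETS,
    build_prepost,
    classify_suppression,
    filter_units,
    fit_suppression,
)
from .synth import (
    GroundTruth,
    anesthetized_ground_truth,
    generate_cohort,
    generate_roi_traces,
    generate_spike_counts,
)
from .tuning import fit_naka_rushton, normalize_and_refit

__all__ = ["run_pipeline", "PipelineError", "ALL_STAGES"]

ALL_STAGES = ("simulate", "preprocess", "components", "regress", "tuning",
              "gain", "report")


class PipelineError(RuntimeError):
    pass


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise PipelineError(
            f"stage {needed_by!r} is missing its input {path.name} — run the "
            f"{stage!r} stage first"
        )


def _json_dump(obj, path):
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return json.load(fh)
    return dict(config)


def _build_ground_truths(cfg, seed) -> list[GroundTruth]:
    n = int(cfg.get("n_subjects", 3))
    overrides = dict(cfg.get("ground_truth", {}))
    for key, val in overrides.items():
        if isinstance(val, list):
            overrides[key] = tuple(val)
    return [anesthetized_ground_truth(seed=seed + i, **overrides) for i in range(n)]


def run_pipeline(config, out=None) -> dict:
    """Run the configured stages; returns a dict of written artifact paths.

    Config keys: ``dataset_root`` (required), ``stages`` (default all),
    ``seed`` (default 0), ``n_subjects``, ``n_trials``, ``protocol``
    (field overrides for the trial-train protocol), ``ground_truth``
    (GroundTruth field overrides), ``contrast_trials``.
    """
    cfg = _load_config(config)
    root = Path(cfg.get("dataset_root") or out or ".")
    root.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", ALL_STAGES))
    seed = int(cfg.get("seed", 0))
    n_trials = int(cfg.get("n_trials", 8))
    data = root / "data"
    res = root / "results"
    res.mkdir(exist_ok=True)

    proto_overrides = cfg.get("protocol", {})
    protocol = default_train_protocol(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in proto_overrides.items()
    })
    cproto = default_contrast_protocol(
        frame_rate=protocol.frame_rate
    )
    gts = _build_ground_truths(cfg, seed)
    artifacts: dict = {}
    log = {
        "seed": seed,
        "stages_run": [],
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "parameters": {"n_subjects": len(gts), "n_trials": n_trials,
                       "protocol": protocol.to_dict()},
    }

    for stage in stages:
        if stage == "simulate":
            _stage_simulate(gts, protocol, cproto, data, n_trials, cfg, artifacts)
        elif stage == "preprocess":
            _stage_preprocess(gts, protocol, data, res, artifacts)
        elif stage == "components":
            _stage_components(protocol, res, artifacts)
        elif stage == "regress":
            _stage_regress(gts, protocol, data, res, artifacts)
        elif stage == "tuning":
            _stage_tuning(cproto, data, res, artifacts)
        elif stage == "gain":
            _stage_gain(cproto, data, res, artifacts)
        elif stage == "report":
            _stage_report(root, res, artifacts, log)
        else:
            raise PipelineError(f"unknown stage {stage!r}")
        log["stages_run"].append(stage)

    _json_dump(log, res / "run_log.json")
    artifacts["run_log"] = str(res / "run_log.json")
    return artifacts


# -- stages -----------------------------------------------------------------


def _stage_simulate(gts, protocol, cproto, data, n_trials, cfg, artifacts):
    manifest = generate_cohort(
        gts, protocol, data, n_trials=n_trials, overwrite=True
    )
    artifacts["manifest"] = str(data / "manifest.csv")
    # spiking path (trial-train protocol)
    n_units = int(cfg.get("n_units", 30))
    for si, gt in enumerate(gts):
        sub = data / f"sub-{si + 1:02d}"
        for cond in CORE_CONDITIONS:
            mua = generate_spike_counts(
                gt, protocol, cond, n_units=n_units, n_trials=n_trials
            )
            write_spike_counts(mua, sub / f"mua_{cond.name}.csv")
    # contrast-series ROI traces
    ctrials = int(cfg.get("contrast_trials", 10))
    rows = {}
    for si, gt in enumerate(gts):
        for c in cproto.contrasts:
            for ph in ("off", "on"):
                cond = ConditionLabel(stimulus="V", photostim=ph, contrast=c)
                tr = generate_roi_traces(gt, cproto, cond, ctrials)
                rows[f"sub-{si + 1:02d}/{cond.name}"] = tr
        for ph in ("off", "on"):
            cond = ConditionLabel(stimulus="S", photostim=ph)
            rows[f"sub-{si + 1:02d}/{cond.name}"] = generate_roi_traces(
                gt, cproto, cond, ctrials
            )
    df = traces_to_frame(rows, cproto.frame_rate)
    df.to_csv(data / "contrast_traces.csv", index=False)
    artifacts["contrast_traces"] = str(data / "contrast_traces.csv")


def _stage_preprocess(gts, protocol, data, res, artifacts):
    _require(data / "manifest.csv", "simulate", "preprocess")
    manifest = pd.read_csv(data / "manifest.csv")
    all_traces = []
    for subject, sub_manifest in manifest.groupby("subject"):
        stacks = {}
        for cond_name, rows in sub_manifest.groupby("condition"):
            stacks[cond_name] = [
                read_trial_stack(data / p, protocol)
                for p in sorted(rows["path"])
            ]
        ts = preprocess_trials(
            stacks, protocol, blank_condition="S", control_condition="V",
            smooth_sigma=min(protocol.frame_rate, 3.0),
            cutoff_wavelength=None if min(
                next(iter(stacks.values()))[0].pixels.shape[1:]
            ) < 16 else 33.0,
        )
        df = traces_to_frame(ts.traces, protocol.frame_rate)
        df.insert(0, "subject", subject)
        all_traces.append(df)
        _json_dump(
            {"stage_log": ts.stage_log, **ts.normalization_record},
            res / f"{subject}_preprocess_log.json",
        )
    pd.concat(all_traces, ignore_index=True).to_csv(
        res / "roi_traces.csv", index=False
    )
    artifacts["roi_traces"] = str(res / "roi_traces.csv")


def _stage_components(protocol, res, artifacts):
    _require(res / "roi_traces.csv", "preprocess", "components")
    df = pd.read_csv(res / "roi_traces.csv")
    metrics_rows, eph_rows = [], []
    for subject, sub in df.groupby("subject"):
        traces = {}
        for cond, cd in sub.groupby("condition"):
            nt = cd["trial"].nunique()
            traces[cond] = (
                cd.sort_values(["trial", "time_s"])["value"].to_numpy()
                .reshape(nt, -1)
            )
        normed, scale = normalize_to_first_peak(traces, protocol, control="V")
        windows = locate_windows(normed["V"].mean(axis=0), protocol)
        for cond, arr in normed.items():
            m = compute_metrics(arr.mean(axis=0), windows, protocol.frame_rate,
                                condition=cond)
            mdf = m.to_frame()
            mdf.insert(0, "subject", subject)
            metrics_rows.append(mdf)
        if "V_ph" in normed and "S_ph" in normed:
            eph, eph_avg, used = evoked_component(normed["V_ph"], normed["S_ph"])
            m = compute_metrics(eph_avg, windows, protocol.frame_rate,
                                condition="E_ph")
            mdf = m.to_frame()
            mdf.insert(0, "subject", subject)
            mdf["pairing"] = used
            metrics_rows.append(mdf)
            eph_df = traces_to_frame({"E_ph": eph}, protocol.frame_rate)
            eph_df.insert(0, "subject", subject)
            eph_rows.append(eph_df)
    pd.concat(metrics_rows, ignore_index=True).to_csv(
        res / "component_metrics.csv", index=False
    )
    artifacts["component_metrics"] = str(res / "component_metrics.csv")
    if eph_rows:
        pd.concat(eph_rows, ignore_index=True).to_csv(
            res / "evoked_component.csv", index=False
        )
        artifacts["evoked_component"] = str(res / "evoked_component.csv")


def _stage_regress(gts, protocol, data, res, artifacts):
    from .io import read_spike_counts

    fits = []
    excluded = []
    for si in range(len(gts)):
        sub = data / f"sub-{si + 1:02d}"
        _require(sub / "mua_S.csv", "simulate", "regress")
        unit_traces = {}
        for ph, name in ((0, "S"), (1, "S_ph")):
            mat = read_spike_counts(sub / f"mua_{name}.csv")
            unit_traces[ph] = mat.rates().mean(axis=2)  # (unit, bin) Hz
            bin_rate = 1.0 / mat.bin_width
        # the regression windows are 4 s where the protocol allows; with the
        # default 2.5 s photostimulation onset the pre window is the full
        # available pre-period
        wlen = min(4.0, protocol.photostim_onset)
        records = build_prepost(unit_traces, protocol, bin_rate,
                                window_len=wlen, subject_id=sub.name)
        lo, hi = FILTER_PRESETS["default"]
        records, bad = filter_units(records, lo, hi)
        excluded.extend((sub.name, u) for u in bad)
        fits.append(fit_suppression(records, filter_applied="default",
                                    subject_id=sub.name))
    result = classify_suppression(fits)
    result["subject_fits"] = [
        {"subject": f.subject_id, "b1": f.b1, "b2": f.b2, "b3": f.b3,
         "b4": f.b4, "n_records": f.n_records}
        for f in fits
    ]
    _json_dump(result, res / "suppression_fit.json")
    pd.DataFrame(excluded, columns=["subject", "unit_id"]).to_csv(
        res / "excluded_units.csv", index=False
    )
    artifacts["suppression_fit"] = str(res / "suppression_fit.json")


def _contrast_traces(data):
    df = pd.read_csv(data / "contrast_traces.csv")
    out = {}
    for cond, cd in df.groupby("condition"):
        nt = cd["trial"].nunique()
        out[cond] = (
            cd.sort_values(["trial", "time_s"])["value"].to_numpy()
            .reshape(nt, -1)
        )
    return out


def _peaks_and_windows(traces, cproto):
    """Per-condition mean traces, per-contrast windows (from control) and
    peak values for V / V_ph / E_ph, averaged across subjects."""
    subjects = sorted({k.split("/")[0] for k in traces})
    peaks = {"V": {}, "V_ph": {}, "E_ph": {}}
    windows = {}
    metrics = {"V": {}, "V_ph": {}, "E_ph": {}}
    sph_means = []
    for c in sorted({float(k.split("_c")[1].split("_")[0])
                     for k in traces if "_c" in k}, reverse=True):
        v = np.mean([traces[f"{s}/V_c{c:g}"] for s in subjects], axis=(0, 1))
        vph = np.mean([traces[f"{s}/V_ph_c{c:g}"] for s in subjects], axis=(0, 1))
        sph = np.mean([traces[f"{s}/S_ph"] for s in subjects], axis=(0, 1))
        eph = vph - sph
        win = locate_windows(v, cproto)
        windows[c] = win
        rate = cproto.frame_rate
        metrics["V"][c] = compute_metrics(v, win, rate, condition="V")
        metrics["V_ph"][c] = compute_metrics(vph, win, rate, condition="V_ph")
        metrics["E_ph"][c] = compute_metrics(eph, win, rate, condition="E_ph")
        i_pk = int(round(win.peak_times[0] * rate))
        peaks["V"][c] = float(v[i_pk])
        peaks["V_ph"][c] = float(vph[i_pk])
        peaks["E_ph"][c] = float(eph[i_pk])
    sph = np.mean([traces[f"{s}/S_ph"] for s in subjects], axis=(0, 1))
    return peaks, windows, metrics, sph


def _stage_tuning(cproto, data, res, artifacts):
    _require(data / "contrast_traces.csv", "simulate", "tuning")
    traces = _contrast_traces(data)
    peaks, windows, metrics, _ = _peaks_and_windows(traces, cproto)
    out = {}
    tidy = []
    for cond, pk in peaks.items():
        contrasts = np.array(sorted(pk), dtype=float)
        vals = np.array([pk[c] for c in contrasts])
        fit = fit_naka_rushton(contrasts, vals)
        scaled, nfit = normalize_and_refit(pk)
        out[cond] = {
            "raw": {"r_max": fit.r_max, "c50": fit.c50, "n": fit.n,
                    "r0": fit.r0, "r_squared": fit.r_squared},
            "normalized": {"r_max": nfit.r_max, "c50": nfit.c50, "n": nfit.n,
                           "r0": nfit.r0, "r_squared": nfit.r_squared},
        }
        for c in contrasts:
            tidy.append({"condition": cond, "contrast": c, "peak": pk[c],
                         "normalized_peak": scaled[c]})
    _json_dump(out, res / "contrast_tuning.json")
    pd.DataFrame(tidy).to_csv(res / "contrast_peaks.csv", index=False)
    artifacts["contrast_tuning"] = str(res / "contrast_tuning.json")


def _stage_gain(cproto, data, res, artifacts):
    _require(data / "contrast_traces.csv", "simulate", "gain")
    traces = _contrast_traces(data)
    peaks, windows, metrics, sph = _peaks_and_windows(traces, cproto)
    g, pooled = estimate_gain(metrics["V"], metrics["V_ph"])
    decomp = component_weights(
        g, metrics["E_ph"], sph, windows, cproto, g_pooled=pooled,
    )
    decomp.to_frame().to_csv(res / "gain_decomposition.csv", index=False)
    artifacts["gain_decomposition"] = str(res / "gain_decomposition.csv")


def _stage_report(root, res, artifacts, log):
    # paths are stored relative to the dataset root so a run is reproducible
    # byte-for-byte regardless of where it lives
    rel = {
        k: str(Path(v).resolve().relative_to(root.resolve()))
        for k, v in artifacts.items()
    }
    report = {"artifacts": rel}
    for name in ("suppression_fit", "contrast_tuning"):
        p = res / f"{name}.json"
        if p.exists():
            with open(p) as fh:
                report[name] = json.load(fh)
    gd = res / "gain_decomposition.csv"
    if gd.exists():
        report["gain_decomposition"] = pd.read_csv(gd).to_dict(orient="list")
    report["log"] = {k: v for k, v in log.items() if k != "stages_run"}
    _json_dump(report, res / "report.json")
    artifacts["report"] = str(res / "report.json")
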