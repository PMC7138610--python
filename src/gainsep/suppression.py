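"""Divisive vs subtractive classification of photostimulation suppression.

The post-photostimulation mean rate of each unit is regressed on its
pre-photostimulation rate with a photostimulation indicator:

    fr_post = b1 + b2·ph + b3·fr_pre + b4·fr_pre·ph

``b2`` (intercept shift) is the subtractive term and ``b4`` (slope change)
the divisive term. A purely divisive suppression with gain ``g_s`` and
additive shift ``offset`` identifies as ``b4 = g_s − 1`` and ``b2 = offset``.
Classification is by one-sided one-sample t tests on the per-subject
coefficients in the suppressive (negative) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocol import ProtocolSpec, time_to_frames

__all__ = [
    "SuppressionFit",
    "build_prepost",
    "filter_units",
    "fit_suppression",
    "classify_suppression",
    "FILTER_PRESETS",
]

#: named unit-rate filters: the default floor-effect guard and the band used
#: for the pre/post regression figures
FILTER_PRESETS = {"default": (1.0, None), "fig4": (1.0, 20.0)}


@dataclass
class SuppressionFit:
    """OLS fit of the pre/post regression."""

    b1: float  # intercept
    b2: float  # subtractive term (photostim intercept shift)
    b3: float  # slope
    b4: float  # divisive term (photostim slope change)
    standard_errors: tuple
    n_records: int
    residual_std: float
    r_squared: float
    filter_applied: str = "none"
    subject_id: object = None

    @property
    def coefficients(self):
        return np.array([self.b1, self.b2, self.b3, self.b4])


def build_prepost(
    unit_traces: dict,
    protocol: ProtocolSpec,
    bin_rate: float,
    window_len: float = 4.0,
    subject_id=None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-unit mean rates in the 4 s windows flanking photostimulation onset.

    ``unit_traces`` maps ``ph`` indicator (0/1) to a (units, time) rate
    array; pre = ``[onset − window_len, onset)``, post = ``[onset,
    onset + window_len)``. Rates are normalized by the maximum pre rate over
    all units and conditions (raw rates kept in ``fr_pre_hz`` for filtering).
    """
    onset = protocol.photostim_onset
    if window_len > onset:
        raise ValueError(
            f"window_len {window_len} s exceeds photostimulation onset "
            f"{onset} s; pre window would be clipped"
        )
    rows = []
    for ph, arr in unit_traces.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        n = arr.shape[1]
        p0, p1 = time_to_frames(onset - window_len, onset, bin_rate, n)
        q0, q1 = time_to_frames(onset, onset + window_len, bin_rate, n)
        if q1 <= q0 or q1 > n:
            raise ValueError("trace shorter than the post window")
        for u in range(arr.shape[0]):
            rows.append(
                {
                    "unit_id": u,
                    "fr_pre": arr[u, p0:p1].mean(),
                    "fr_post": arr[u, q0:q1].mean(),
                    "ph": int(ph),
                    "subject_id": subject_id,
                }
            )
    df = pd.DataFrame(rows)
    df["fr_pre_hz"] = df["fr_pre"]
    df["fr_post_hz"] = df["fr_post"]
    if normalize:
        peak = df["fr_pre"].max()
        if peak <= 0:
            raise ValueError("maximum pre rate is not positive; cannot normalize")
        df["fr_pre"] = df["fr_pre"] / peak
        df["fr_post"] = df["fr_post"] / peak
    return df


def filter_units(
    records: pd.DataFrame,
    min_rate: float = 1.0,
    max_rate: float | None = None,
    rate_column: str = "fr_pre_hz",
):
    """Drop units whose control (ph=0) pre rate falls outside
    ``[min_rate, max_rate]`` Hz. Returns ``(kept records, excluded ids)``."""
    base = records[records["ph"] == 0].set_index("unit_id")[rate_column]
    hi = np.inf if max_rate is None else max_rate
    bad = base[(base < min_rate) | (base > hi)].index
    kept = records[~records["unit_id"].isin(bad)]
    if kept.empty or kept["unit_id"].nunique() == 0:
        raise ValueError(
            f"all units excluded by the [{min_rate}, {max_rate}] Hz filter"
        )
    return kept.reset_index(drop=True), sorted(bad.tolist())


def fit_suppression(records: pd.DataFrame, filter_applied: str = "none",
                    subject_id=None) -> SuppressionFit:
    """Ordinary least squares on the pre/post design.

    Design columns: intercept, ph, fr_pre, fr_pre·ph. Raises on a
    rank-deficient design, naming the collinear column.
    """
    pre = records["fr_pre"].to_numpy(dtype=float)
    post = records["fr_post"].to_numpy(dtype=float)
    ph = records["ph"].to_numpy(dtype=float)
    for level in (0, 1):
        vals = pre[ph == level]
        if np.unique(vals).size < 2:
            raise ValueError(
                f"need >= 2 distinct pre rates at ph={level} to identify the "
                "slope terms"
            )
    x = np.column_stack([np.ones_like(pre), ph, pre, pre * ph])
    rank = np.linalg.matrix_rank(x)
    if rank < 4:
        names = ["intercept", "ph", "fr_pre", "fr_pre:ph"]
        raise ValueError(
            f"rank-deficient design (rank {rank} < 4); collinearity among "
            f"{names}"
        )
    beta, _, _, _ = np.linalg.lstsq(x, post, rcond=None)
    resid = post - x @ beta
    n, p = x.shape
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = tuple(np.sqrt(np.diag(cov)))
    ss_tot = float(np.sum((post - post.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    return SuppressionFit(
        b1=float(beta[0]),
        b2=float(beta[1]),
        b3=float(beta[2]),
        b4=float(beta[3]),
        standard_errors=se,
        n_records=n,
        residual_std=float(np.sqrt(sigma2)),
        r_squared=r2,
        filter_applied=filter_applied,
        subject_id=subject_id,
    )


def classify_suppression(fits: list, alpha: float = 0.05) -> dict:
    """Label the suppression regime from per-subject regression fits.

    One-sided one-sample t tests (direction: suppressive, i.e. negative) on
    the subtractive (b2) and divisive (b4) coefficients across subjects:
    ``divisive`` if only b4 is significantly negative, ``subtractive`` if
    only b2, ``mixed`` if both, ``none`` otherwise. With fewer than three
    subjects the tests are skipped and the label comes from point estimates
    with an ``untested`` flag.
    """
    b2s = np.array([f.b2 for f in fits])
    b4s = np.array([f.b4 for f in fits])
    out = {
        "n_subjects": len(fits),
        "b2_mean": float(b2s.mean()),
        "b2_sem": float(sps.sem(b2s)) if len(fits) > 1 else np.nan,
        "b4_mean": float(b4s.mean()),
        "b4_sem": float(sps.sem(b4s)) if len(fits) > 1 else np.nan,
        "alpha": alpha,
    }
    if len(fits) < 3:
        sub = b2s.mean() < -alpha  # point-estimate fallback, crude threshold
        div = b4s.mean() < -alpha
        out.update(untested=True, p_b2=np.nan, p_b4=np.nan)
    else:
        t2 = sps.ttest_1samp(b2s, 0.0, alternative="less")
        t4 = sps.ttest_1samp(b4s, 0.0, alternative="less")
        out.update(
            untested=False,
            t_b2=float(t2.statistic),
            p_b2=float(t2.pvalue),
            t_b4=float(t4.statistic),
            p_b4=float(t4.pvalue),
        )
        sub = t2.pvalue < alpha
        div = t4.pvalue < alpha
    if sub and div:
        label = "mixed"
    elif div:
        label = "divisive"
    elif sub:
        label = "subtractive"
    else:
        label = "none"
    out["label"] = label
    return out
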