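"""One-sided t tests, max-statistic permutation correction, onset detection
and detrended comparisons.

Familywise correction over a family of paired comparisons (e.g. the ten
stimuli of a trial) uses Westfall-Young-style sign-flip permutation with the
max statistic: every permutation flips each pair's sign independently, the
maximum of the family's statistics is recorded, and a member is significant
when its observed statistic exceeds the (1−α) quantile of that null maximum
distribution. With n pairs ≤ 12 all 2ⁿ sign patterns are enumerated exactly;
otherwise 10,000 Monte-Carlo permutations with a logged seed are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "t_tests",
    "permutation_correct",
    "onset_of_significance",
    "detrend_compare",
]

EXACT_ENUMERATION_LIMIT = 4096  # enumerate all sign flips when 2^n <= this


@dataclass
class StatResult:
    statistic: float
    p_raw: float
    n: int
    test_name: str
    side: str
    p_corrected: float | None = None
    degenerate: bool = False
    seed: int | None = None


def _one_sided_from_stat(t, dof, side):
    if side == "less":
        return float(sps.t.cdf(t, dof))
    if side == "greater":
        return float(sps.t.sf(t, dof))
    return float(2 * sps.t.sf(abs(t), dof))


def t_tests(a, b=None, kind: str = "one_sample", side: str = "less",
            popmean: float = 0.0) -> StatResult:
    """One-sample, two-sample or paired t test with a one-sided default.

    Zero-variance conventions: zero effect → statistic 0, p = 1; nonzero
    effect → p = 0 with the result flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    if kind == "one_sample":
        diffs = a - popmean
    elif kind == "paired":
        if b is None:
            raise ValueError("paired test needs two samples")
        b = np.asarray(b, dtype=float)
        diffs = a - b
    elif kind == "two_sample":
        if b is None:
            raise ValueError("two-sample test needs two samples")
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need n >= 2 per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            effect = a.mean() - b.mean()
            if effect == 0:
                return StatResult(0.0, 1.0, a.size + b.size, kind, side,
                                  degenerate=True)
            p = 0.0 if side != "two-sided" else 0.0
            stat = np.inf * np.sign(effect)
            return StatResult(float(stat), p, a.size + b.size, kind, side,
                              degenerate=True)
        res = sps.ttest_ind(a, b, alternative=_alt(side))
        return StatResult(float(res.statistic), float(res.pvalue),
                          a.size + b.size, kind, side)
    else:
        raise ValueError(f"unknown test kind {kind!r}")

    if diffs.size < 2:
        raise ValueError("need n >= 2")
    sd = diffs.std(ddof=1)
    if sd == 0:
        m = diffs.mean()
        if m == 0:
            return StatResult(0.0, 1.0, diffs.size, kind, side, degenerate=True)
        # all-identical nonzero differences: effect certain in-sample
        signed_ok = (
            side == "two-sided"
            or (side == "less" and m < 0)
            or (side == "greater" and m > 0)
        )
        return StatResult(float(np.inf * np.sign(m)),
                          0.0 if signed_ok else 1.0,
                          diffs.size, kind, side, degenerate=True)
    t = diffs.mean() / (sd / np.sqrt(diffs.size))
    p = _one_sided_from_stat(t, diffs.size - 1, side)
    return StatResult(float(t), p, diffs.size, kind, side)


def _alt(side):
    return {"less": "less", "greater": "greater", "two-sided": "two-sided"}[side]


def _member_t(diffs):
    """t statistics of each family member's paired differences (k, n) → (k,)."""
    n = diffs.shape[1]
    m = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0  # zero-variance zero-effect members
    return t


def _sign_patterns(n):
    """All 2^n sign vectors (±1), shape (2^n, n)."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    return 1 - 2 * bits  # 0→+1, 1→−1


def _perm_stats(diffs, signs, side):
    """Family statistics under each sign pattern.

    Exploits that sums of squares are sign-invariant: for pattern s,
    mean = (s·d)/n and the sample variance follows from the unchanged
    per-member sum of squares.
    """
    k, n = diffs.shape
    sums = signs @ diffs.T  # (P, k)
    mean = sums / n
    ss = np.sum(diffs**2, axis=1)  # (k,), invariant
    var = (ss[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    if side == "less":
        return -t
    if side == "greater":
        return t
    return np.abs(t)


def permutation_correct(
    paired_differences,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    side: str = "two-sided",
):
    """Max-statistic sign-flip correction over a family of paired samples.

    ``paired_differences`` is (k members, n pairs). Returns a dict with the
    per-member observed statistics, corrected p values
    (``P(max over family ≥ observed)``), raw permutation p values, the
    significance mask at ``alpha``, and whether enumeration was exact.
    """
    diffs = np.atleast_2d(np.asarray(paired_differences, dtype=float))
    k, n = diffs.shape
    if k == 0 or diffs.size == 0:
        raise ValueError("empty family")
    if n < 2:
        raise ValueError("need at least 2 pairs per member")

    t_obs = _member_t(diffs)
    obs = {"less": -t_obs, "greater": t_obs, "two-sided": np.abs(t_obs)}[side]

    exact = 2**n <= EXACT_ENUMERATION_LIMIT
    if exact:
        signs = _sign_patterns(n)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n))
    stats = _perm_stats(diffs, signs, side)  # (P, k)
    max_stat = stats.max(axis=1)  # (P,)
    n_p = len(max_stat)
    # corrected p: fraction of permutations whose family max reaches the
    # observed member statistic (enumeration includes the identity pattern;
    # Monte-Carlo uses the add-one convention)
    if exact:
        p_corr = (max_stat[None, :] >= obs[:, None] - 1e-12).mean(axis=1)
        p_raw = np.array(
            [(stats[:, j] >= obs[j] - 1e-12).mean() for j in range(k)]
        )
    else:
        p_corr = ((max_stat[None, :] >= obs[:, None] - 1e-12).sum(axis=1) + 1) / (
            n_p + 1
        )
        p_raw = np.array(
            [((stats[:, j] >= obs[j] - 1e-12).sum() + 1) / (n_p + 1)
             for j in range(k)]
        )
    mask = p_corr <= alpha
    return {
        "statistic": t_obs,
        "p_corrected": p_corr,
        "p_raw": p_raw,
        "mask": mask,
        "alpha": alpha,
        "exact": exact,
        "n_permutations": n_p,
        "side": side,
        "seed": None if exact else seed,
    }


def onset_of_significance(
    trace_or_diffs,
    protocol_onset: float,
    rate: float,
    criterion: str = "sd2",
    pre_window: tuple[float, float] | None = None,
    n_consecutive: int = 2,
    direction: str = "below",
    alpha: float = 0.05,
    seed: int = 0,
) -> float | None:
    """First post-onset time at which suppression is significant for at least
    ``n_consecutive`` consecutive bins; ``None`` if never.

    ``criterion="sd2"``: the per-time trace falls below (or above, per
    ``direction``) mean ± 2·SD of the pre-onset reference window.
    ``criterion="permutation"``: ``trace_or_diffs`` is a (time, n pairs)
    family of per-time paired differences; the max-statistic corrected mask
    defines significance.
    """
    i_on = int(round(protocol_onset * rate))
    if criterion == "sd2":
        trace = np.asarray(trace_or_diffs, dtype=float)
        if pre_window is None:
            pre_window = (0.0, protocol_onset)
        j0, j1 = int(round(pre_window[0] * rate)), int(round(pre_window[1] * rate))
        base = trace[j0:j1]
        if base.size < 2:
            raise ValueError("reference window too short")
        mu, sd = base.mean(), base.std(ddof=0)
        if direction == "below":
            sig = trace[i_on:] < mu - 2 * sd
        else:
            sig = trace[i_on:] > mu + 2 * sd
    elif criterion == "permutation":
        diffs = np.asarray(trace_or_diffs, dtype=float)  # (time, n)
        side = "less" if direction == "below" else "greater"
        res = permutation_correct(
            diffs[i_on:], alpha=alpha, seed=seed, side=side
        )
        sig = res["mask"]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= n_consecutive:
            return (i_on + i - n_consecutive + 1) / rate
    return None


def detrend_compare(trace_a, trace_b, window: tuple[int, int] | None = None
                    ) -> StatResult:
    """Two-sample t test on linearly detrended traces.

    Each full trace has its least-squares line (slope and intercept) removed,
    then residual values are compared within the optional sample ``window``.
    Detrending over the whole trace (rather than the comparison window, whose
    residual mean would vanish identically) lets a localized deviation reach
    significance while a shared ramp or constant offset cannot.
    """
    from scipy.signal import detrend

    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("window must span at least 3 samples")
    ra = detrend(a, type="linear")
    rb = detrend(b, type="linear")
    if window is not None:
        ra = ra[window[0]: window[1]]
        rb = rb[window[0]: window[1]]
        if ra.size < 3 or rb.size < 3:
            raise ValueError("window must span at least 3 samples")
    if np.allclose(ra, 0) and np.allclose(rb, 0):
        return StatResult(0.0, 1.0, a.size + b.size, "detrended_two_sample",
                          "two-sided", degenerate=True)
    res = sps.ttest_ind(ra, rb)
    return StatResult(float(res.statistic), float(res.pvalue), a.size + b.size,
                      "detrended_two_sample", "two-sided")
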