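"""Set-point measurements: population entropy and mutual information,
significance-filtered spike-burst correlations, burst/rate statistics, and
traversal dwell times.

Entropy is measured on per-time-step population *words* — the binary
pattern of which units are active in one 1-ms bin — with the plug-in
(maximum-likelihood) estimator over observed word frequencies.  Mutual
information between two simultaneously recorded populations is
I = H(A) + H(B) - H(A,B), with joint words formed by concatenation.  An
optional subsampling report estimates the plug-in bias by re-estimating on
data fractions (direct-method style extrapolation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "word_counts",
    "population_entropy",
    "population_mi",
    "entropy_bias_report",
    "spike_burst_correlations",
    "transient_durations",
    "dwell_times",
    "burst_and_rate_stats",
]


# ---------------------------------------------------------------------------
# population words, entropy, mutual information

def _as_words(raster: np.ndarray) -> np.ndarray:
    """Hash each time-step population pattern to an opaque word id."""
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("raster must be (time x unit)")
    if raster.shape[0] < 1:
        raise ValueError("need at least one sample")
    packed = np.packbits(raster.astype(bool), axis=1)
    return np.array([row.tobytes() for row in packed], dtype=object)


def word_counts(raster: np.ndarray) -> Counter:
    return Counter(_as_words(raster))


def _entropy_from_counts(counts: np.ndarray, n: int) -> float:
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def population_entropy(raster: np.ndarray) -> float:
    """Plug-in entropy (bits) of the per-time-step population word
    distribution."""
    counts = np.fromiter(word_counts(raster).values(), dtype=float)
    return _entropy_from_counts(counts, raster.shape[0])


def population_mi(rasterA: np.ndarray, rasterB: np.ndarray) -> float:
    """Mutual information (bits) between two time-aligned population word
    streams; joint words are concatenations.  Clipped at zero (the plug-in
    difference can dip infinitesimally negative)."""
    rasterA, rasterB = np.asarray(rasterA), np.asarray(rasterB)
    if rasterA.shape[0] != rasterB.shape[0]:
        raise ValueError("streams must be time-aligned (equal sample counts)")
    hA = population_entropy(rasterA)
    hB = population_entropy(rasterB)
    hAB = population_entropy(np.concatenate([rasterA, rasterB], axis=1))
    return max(hA + hB - hAB, 0.0)


def entropy_bias_report(raster: np.ndarray,
                        fractions=(1.0, 0.8, 0.6, 0.5, 0.4),
                        seed: int = 0) -> pd.DataFrame:
    """Plug-in entropy on nested random subsamples of the word stream, for
    inspecting the estimator's sample-size dependence; a linear fit in
    1/samples gives an extrapolated (bias-reduced) estimate."""
    words = _as_words(raster)
    n = words.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    rows = []
    for f in sorted(fractions):
        m = max(1, int(round(f * n)))
        sub = words[perm[:m]]
        counts = np.fromiter(Counter(sub).values(), dtype=float)
        rows.append({"fraction": f, "samples": m,
                     "entropy_bits": _entropy_from_counts(counts, m)})
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        slope, intercept = np.polyfit(1.0 / df["samples"], df["entropy_bits"], 1)
        df.attrs["extrapolated_bits"] = float(intercept)
    return df


# ---------------------------------------------------------------------------
# correlations

def spike_burst_correlations(spike_trains: np.ndarray,
                             burst_trains: np.ndarray,
                             alpha: float = 0.05):
    """Pearson correlation between every (cortical unit, MSN) pair of
    equal-length series, zeroing coefficients that fail a two-sided t-test
    at level ``alpha``.

    Returns ``(r, significant, flags)``: the raw coefficient matrix, the
    significance mask, and a mask of pairs where r was undefined
    (zero-variance series, reported as zero).
    """
    S = np.asarray(spike_trains, dtype=float)
    B = np.asarray(burst_trains, dtype=float)
    if S.shape[0] != B.shape[0]:
        raise ValueError("series must have equal length")
    n = S.shape[0]
    Sc = S - S.mean(axis=0)
    Bc = B - B.mean(axis=0)
    s_sd = np.sqrt((Sc ** 2).sum(axis=0))
    b_sd = np.sqrt((Bc ** 2).sum(axis=0))
    denom = np.outer(s_sd, b_sd)
    flags = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Sc.T @ Bc) / denom
    r[flags] = 0.0
    r = np.clip(r, -1.0, 1.0)
    # two-sided t-test on r with n-2 dof
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    significant = (pvals < alpha) & ~flags
    return r, significant, flags


def d1_d2_group_comparison(r: np.ndarray, significant: np.ndarray,
                           msn_type: np.ndarray,
                           area_of_unit: np.ndarray,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Mean significance-filtered coefficient per (cortical area x MSN
    type), with a two-sample t-test between the D1 and D2 coefficient
    distributions per area."""
    rz = np.where(significant, r, 0.0)
    rows = []
    for area in np.unique(area_of_unit):
        sel = area_of_unit == area
        d1 = rz[np.ix_(sel, msn_type)].ravel()
        d2 = rz[np.ix_(sel, ~msn_type)].ravel()
        t, p = stats.ttest_ind(d1, d2, equal_var=False)
        rows.append({"area": int(area), "mean_r_d1": d1.mean(),
                     "mean_r_d2": d2.mean(), "t": float(t), "p": float(p),
                     "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# burst / rate statistics

def transient_durations(trace: np.ndarray) -> np.ndarray:
    """Durations (in samples) of completed positive transients of a 1-D
    trace (onset at crossing above 0, offset at return to <= 0)."""
    pos = np.asarray(trace) > 0
    d = np.diff(pos.astype(np.int8))
    on = np.flatnonzero(d == 1) + 1
    off = np.flatnonzero(d == -1) + 1
    if pos[0] and off.size:
        off = off[1:]   # transient already in progress at t=0: not completed
    m = min(on.size, off.size)
    return (off[:m] - on[:m]).astype(np.int64)


def all_transient_durations(traces: np.ndarray) -> np.ndarray:
    """Pooled positive-transient durations across columns of a
    (time x unit) trace array."""
    return np.concatenate([transient_durations(traces[:, i])
                           for i in range(traces.shape[1])] or
                          [np.array([], dtype=np.int64)])


def bout_durations(trace: np.ndarray, merge_gap: int = 500) -> np.ndarray:
    """Durations (samples) of bursts-of-bursts: positive transients of a
    trace merged into one bout when separated by less than ``merge_gap``
    samples."""
    pos = np.asarray(trace) > 0
    idx = np.flatnonzero(pos)
    if idx.size == 0:
        return np.array([], dtype=np.int64)
    breaks = np.flatnonzero(np.diff(idx) >= merge_gap)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return (ends - starts + 1).astype(np.int64)


def dwell_times(raster: np.ndarray, smooth_ms: int = 50,
                corr_threshold: float = 0.8) -> np.ndarray:
    """Traversal dwell times: run lengths (ms) over which successive
    smoothed population vectors stay pairwise-correlated above threshold.

    The raster is averaged over non-overlapping ``smooth_ms`` windows (so
    successive vectors share no samples); a dwell ends when the correlation
    between a window's population vector and the next drops below the
    threshold.  Trend-level only; the window and threshold are operating
    choices, not model quantities.
    """
    X = np.asarray(raster, dtype=float)
    n_win = X.shape[0] // smooth_ms
    if n_win < 2:
        return np.array([], dtype=np.int64)
    sm = X[: n_win * smooth_ms].reshape(n_win, smooth_ms, -1).mean(axis=1)
    sm = sm - sm.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(sm, axis=1)
    ok = norms > 0
    num = (sm[1:] * sm[:-1]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = num / (norms[1:] * norms[:-1])
    c[~(ok[1:] & ok[:-1])] = 0.0
    stable = c >= corr_threshold
    runs = []
    count = 1
    for s in stable:
        if s:
            count += 1
        else:
            runs.append(count)
            count = 1
    runs.append(count)
    return np.asarray(runs, dtype=np.int64) * smooth_ms


def burst_and_rate_stats(layer5_raster: np.ndarray | None = None,
                         da_raster: np.ndarray | None = None,
                         x_f: np.ndarray | None = None,
                         bin_ms: float = 1.0) -> pd.DataFrame:
    """Summary table of population set points: mean firing rates
    (spikes/s), MSN positive-transient duration statistics (ms), dopamine
    inter-spike-interval statistics, and traversal dwell times (ms)."""
    rows = []

    def rate_row(name, raster):
        rate = raster.mean() * 1000.0 / bin_ms
        rows.append({"population": name, "statistic": "mean_rate_hz",
                     "value": float(rate)})

    if layer5_raster is not None:
        rate_row("layer5", layer5_raster)
        dw = dwell_times(layer5_raster)
        if dw.size:
            rows.append({"population": "layer5",
                         "statistic": "mean_dwell_ms",
                         "value": float(dw.mean() * bin_ms)})
    if da_raster is not None:
        rate_row("dopamine", da_raster)
        isis = []
        for i in range(da_raster.shape[1]):
            tspk = np.flatnonzero(da_raster[:, i])
            if tspk.size > 1:
                isis.append(np.diff(tspk))
        if isis:
            isis = np.concatenate(isis) * bin_ms
            rows.append({"population": "dopamine",
                         "statistic": "mean_isi_ms",
                         "value": float(isis.mean())})
            rows.append({"population": "dopamine",
                         "statistic": "cv_isi",
                         "value": float(isis.std() / isis.mean())})
    if x_f is not None:
        durs = all_transient_durations(x_f) * bin_ms
        if durs.size:
            rows.append({"population": "striatum",
                         "statistic": "mean_burst_duration_ms",
                         "value": float(durs.mean())})
            rows.append({"population": "striatum",
                         "statistic": "n_bursts",
                         "value": float(durs.size)})
    return pd.DataFrame(rows)
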