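"""Neural ITD-sensitivity quantification: AMUA, spike detection, tuning, STVR.

The analog multi-unit activity (AMUA) measure band-passes the raw
extracellular signal to the spike band (300 Hz-6 kHz), rectifies it, and
low-passes at 6 kHz; its mean over a response window is a spike-density
proxy robust to spike collisions.  Per-trial response amplitudes grouped
by stimulus ITD feed a one-way ANOVA; the signal-to-total variance ratio

    STVR = SS_group / SS_total

is the fraction of trial-to-trial response variance explained by ITD
(0 = no effect, 1 = responses fully determined by ITD), with significance
from the ANOVA F test at p <= 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal
from scipy.stats import f as f_dist

from .neuro_sim import RecordingBlock

__all__ = [
    "AMUAConfig",
    "AnalysisWindows",
    "ResponseMatrix",
    "STVRResult",
    "compute_amua",
    "detect_spikes",
    "build_response_matrix",
    "tuning_curve",
    "compute_stvr",
    "stvr_null_distribution",
]


@dataclass(frozen=True)
class AMUAConfig:
    """AMUA filter chain: band-pass, rectify, low-pass (all at native rate)."""

    bp_low_hz: float = 300.0
    bp_high_hz: float = 6000.0
    lp_hz: float = 6000.0
    filter_order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.bp_low_hz < self.bp_high_hz:
            raise ValueError("need 0 < bp_low_hz < bp_high_hz")


@dataclass(frozen=True)
class AnalysisWindows:
    """Post-onset analysis windows (ms): response, baseline, artifact blank."""

    response_ms: tuple[float, float] = (3.0, 80.0)
    baseline_ms: tuple[float, float] = (300.0, 500.0)
    artifact_blank_ms: float = 2.5

    def __post_init__(self) -> None:
        r0, r1 = self.response_ms
        b0, b1 = self.baseline_ms
        if not (r0 < r1 <= b0 < b1):
            raise ValueError("response and baseline windows must be ordered and disjoint")
        if self.artifact_blank_ms < 0:
            raise ValueError("artifact_blank_ms must be >= 0")

    @property
    def effective_response_ms(self) -> tuple[float, float]:
        """Response window with the artifact blank removed from its start."""
        return (max(self.response_ms[0], self.artifact_blank_ms), self.response_ms[1])


@dataclass
class ResponseMatrix:
    """Per-trial response amplitudes grouped by ITD: (levels x repeats)."""

    values: np.ndarray
    itd_levels_us: np.ndarray
    measure: Literal["amua_mean", "spike_count"]
    baselines: np.ndarray | None = None  # per-trial baseline means, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.itd_levels_us = np.asarray(self.itd_levels_us, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.itd_levels_us.size:
            raise ValueError("values must be (n_levels, n_repeats)")


@dataclass
class STVRResult:
    """One-way-ANOVA summary of a response matrix."""

    stvr: float
    ss_group: float
    ss_total: float
    f_stat: float
    p_value: float
    df_between: int
    df_within: int

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.01


def _sos(cfg: AMUAConfig, fs: float):
    nyq = fs / 2.0
    hi = cfg.bp_high_hz
    if hi >= nyq:
        warnings.warn(
            f"bp_high_hz {hi} >= Nyquist {nyq}; clipping to 0.99*Nyquist",
            RuntimeWarning,
            stacklevel=3,
        )
        hi = 0.99 * nyq
    bp = signal.butter(cfg.filter_order, [cfg.bp_low_hz, hi], "bandpass", fs=fs, output="sos")
    lp_hz = min(cfg.lp_hz, 0.99 * nyq)
    lp = signal.butter(cfg.filter_order, lp_hz, "lowpass", fs=fs, output="sos")
    return bp, lp


def _filt(sos, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    return signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)


def bandpass(trace: np.ndarray, fs: float, cfg: AMUAConfig | None = None) -> np.ndarray:
    """Spike-band (300 Hz-6 kHz) filtered trace."""
    cfg = cfg or AMUAConfig()
    bp, _ = _sos(cfg, fs)
    return _filt(bp, np.asarray(trace, float), cfg.zero_phase)


def compute_amua(trace: np.ndarray, fs: float, config: AMUAConfig | None = None) -> np.ndarray:
    """AMUA: band-pass, rectify (absolute value), low-pass, at native rate.

    The output is non-negative up to low-pass filter ringing.
    """
    config = config or AMUAConfig()
    x = np.asarray(trace, dtype=float)
    warmup = 3 * (2 * config.filter_order + 1)
    if x.size <= warmup:
        raise ValueError(f"trace too short for filter warm-up ({x.size} <= {warmup})")
    bp, lp = _sos(config, fs)
    y = np.abs(_filt(bp, x, config.zero_phase))
    return _filt(lp, y, config.zero_phase)


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    config: AMUAConfig | None = None,
    k_sd: float = 4.0,
    refractory_ms: float = 1.0,
    exclude_spans_s: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Threshold-crossing spike times (s) on the band-passed trace.

    The threshold is ``k_sd`` standard deviations of the band-passed
    signal (plain SD; optionally estimated excluding artifact spans);
    crossings of either polarity count, and detections within
    ``refractory_ms`` of the previous one are merged.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < int(0.1 * fs):
        raise ValueError("trace must be at least 100 ms long for SD estimation")
    y = bandpass(x, fs, config)
    keep = np.ones(y.size, dtype=bool)
    if exclude_spans_s:
        for t0, t1 in exclude_spans_s:
            keep[int(t0 * fs) : int(np.ceil(t1 * fs))] = False
    sd = float(np.std(y[keep]))
    if sd == 0.0:
        raise ValueError("zero-variance trace: spike threshold undefined")
    a = np.abs(y)
    thr = k_sd * sd
    above = a >= thr
    prev = np.concatenate([[False], above[:-1]])
    crossings = np.flatnonzero(above & ~prev)
    if crossings.size == 0:
        return np.empty(0)
    refr = refractory_ms / 1000.0 * fs
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= refr:
            kept.append(c)
    return np.asarray(kept) / fs


def _window_means(
    series: np.ndarray, fs: float, events_s: np.ndarray, win_ms: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of a series in a post-event window; returns (means, valid mask)."""
    i0 = np.round((events_s + win_ms[0] / 1000.0) * fs).astype(int)
    i1 = np.round((events_s + win_ms[1] / 1000.0) * fs).astype(int)
    valid = (i0 >= 0) & (i1 <= series.size) & (i1 > i0)
    means = np.full(events_s.size, np.nan)
    for j in np.flatnonzero(valid):
        means[j] = series[i0[j] : i1[j]].mean()
    return means, valid


def build_response_matrix(
    rec: RecordingBlock,
    windows: AnalysisWindows | None = None,
    measure: Literal["amua_mean", "spike_count"] = "amua_mean",
    channel: int = 0,
    amua_config: AMUAConfig | None = None,
    spike_times_s: np.ndarray | None = None,
) -> ResponseMatrix:
    """Per-event response amplitudes grouped by ITD level.

    ``amua_mean``: mean AMUA over the response window (artifact blank
    removed from its start).  ``spike_count``: threshold-crossing count in
    the same window, or counts of ``spike_times_s`` when given (e.g.
    ground-truth spikes).  Events whose windows fall outside the trace are
    dropped with a warning; levels are subsampled to the common repeat
    count if the design ends up ragged.
    """
    windows = windows or AnalysisWindows()
    trace = rec.trace[channel]
    fs = rec.sample_rate_hz
    win = windows.effective_response_ms

    if measure == "amua_mean":
        series = compute_amua(trace, fs, amua_config)
        resp, valid = _window_means(series, fs, rec.event_times_s, win)
        base, bvalid = _window_means(series, fs, rec.event_times_s, windows.baseline_ms)
        valid &= bvalid
    elif measure == "spike_count":
        if spike_times_s is None:
            blank = [
                (t, t + windows.artifact_blank_ms / 1000.0) for t in rec.event_times_s
            ]
            spike_times_s = detect_spikes(trace, fs, amua_config, exclude_spans_s=blank)
        t = np.asarray(spike_times_s)
        ev = rec.event_times_s
        resp = np.array(
            [np.sum((t >= e + win[0] / 1e3) & (t < e + win[1] / 1e3)) for e in ev],
            dtype=float,
        )
        base = np.array(
            [
                np.sum(
                    (t >= e + windows.baseline_ms[0] / 1e3)
                    & (t < e + windows.baseline_ms[1] / 1e3)
                )
                for e in ev
            ],
            dtype=float,
        )
        end_s = trace.size / fs
        valid = ev + windows.baseline_ms[1] / 1e3 <= end_s + 0.5 / fs
    else:
        raise ValueError(f"unknown measure {measure!r}")

    if not np.all(valid):
        warnings.warn(
            f"dropped {int(np.sum(~valid))} events outside trace bounds",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = rec.itd_labels_us[valid]
    resp, base = resp[valid], base[valid]
    levels = np.unique(labels)
    counts = [int(np.sum(labels == lv)) for lv in levels]
    n_min = min(counts)
    if len(set(counts)) > 1:
        warnings.warn(
            f"ragged design; subsampling every level to {n_min} repeats",
            RuntimeWarning,
            stacklevel=2,
        )
    values = np.empty((levels.size, n_min))
    baselines = np.empty_like(values)
    for i, lv in enumerate(levels):
        idx = np.flatnonzero(labels == lv)[:n_min]
        values[i] = resp[idx]
        baselines[i] = base[idx]
    return ResponseMatrix(values, levels, measure, baselines)


def tuning_curve(
    matrix: ResponseMatrix, baselines: np.ndarray | None = None
) -> "pd.DataFrame":
    """Baseline-corrected tuning curve normalized to its maximum mean response.

    Per level: mean response minus the grand mean baseline, divided by the
    maximum baseline-corrected mean across levels (so the curve peaks at
    1 whenever any level exceeds baseline); SEM on the same scale.  If no
    level exceeds baseline, normalization uses |max| and the result is
    flagged in the ``normalized_by_abs`` attribute.
    """
    import pandas as pd

    base = baselines if baselines is not None else matrix.baselines
    base_mean = float(np.mean(base)) if base is not None else 0.0
    mean = matrix.values.mean(axis=1) - base_mean
    sem = matrix.values.std(axis=1, ddof=1) / np.sqrt(matrix.values.shape[1])
    mx = float(mean.max())
    by_abs = mx <= 0
    denom = abs(mx) if by_abs else mx
    if denom == 0:
        raise ValueError("flat response at baseline: normalization undefined")
    if by_abs:
        warnings.warn("no level exceeds baseline; normalizing by |max|", RuntimeWarning)
    df = pd.DataFrame(
        {
            "itd_us": matrix.itd_levels_us,
            "mean": matrix.values.mean(axis=1),
            "sem": sem,
            "norm_mean": mean / denom,
            "norm_sem": sem / denom,
        }
    )
    df.attrs["normalized_by_abs"] = by_abs
    df.attrs["baseline_mean"] = base_mean
    return df


def compute_stvr(matrix: ResponseMatrix | Sequence[np.ndarray]) -> STVRResult:
    """Signal-to-total variance ratio via one-way ANOVA of responses by ITD.

    stvr = SS_group / SS_total; F = (SS_group/df_between) /
    (SS_within/df_within); p from the F distribution.  Accepts a
    ResponseMatrix or a ragged list of per-level arrays (unequal repeat
    counts use the general unbalanced ANOVA formulas).
    """
    if isinstance(matrix, ResponseMatrix):
        groups = [matrix.values[i] for i in range(matrix.values.shape[0])]
    else:
        groups = [np.asarray(g, dtype=float) for g in matrix]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 ITD levels")
    if any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 repeats per level")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    if ss_total == 0.0:
        raise ValueError("zero total variance: STVR undefined")
    ss_group = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_group
    df_b = k - 1
    df_w = allv.size - k
    f_stat = (ss_group / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    p = float(f_dist.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0
    return STVRResult(ss_group / ss_total, ss_group, ss_total, float(f_stat), p, df_b, df_w)


@dataclass
class STVRNull:
    observed_stvr: float
    permutation_p: float
    null_stvr: np.ndarray

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.null_stvr, q)


def stvr_null_distribution(
    matrix: ResponseMatrix, n_perm: int = 2000, seed: int = 0
) -> STVRNull:
    """Permutation null for the STVR: label shuffles of the pooled responses.

    The permutation p-value is (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", RuntimeWarning)
    obs = compute_stvr(matrix)
    vals = matrix.values
    k, n = vals.shape
    flat = vals.ravel().copy()
    rng = np.random.default_rng(seed)
    grand = flat.mean()
    ss_total = float(np.sum((flat - grand) ** 2))
    null = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(flat)
        m = flat.reshape(k, n).mean(axis=1)
        null[i] = n * float(np.sum((m - grand) ** 2)) / ss_total
    p = (1.0 + float(np.sum(null >= obs.stvr))) / (n_perm + 1.0)
    return STVRNull(obs.stvr, p, null)
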