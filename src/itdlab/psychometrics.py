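"""Maximum-likelihood fitting of the four-parameter probit psychometric model.

The model for the probability of a 'right' choice as a function of the
interaural time difference (ITD, in ms, left-arrival minus right-arrival) is

    p_R(ITD) = Phi(ITD * alpha + beta) * (1 - gamma) + gamma/2 + delta

where Phi is the standard normal CDF, alpha (1/ms) scales sensitivity,
beta shifts the perceptual midline, gamma in [0, 1] is the lapse rate and
delta an additive spout bias.  The sensitivity summary is the slope of the
fitted curve at ITD = 0,

    slope = phi(0) * alpha * (1 - gamma)

with phi(0) = 0.3989... the standard normal density at zero; reported in
percent 'right' per µs (the per-ms slope divided by 10).  The 75%-correct
threshold is the mean absolute ITD at which the fitted curve crosses 25%
and 75% 'right'.

Fitting maximizes the Bernoulli likelihood over non-correction trials with
multi-start L-BFGS-B under box constraints that keep p_R a valid
probability over the fitted range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import mannwhitneyu, norm, wilcoxon
from statsmodels.stats.proportion import proportion_confint

from .behavior_sim import TrialRecord, filter_analysis_trials

__all__ = [
    "PsychometricFit",
    "FitReport",
    "FitConfig",
    "wilson_interval",
    "neg_log_likelihood",
    "fit_psychometric",
    "slope_at_zero",
    "threshold75",
    "proportions_by_itd",
    "compare_groups",
]

PHI0 = float(norm.pdf(0.0))  # 0.3989...
_EPS = 1e-9

# One hardware ITD step (20.48 µs = 0.02048 ms) can span the whole curve:
# alpha up to ~300/ms puts +-3 SD of the probit inside a single step.
ALPHA_MAX_PER_MS = 300.0
BOUNDS = dict(
    alpha=(0.0, ALPHA_MAX_PER_MS),
    beta=(-5.0, 5.0),
    gamma=(0.0, 0.5),
    delta=(-0.3, 0.3),
)


@dataclass
class PsychometricFit:
    """Maximum-likelihood parameter estimates of the probit model."""

    alpha_per_ms: float
    beta: float
    gamma: float
    delta: float
    neg_log_likelihood: float
    converged: bool
    n_trials_used: int
    at_boundary: bool = False

    def predict(self, itd_ms: float | np.ndarray) -> np.ndarray | float:
        """Fitted p_R at an ITD in ms (clamped to [0, 1])."""
        p = (
            norm.cdf(np.asarray(itd_ms, dtype=float) * self.alpha_per_ms + self.beta)
            * (1.0 - self.gamma)
            + self.gamma / 2.0
            + self.delta
        )
        out = np.clip(p, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class FitReport:
    """Derived summaries of a psychometric fit."""

    slope_pct_per_us: float
    threshold75_us: float | None
    itd25_us: float | None
    itd75_us: float | None
    proportions: pd.DataFrame


@dataclass
class FitConfig:
    n_starts: int = 6
    seed: int = 0
    exact_slope: bool = False  # evaluate the density at beta instead of 0


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must lie in (0, 1)")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return float(lo), float(hi)


def _trials_to_arrays(trials: Iterable[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    itd_ms = np.array([t.itd_us / 1000.0 for t in trials], dtype=float)
    right = np.array([t.response == "R" for t in trials], dtype=float)
    return itd_ms, right


def _model_p(params: np.ndarray, itd_ms: np.ndarray) -> np.ndarray:
    a, b, g, d = params
    return norm.cdf(itd_ms * a + b) * (1.0 - g) + g / 2.0 + d


def neg_log_likelihood(
    params: Sequence[float], trials: Sequence[TrialRecord]
) -> float:
    """Trial-wise Bernoulli negative log-likelihood of (alpha, beta, gamma, delta).

    Probabilities are clamped to [1e-9, 1 - 1e-9]; clamping warns.
    Corrections must already be excluded by the caller.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    itd_ms, right = _trials_to_arrays(trials)
    p = _model_p(np.asarray(params, dtype=float), itd_ms)
    if np.any((p < _EPS) | (p > 1.0 - _EPS)):
        warnings.warn("likelihood probabilities clamped", RuntimeWarning, stacklevel=2)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    nll = -float(np.sum(right * np.log(p) + (1.0 - right) * np.log1p(-p)))
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite negative log-likelihood")
    return nll


def _binned_nll(params: np.ndarray, itd_ms: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    # Per-level binomial counts give the same sum as the trial-wise Bernoulli NLL.
    p = np.clip(_model_p(params, itd_ms), _EPS, 1.0 - _EPS)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _heuristic_start(itd_ms: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    # Probit regression on per-level proportions clamped away from 0/1.
    p_hat = np.clip(k / n, 0.02, 0.98)
    z = norm.ppf(p_hat)
    if itd_ms.size >= 2 and np.ptp(itd_ms) > 0:
        a, b = np.polyfit(itd_ms, z, 1)
    else:  # degenerate design; fall back to a shallow curve
        a, b = 5.0, 0.0
    a = float(np.clip(a, *BOUNDS["alpha"]))
    b = float(np.clip(b, *BOUNDS["beta"]))
    return np.array([a, b, 0.02, 0.0])


def fit_psychometric(
    trials: Sequence[TrialRecord], config: FitConfig | None = None
) -> tuple[PsychometricFit, FitReport]:
    """Fit the probit model by multi-start maximum likelihood.

    Correction trials are excluded here; the fit is invariant to trial
    order (the likelihood only sees per-level counts).  Requires at least
    two distinct ITD levels.  Degenerate data (all responses on one side)
    produce a boundary-flagged fit rather than an error.
    """
    config = config or FitConfig()
    kept = filter_analysis_trials(trials)
    if not kept:
        raise ValueError("no non-correction trials to fit")
    tab = proportions_by_itd(kept)
    if len(tab) < 2:
        raise ValueError("need >= 2 distinct ITD levels")
    itd_ms = tab["itd_us"].to_numpy() / 1000.0
    k = tab["k"].to_numpy(dtype=float)
    n = tab["n"].to_numpy(dtype=float)

    rng = np.random.default_rng(config.seed)
    starts = [_heuristic_start(itd_ms, k, n)]
    for _ in range(config.n_starts - 1):
        base = starts[0].copy()
        base[0] = np.clip(base[0] * rng.uniform(0.3, 3.0), *BOUNDS["alpha"])
        base[1] = np.clip(base[1] + rng.normal(0, 0.5), *BOUNDS["beta"])
        base[2] = rng.uniform(0.0, 0.3)
        base[3] = rng.uniform(-0.1, 0.1)
        starts.append(base)

    bounds = [BOUNDS["alpha"], BOUNDS["beta"], BOUNDS["gamma"], BOUNDS["delta"]]
    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            _binned_nll, x0, args=(itd_ms, k, n), method="L-BFGS-B", bounds=bounds
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    a, b, g, d = (float(v) for v in best.x)
    # Box-bound hits and separable data (near-zero deviance ridge) are both
    # degenerate: the MLE is not interior and standard errors are meaningless.
    at_boundary = bool(
        np.isclose(a, BOUNDS["alpha"][1])
        or np.isclose(g, BOUNDS["gamma"][1])
        or np.isclose(abs(d), BOUNDS["delta"][1])
        or best.fun < 1e-3
    )
    fit = PsychometricFit(
        alpha_per_ms=a,
        beta=b,
        gamma=g,
        delta=d,
        neg_log_likelihood=float(best.fun),
        converged=any_success,
        n_trials_used=len(kept),
        at_boundary=at_boundary,
    )
    thr = threshold75(fit)
    report = FitReport(
        slope_pct_per_us=slope_at_zero(fit, exact=config.exact_slope),
        threshold75_us=thr[0],
        itd25_us=thr[1],
        itd75_us=thr[2],
        proportions=tab,
    )
    return fit, report


def slope_at_zero(fit: PsychometricFit, exact: bool = False) -> float:
    """Psychometric slope in % 'right' per µs.

    Default: phi(0) * alpha * (1 - gamma) / 10 — the conventional summary,
    which evaluates the normal density at 0 regardless of the bias beta.
    With ``exact=True`` the density is evaluated at beta, giving the true
    derivative of the fitted curve at ITD = 0.
    """
    dens = float(norm.pdf(fit.beta)) if exact else PHI0
    return dens * fit.alpha_per_ms * (1.0 - fit.gamma) / 10.0


def _crossing(fit: PsychometricFit, level: float) -> float | None:
    lo, hi = -10.0, 10.0  # ms
    f = lambda x: fit.predict(x) - level
    if f(lo) * f(hi) > 0:
        return None  # level unreachable given gamma/delta
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


def threshold75(
    fit: PsychometricFit,
) -> tuple[float | None, float | None, float | None]:
    """75%-correct threshold: mean |ITD| of the 25% and 75% crossings (µs).

    Returns ``(threshold_us, itd25_us, itd75_us)``; all None when either
    level is unreachable (for example when the lapse rate caps the curve
    below 75%).
    """
    c25 = _crossing(fit, 0.25)
    c75 = _crossing(fit, 0.75)
    if c25 is None or c75 is None:
        return None, None, None
    itd25_us, itd75_us = c25 * 1000.0, c75 * 1000.0
    return (abs(itd25_us) + abs(itd75_us)) / 2.0, itd25_us, itd75_us


def proportions_by_itd(trials: Sequence[TrialRecord], conf: float = 0.95) -> pd.DataFrame:
    """Per-ITD response table: n, k ('right' count), p_hat and Wilson CI.

    Expects corrections to be excluded already; rows sorted by ITD.
    """
    rows = []
    itd_us = np.array([t.itd_us for t in trials], dtype=float)
    right = np.array([t.response == "R" for t in trials])
    for level in np.unique(itd_us):
        mask = itd_us == level
        n, kk = int(mask.sum()), int(right[mask].sum())
        lo, hi = wilson_interval(kk, n, conf)
        rows.append((level, n, kk, kk / n, lo, hi))
    return pd.DataFrame(
        rows, columns=["itd_us", "n", "k", "p_hat", "wilson_low", "wilson_high"]
    )


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float


def compare_groups(
    slopes_a: Sequence[float],
    slopes_b: Sequence[float],
    paired: bool = True,
) -> GroupComparison:
    """Wilcoxon comparison of two groups of psychometric slopes.

    Paired: signed-rank test with zero differences dropped (Wilcoxon's
    original convention) and exact p-values for n <= 25 when the
    difference magnitudes are tie-free.  Unpaired: Mann-Whitney rank-sum,
    exact for small tie-free samples.  All differences zero gives p = 1.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal lengths")
        d = a - b
        nz = d[d != 0.0]
        if nz.size == 0:
            return GroupComparison(
                0.0, 1.0, "wilcoxon-signed-rank (all differences zero)",
                float(np.median(a)), float(np.median(b)),
                float(np.mean(a)), float(np.mean(b)),
            )
        tie_free = np.unique(np.abs(nz)).size == nz.size
        method = "exact" if (nz.size <= 25 and tie_free) else "auto"
        res = wilcoxon(a, b, zero_method="wilcox", method=method)
        name = f"wilcoxon-signed-rank ({method})"
    else:
        tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 25 and tie_free) else "auto"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        name = f"mann-whitney-rank-sum ({method})"
    return GroupComparison(
        float(res.statistic), float(res.pvalue), name,
        float(np.median(a)), float(np.median(b)),
        float(np.mean(a)), float(np.mean(b)),
    )
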