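"""Synthetic 2AFC lateralization sessions with correction-trial dynamics.

A simulated rat hears a pulse train with some ITD and licks the left or
right response spout.  Choices are Bernoulli draws from the four-parameter
probit psychometric model

    p_R(ITD) = Phi(ITD * alpha + beta) * (1 - gamma) + gamma/2 + delta

with sensitivity ``alpha`` (1/ms), ear bias ``beta`` (shift of the
perceptual midline, in units of the probit argument), lapse rate ``gamma``
(fraction of stimulus-independent guesses) and spout bias ``delta``
(additive preference for the right spout).  After an incorrect response
the same ITD is repeated as a "correction trial"; correction trials are
flagged and excluded from psychometric analysis because a "change side
after a mistake" strategy answers them without attending to the stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "GroundTruthModel",
    "TrialRecord",
    "DEFAULT_ITD_SET_US",
    "response_probability",
    "simulate_session",
    "filter_analysis_trials",
]

#: Behavioral ITD set (µs): 25 µs steps plus the ±160 µs endpoints.
DEFAULT_ITD_SET_US: tuple[float, ...] = (
    -160.0, -150.0, -125.0, -100.0, -75.0, -50.0, -25.0,
    0.0,
    25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 160.0,
)


@dataclass(frozen=True)
class GroundTruthModel:
    """Generative psychometric parameters (alpha in 1/ms)."""

    alpha_per_ms: float
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class TrialRecord:
    """One 2AFC trial of a lateralization session."""

    session_id: str
    trial_index: int
    itd_us: float
    response: Literal["L", "R"]
    correct: bool
    is_correction: bool
    rng_seed_ref: int


def response_probability(
    model: GroundTruthModel, itd_ms: float | np.ndarray, warn_on_clamp: bool = True
):
    """Probability of a 'right' response at a given ITD (ms, left-minus-right).

    Evaluates Phi(ITD*alpha + beta)*(1-gamma) + gamma/2 + delta and clamps
    the result to [0, 1]; clamping (possible when delta pushes the curve
    outside the unit interval) triggers a warning.
    """
    p = (
        norm.cdf(np.asarray(itd_ms, dtype=float) * model.alpha_per_ms + model.beta)
        * (1.0 - model.gamma)
        + model.gamma / 2.0
        + model.delta
    )
    clamped = (p < 0.0) | (p > 1.0)
    if np.any(clamped) and warn_on_clamp:
        warnings.warn(
            "response probability clamped to [0, 1] (delta pushed it outside)",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _rewarded_side(itd_us: float, rng: np.random.Generator) -> str:
    # Positive ITD (right ear leading) is reinforced at the right spout;
    # zero-ITD trials are rewarded at a uniformly random side.
    if itd_us > 0:
        return "R"
    if itd_us < 0:
        return "L"
    return "R" if rng.random() < 0.5 else "L"


def simulate_session(
    model: GroundTruthModel,
    itd_set_us: Sequence[float] = DEFAULT_ITD_SET_US,
    n_trials: int = 1000,
    seed: int = 0,
    *,
    session_id: str = "sim",
    count: Literal["total", "analysis"] = "total",
    max_corrections: int | None = None,
) -> list[TrialRecord]:
    """Simulate one session of the 2AFC task.

    After each correct trial a new ITD is drawn uniformly from
    ``itd_set_us``; after each incorrect trial the same ITD repeats as a
    correction trial (until correct, or until ``max_corrections``
    consecutive corrections, after which a fresh ITD is drawn).  With
    ``count='total'`` the log holds ``n_trials`` records; with
    ``count='analysis'`` the session runs until it holds ``n_trials``
    NON-correction trials.  Identical arguments reproduce identical logs.
    """
    itd_set = [float(v) for v in itd_set_us]
    if not itd_set:
        raise ValueError("itd_set_us must be non-empty")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    n_analysis = 0
    itd_us = itd_set[rng.integers(len(itd_set))]
    is_correction = False
    run_corrections = 0
    idx = 0
    while (len(records) if count == "total" else n_analysis) < n_trials:
        p_right = response_probability(model, itd_us / 1000.0, warn_on_clamp=False)
        response = "R" if rng.random() < p_right else "L"
        correct = response == _rewarded_side(itd_us, rng)
        records.append(
            TrialRecord(session_id, idx, itd_us, response, correct, is_correction, seed)
        )
        idx += 1
        if not is_correction:
            n_analysis += 1
        if correct:
            itd_us = itd_set[rng.integers(len(itd_set))]
            is_correction = False
            run_corrections = 0
        else:
            run_corrections += 1
            if max_corrections is not None and run_corrections > max_corrections:
                itd_us = itd_set[rng.integers(len(itd_set))]
                is_correction = False
                run_corrections = 0
            else:
                is_correction = True
    return records


def filter_analysis_trials(log: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Drop correction trials; order preserved."""
    return [t for t in log if not t.is_correction]
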