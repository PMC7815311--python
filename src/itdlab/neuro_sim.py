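"""Synthetic extracellular recordings with ITD-tuned multi-unit activity.

Generates raw multichannel-style voltage traces that emulate inferior
colliculus recordings under binaural pulse stimulation: an ITD-tuned
inhomogeneous Poisson spike process rendered as biphasic extracellular
waveforms in white noise, a short stimulus-artifact transient after each
onset, and the standard trial structure (17 ITD levels spanning
±163.84 µs in 20.48 µs steps, 30 repeats each, 500 ms inter-stimulus
interval).  Ground truth (tuning function and spike times) is retained so
the analysis chain can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TuningFunction",
    "RecordingBlock",
    "RECORDING_FS_HZ",
    "make_trial_schedule",
    "spike_template",
    "simulate_recording",
]

#: Default recording sample rate (Hz); the nominal hardware rate behind "24.414 kHz".
RECORDING_FS_HZ = 24414.0625


@dataclass(frozen=True)
class TuningFunction:
    """Parametric ITD tuning of a simulated multi-unit site.

    ``rate(itd)`` in the response window interpolates between
    ``driven_rate_hz * (1 - depth)`` and ``driven_rate_hz`` according to
    the tuning shape; ``depth=0`` makes the rate ITD-independent.
    Baseline firing continues at ``base_rate_hz`` throughout the trace.
    """

    shape: Literal["peak", "sigmoid", "trough", "multipeak"] = "sigmoid"
    depth: float = 0.8
    best_itd_us: float = 0.0
    width_us: float = 80.0
    base_rate_hz: float = 20.0
    driven_rate_hz: float = 150.0
    response: Literal["onset", "sustained"] = "sustained"

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")
        if self.base_rate_hz < 0 or self.driven_rate_hz < 0:
            raise ValueError("rates must be non-negative")

    def _shape_gain(self, itd_us: np.ndarray) -> np.ndarray:
        x = (itd_us - self.best_itd_us) / self.width_us
        if self.shape == "peak":
            return np.exp(-0.5 * x**2)
        if self.shape == "trough":
            return 1.0 - np.exp(-0.5 * x**2)
        if self.shape == "sigmoid":
            return 1.0 / (1.0 + np.exp(-x))
        if self.shape == "multipeak":
            return 0.5 * (1.0 + np.cos(np.pi * x))
        raise ValueError(f"unknown shape {self.shape!r}")

    def rate(self, itd_us: float | np.ndarray) -> np.ndarray | float:
        """Driven firing rate (Hz) in the response window at a given ITD (µs)."""
        g = self._shape_gain(np.asarray(itd_us, dtype=float))
        r = self.driven_rate_hz * (1.0 - self.depth + self.depth * g)
        return float(r) if r.ndim == 0 else r

    @property
    def response_window_ms(self) -> tuple[float, float]:
        """Window of elevated firing after onset: 3-15 ms (onset) or 3-80 ms (sustained)."""
        return (3.0, 15.0) if self.response == "onset" else (3.0, 80.0)


@dataclass
class RecordingBlock:
    """Raw trace plus stimulus events; the container the analysis consumes."""

    trace: np.ndarray  # (channels, samples)
    sample_rate_hz: float
    event_times_s: np.ndarray
    itd_labels_us: np.ndarray
    ground_truth_tuning: TuningFunction | None = None
    ground_truth_spikes_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trace = np.atleast_2d(np.asarray(self.trace))
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.itd_labels_us = np.asarray(self.itd_labels_us, dtype=float)
        if self.event_times_s.size != self.itd_labels_us.size:
            raise ValueError("event times and ITD labels must have equal length")
        if np.any(np.diff(self.event_times_s) < 0):
            raise ValueError("event times must be sorted ascending")


def make_trial_schedule(
    itd_min_us: float = -163.84,
    itd_max_us: float = 163.84,
    step_us: float = 20.48,
    n_repeats: int = 30,
    isi_ms: float = 500.0,
    seed: int = 0,
    order: Literal["shuffle", "blocked"] = "shuffle",
    start_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-random trial schedule: each ITD level exactly ``n_repeats`` times.

    Defaults give the standard full design: 17 levels x 30 repeats = 510
    events at 500 ms spacing.  ``order='blocked'`` shuffles levels within
    each repeat block instead of shuffling the full list.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n_steps = (itd_max_us - itd_min_us) / step_us
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step_us must divide the ITD range")
    levels = itd_min_us + step_us * np.arange(int(round(n_steps)) + 1)
    rng = np.random.default_rng(seed)
    if order == "shuffle":
        labels = np.repeat(levels, n_repeats)
        rng.shuffle(labels)
    elif order == "blocked":
        blocks = [rng.permutation(levels) for _ in range(n_repeats)]
        labels = np.concatenate(blocks)
    else:
        raise ValueError(f"unknown order {order!r}")
    times = start_s + np.arange(labels.size) * isi_ms / 1000.0
    return times, labels


def spike_template(fs: float, duration_ms: float = 1.2) -> np.ndarray:
    """Canonical biphasic extracellular spike waveform, peak-normalized to 1.

    Negative-leading biphasic shape (derivative-of-Gaussian) spanning
    ``duration_ms``; only its band-limited energy matters downstream.
    """
    n = max(int(round(duration_ms / 1000.0 * fs)), 3)
    t = np.linspace(-1.0, 1.0, n)
    w = -t * np.exp(-0.5 * (t / 0.35) ** 2)
    return w / np.max(np.abs(w))


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def simulate_recording(
    tuning: TuningFunction,
    schedule: tuple[np.ndarray, np.ndarray],
    noise_sd: float = 1.0,
    snr: float = 10.0,
    fs: float = RECORDING_FS_HZ,
    seed: int = 0,
    artifact_amplitude: float | None = None,
    n_channels: int = 1,
) -> RecordingBlock:
    """Render an ITD-tuning experiment as a raw voltage trace.

    Spikes are an inhomogeneous Poisson process: rate ``tuning.rate(itd)``
    inside the response window of each stimulus, ``base_rate_hz``
    elsewhere.  Each spike adds a biphasic template of peak amplitude
    ``snr * noise_sd`` (jittered ±20%) to white Gaussian noise.  The first
    2.5 ms after every onset carry a large damped-oscillation transient
    mimicking electrical stimulus artifact, so artifact blanking is
    exercised downstream.  Identical seeds give bit-identical traces.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    event_times, labels = np.asarray(schedule[0], float), np.asarray(schedule[1], float)
    rng = np.random.default_rng(seed)
    t_end = event_times[-1] + 0.5 if event_times.size else 1.0
    n_samples = int(round(t_end * fs))
    template = spike_template(fs) * snr * noise_sd

    # artifact transient: 2.5 ms damped oscillation, amplitude >> spikes
    if artifact_amplitude is None:
        artifact_amplitude = 20.0 * snr * noise_sd
    n_art = int(round(2.5e-3 * fs))
    t_art = np.arange(n_art) / fs
    artifact = artifact_amplitude * np.exp(-t_art / 0.5e-3) * np.cos(
        2 * np.pi * 3000.0 * t_art
    )

    win0, win1 = (w / 1000.0 for w in tuning.response_window_ms)
    channels = []
    all_spikes = None
    for _ in range(n_channels):
        trace = rng.normal(0.0, noise_sd, n_samples)
        # baseline spiking over the whole trace
        spikes = [_poisson_times(rng, tuning.base_rate_hz, 0.0, t_end)]
        for t_ev, itd in zip(event_times, labels):
            extra = float(tuning.rate(itd)) - tuning.base_rate_hz
            if extra > 0:
                spikes.append(_poisson_times(rng, extra, t_ev + win0, t_ev + win1))
        spike_times = np.sort(np.concatenate(spikes))
        idx = np.round(spike_times * fs).astype(int)
        for i in idx:
            hi = min(i + template.size, n_samples)
            if hi > i >= 0:
                trace[i:hi] += template[: hi - i] * rng.uniform(0.8, 1.2)
        ev_idx = np.round(event_times * fs).astype(int)
        for i in ev_idx:
            hi = min(i + n_art, n_samples)
            if hi > i >= 0:
                trace[i:hi] += artifact[: hi - i]
        channels.append(trace)
        if all_spikes is None:
            all_spikes = spike_times
    return RecordingBlock(
        trace=np.stack(channels),
        sample_rate_hz=fs,
        event_times_s=event_times,
        itd_labels_us=labels,
        ground_truth_tuning=tuning,
        ground_truth_spikes_s=all_spikes,
    )
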