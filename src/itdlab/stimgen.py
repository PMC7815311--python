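"""Binaural pulse-train stimulus construction with sample-quantized ITDs.

Electric stimuli are biphasic current pulse trains (positive phase, zero
gap, negative phase, in integer sample counts at the stimulator rate);
acoustic stimuli are single-sample "click" impulse trains.  Interaural time
differences (ITDs) are realized by delaying one channel by an integer
number of samples, so the achievable ITD grid is set by the sample rate:
one sample is 20.48 µs at 48828.125 Hz (electric) and 20.83 µs at
48000 Hz (acoustic).

Sign convention: the ITD axis is arrival time at the left ear minus
arrival time at the right ear, so negative ITD means the left ear leads.
Operationally, positive ``itd_us`` delays the right channel by
``round(itd_us * fs / 1e6)`` samples (see :func:`quantize_itd`); the
electrophysiology convention (positive = ipsilateral leading) is dataset
metadata, not a different axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSpec",
    "BinauralWaveform",
    "quantize_itd",
    "make_biphasic_pulse_train",
    "make_acoustic_click_train",
    "compute_rms_ild",
    "write_wav",
    "write_stimulus_h5",
    "read_stimulus_h5",
]

#: Stimulator sample rate used for intracochlear electric stimulation (Hz).
ELECTRIC_FS_HZ = 48828.125
#: Sound-card sample rate used for acoustic click stimuli (Hz).
ACOUSTIC_FS_HZ = 48000.0


@dataclass(frozen=True)
class StimulusSpec:
    """Timing parameters of a binaural pulse-train stimulus.

    Parameters
    ----------
    sample_rate_hz : float
        Output sample rate (Hz).
    pulse_rate_hz : float
        Pulse repetition rate (Hz).
    duration_ms : float
        Stimulus duration (ms).  The pulse count is
        ``floor(pulse_rate_hz * duration_ms / 1000)``.
    amplitude : float
        Peak amplitude (unitless).
    phase_samples_pos, phase_samples_gap, phase_samples_neg : int
        Biphasic pulse shape in integer samples: positive phase, zero gap,
        negative phase.  The clinical-style default (3/2/3 samples at
        48828.125 Hz) gives 61.44 µs / 40.96 µs / 61.44 µs.
    itd_us : float
        Requested interaural time difference (µs), positive = right channel
        delayed (left ear leading at the listener).
    """

    sample_rate_hz: float = ELECTRIC_FS_HZ
    pulse_rate_hz: float = 50.0
    duration_ms: float = 200.0
    amplitude: float = 1.0
    phase_samples_pos: int = 3
    phase_samples_gap: int = 2
    phase_samples_neg: int = 3
    itd_us: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.pulse_rate_hz <= 0:
            raise ValueError("pulse_rate_hz must be positive")
        for name in ("phase_samples_pos", "phase_samples_gap", "phase_samples_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_pulses(self) -> int:
        """Pulse count: floor(pulse_rate * duration); fractional pulses are dropped."""
        return int(math.floor(self.pulse_rate_hz * self.duration_ms / 1000.0 + 1e-9))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms / 1000.0 * self.sample_rate_hz))

    def phase_durations_us(self) -> tuple[float, float, float]:
        """Durations (µs) of the positive, gap and negative pulse phases."""
        dt = 1e6 / self.sample_rate_hz
        return (
            self.phase_samples_pos * dt,
            self.phase_samples_gap * dt,
            self.phase_samples_neg * dt,
        )


@dataclass
class BinauralWaveform:
    """Two-channel sample buffer plus the ITD bookkeeping of its construction."""

    left: np.ndarray
    right: np.ndarray
    sample_rate_hz: float
    itd_us_requested: float = 0.0
    itd_us_realized: float = 0.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")

    @property
    def n_samples(self) -> int:
        return self.left.size


def quantize_itd(itd_us: float, sample_rate_hz: float) -> tuple[int, float]:
    """Quantize a requested ITD to the integer-sample grid of a device.

    Returns ``(shift, realized_itd_us)`` where ``shift`` is the
    nearest-integer sample delay (half-sample requests round away from
    zero) and ``realized_itd_us = shift / fs * 1e6``.  The realized ITD is
    always within half a sample period of the request.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    x = itd_us * sample_rate_hz / 1e6
    shift = int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
    realized = shift * 1e6 / sample_rate_hz
    return shift, realized


def _pulse_starts(spec: StimulusSpec) -> np.ndarray:
    idx = np.arange(spec.n_pulses)
    return np.round(idx * spec.sample_rate_hz / spec.pulse_rate_hz).astype(int)


def _place(base_starts: np.ndarray, template: np.ndarray, n: int, offset: int) -> np.ndarray:
    """Scatter a pulse template at shifted start samples into a length-n buffer."""
    out = np.zeros(n, dtype=float)
    for s in base_starts + offset:
        lo = max(s, 0)
        hi = min(s + template.size, n)
        if hi > lo:
            out[lo:hi] += template[lo - s : hi - s]
    return out


def _check_itd_vs_ipi(spec: StimulusSpec, shift: int) -> None:
    ipi_samples = spec.sample_rate_hz / spec.pulse_rate_hz
    if abs(shift) >= ipi_samples:
        raise ValueError(
            f"|ITD| of {abs(shift)} samples meets or exceeds the "
            f"inter-pulse interval ({ipi_samples:.1f} samples)"
        )


def _make_train(spec: StimulusSpec, template: np.ndarray) -> BinauralWaveform:
    if spec.n_pulses < 1 or spec.n_samples < 1:
        raise ValueError("spec yields zero pulses or zero samples")
    shift, realized = quantize_itd(spec.itd_us, spec.sample_rate_hz)
    _check_itd_vs_ipi(spec, shift)
    starts = _pulse_starts(spec)
    # Positive ITD (left arrival minus right arrival > 0): right channel delayed.
    left = _place(starts, template, spec.n_samples, 0)
    if shift == 0:
        right = left.copy()
    else:
        right = _place(starts, template, spec.n_samples, shift)
    return BinauralWaveform(left, right, spec.sample_rate_hz, spec.itd_us, realized)


def make_biphasic_pulse_train(spec: StimulusSpec) -> BinauralWaveform:
    """Build a binaural biphasic pulse train carrying the spec's ITD.

    Each pulse is +amplitude for ``phase_samples_pos`` samples, zero for
    ``phase_samples_gap`` samples, then -amplitude for
    ``phase_samples_neg`` samples, starting at each pulse epoch.  The
    lagging channel is delayed by the quantized integer-sample ITD shift.
    """
    template = np.concatenate(
        [
            np.full(spec.phase_samples_pos, spec.amplitude),
            np.zeros(spec.phase_samples_gap),
            np.full(spec.phase_samples_neg, -spec.amplitude),
        ]
    )
    if template.size == 0:
        raise ValueError("pulse template has zero length (all phase counts zero)")
    return _make_train(spec, template)


def make_acoustic_click_train(spec: StimulusSpec) -> BinauralWaveform:
    """Build a binaural click train: one unit-sample impulse per pulse epoch."""
    template = np.array([spec.amplitude])
    return _make_train(spec, template)


def compute_rms_ild(wave: BinauralWaveform) -> float:
    """Residual interaural level difference, dB; positive = left louder.

    ``20 * log10(rms(left) / rms(right))``.  An all-zero channel makes the
    ratio undefined and raises.
    """
    rms_l = math.sqrt(float(np.mean(wave.left**2)))
    rms_r = math.sqrt(float(np.mean(wave.right**2)))
    if rms_l == 0.0 or rms_r == 0.0:
        raise ValueError("RMS ILD undefined: a channel is all-zero")
    return 20.0 * math.log10(rms_l / rms_r)


def write_wav(wave: BinauralWaveform, path: str) -> None:
    """Write as 2-channel float32 WAV (acoustic stimuli)."""
    from scipy.io import wavfile

    data = np.stack([wave.left, wave.right], axis=1).astype(np.float32)
    wavfile.write(path, int(round(wave.sample_rate_hz)), data)


def write_stimulus_h5(wave: BinauralWaveform, path: str) -> None:
    """Write the waveform as HDF5 dataset ``/stimulus`` (2 x n) with ITD attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("stimulus", data=np.stack([wave.left, wave.right]))
        d.attrs["sample_rate_hz"] = wave.sample_rate_hz
        d.attrs["itd_us_requested"] = wave.itd_us_requested
        d.attrs["itd_us_realized"] = wave.itd_us_realized


def read_stimulus_h5(path: str) -> BinauralWaveform:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["stimulus"]
        arr = d[()]
        return BinauralWaveform(
            arr[0],
            arr[1],
            float(d.attrs["sample_rate_hz"]),
            float(d.attrs["itd_us_requested"]),
            float(d.attrs["itd_us_realized"]),
        )
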