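"""Readers and writers for trial-log CSVs and HDF5 recording containers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior_sim import TrialRecord
from .neuro_sim import RecordingBlock, TuningFunction

__all__ = [
    "TRIAL_CSV_COLUMNS",
    "read_trial_csv",
    "write_trial_csv",
    "read_recording",
    "write_recording",
]

TRIAL_CSV_COLUMNS = [
    "session_id",
    "trial_index",
    "itd_us",
    "response",
    "correct",
    "is_correction",
    "seed",
]


def write_trial_csv(records: list[TrialRecord], path: str) -> None:
    """Write a trial log as CSV (booleans as 0/1, response L/R)."""
    df = pd.DataFrame(
        {
            "session_id": [t.session_id for t in records],
            "trial_index": [t.trial_index for t in records],
            "itd_us": [t.itd_us for t in records],
            "response": [t.response for t in records],
            "correct": [int(t.correct) for t in records],
            "is_correction": [int(t.is_correction) for t in records],
            "seed": [t.rng_seed_ref for t in records],
        }
    )
    df.to_csv(path, index=False)


def read_trial_csv(path: str) -> list[TrialRecord]:
    """Read a trial log, validating schema; errors carry line numbers."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing column(s): {', '.join(missing)}")
    records: list[TrialRecord] = []
    last_idx: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if row.response not in ("L", "R"):
            raise ValueError(f"line {i}: response must be 'L' or 'R', got {row.response!r}")
        for flag in ("correct", "is_correction"):
            v = getattr(row, flag)
            if v not in (0, 1):
                raise ValueError(f"line {i}: {flag} must be 0 or 1, got {v!r}")
        sid = str(row.session_id)
        if sid in last_idx and int(row.trial_index) < last_idx[sid]:
            raise ValueError(f"line {i}: trial_index not sorted within session {sid}")
        last_idx[sid] = int(row.trial_index)
        records.append(
            TrialRecord(
                session_id=sid,
                trial_index=int(row.trial_index),
                itd_us=float(row.itd_us),
                response=row.response,
                correct=bool(row.correct),
                is_correction=bool(row.is_correction),
                rng_seed_ref=int(row.seed),
            )
        )
    return records


def write_recording(block: RecordingBlock, path: str) -> None:
    """Write a recording container: /trace, /events/{time_s,itd_us}, ground truth."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=block.trace)
        d.attrs["sample_rate_hz"] = block.sample_rate_hz
        ev = f.create_group("events")
        ev.create_dataset("time_s", data=block.event_times_s)
        ev.create_dataset("itd_us", data=block.itd_labels_us)
        if block.ground_truth_tuning is not None:
            gt = f.create_group("ground_truth")
            t = block.ground_truth_tuning
            for key in (
                "shape",
                "depth",
                "best_itd_us",
                "width_us",
                "base_rate_hz",
                "driven_rate_hz",
                "response",
            ):
                gt.attrs[key] = getattr(t, key)
            if block.ground_truth_spikes_s is not None:
                gt.create_dataset("spike_times_s", data=block.ground_truth_spikes_s)


def read_recording(path: str) -> RecordingBlock:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["trace"]
        if "sample_rate_hz" not in d.attrs:
            raise ValueError("recording missing 'sample_rate_hz' attribute on /trace")
        times = f["events/time_s"][()]
        labels = f["events/itd_us"][()]
        if times.size != labels.size:
            raise ValueError(
                f"/events length mismatch: {times.size} times vs {labels.size} labels"
            )
        tuning = None
        spikes = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            attrs = {k: gt.attrs[k] for k in gt.attrs}
            for k in ("shape", "response"):
                if k in attrs and isinstance(attrs[k], bytes):
                    attrs[k] = attrs[k].decode()
            tuning = TuningFunction(**attrs)
            if "spike_times_s" in gt:
                spikes = gt["spike_times_s"][()]
        return RecordingBlock(
            trace=d[()],
            sample_rate_hz=float(d.attrs["sample_rate_hz"]),
            event_times_s=times,
            itd_labels_us=labels,
            ground_truth_tuning=tuning,
            ground_truth_spikes_s=spikes,
        )
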