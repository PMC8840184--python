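"""Per-second breath binarization, the cumulative breathing curve, and
WHO-rule apnea-event detection.

A recording is reduced to one flag per second: 1 if the second's RMS
envelope exceeds ``threshold`` times the global envelope maximum, else 0.
The running sum of flags is the cumulative breathing curve; intervals where
its slope is zero are apneic, and maximal zero-runs of at least
``min_duration`` seconds (8 s by the WHO rule, inclusive) are reported as
apnea events with half-open [start, end) bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BreathRecording

DEFAULT_THRESHOLD = 0.05
WHO_MIN_APNEA_S = 8


@dataclass
class BinaryBreathSeries:
    """Per-second breathing indicator plus its cumulative curve."""

    flags: np.ndarray        # {0,1} per second
    cumulative: np.ndarray   # prefix sums of flags
    threshold_used: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=np.int64)
        self.cumulative = np.asarray(self.cumulative, dtype=np.int64)
        if self.flags.shape != self.cumulative.shape:
            raise ValueError("flags and cumulative must have equal length")
        if not np.all(np.isin(self.flags, (0, 1))):
            raise ValueError("flags must be 0/1")
        if not np.array_equal(self.cumulative, np.cumsum(self.flags)):
            raise ValueError("cumulative must be the prefix sum of flags")

    def __len__(self) -> int:
        return int(self.flags.size)


@dataclass(frozen=True)
class ApneaEvent:
    """Maximal no-breathing run of at least the minimum duration.

    Half-open in integer seconds: flags are all 0 over [start_s, end_s).
    """

    start_s: int
    end_s: int

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


ENVELOPE_WIN_S = 0.25


def rms_envelope(recording: BreathRecording, win_s: float = ENVELOPE_WIN_S) -> np.ndarray:
    """Sliding-window RMS envelope, one value per sample."""
    from scipy.ndimage import uniform_filter1d

    win = max(int(round(win_s * recording.rate)), 1)
    return np.sqrt(uniform_filter1d(recording.samples**2, size=win, mode="nearest"))


def rms_per_second(recording: BreathRecording, win_s: float = ENVELOPE_WIN_S) -> np.ndarray:
    """Per-second RMS envelope: the sliding-RMS maximum within each second.

    The sub-second window (0.25 s) makes the value insensitive to whether
    a breath burst straddles a second boundary.  The trailing partial
    second is dropped.
    """
    step = int(round(recording.rate))
    n_sec = recording.samples.size // step
    if n_sec < 1:
        raise ValueError("recording shorter than 1 s")
    env = rms_envelope(recording, win_s)
    return env[: n_sec * step].reshape(n_sec, step).max(axis=1)


def binarize_breath(
    recording: BreathRecording, threshold: float = DEFAULT_THRESHOLD
) -> BinaryBreathSeries:
    """Binarize breath presence per second.

    Second ``i`` is flagged 1 iff its RMS envelope exceeds
    ``threshold`` x the global envelope maximum over the recording.
    An all-silent recording yields all-zero flags.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    env = rms_per_second(recording)
    peak = float(env.max())
    flags = (env > threshold * peak).astype(np.int64) if peak > 0 else np.zeros_like(env, dtype=np.int64)
    return BinaryBreathSeries(
        flags=flags,
        cumulative=np.cumsum(flags),
        threshold_used=threshold,
        source_id=recording.subject_id,
    )


def cumulative_curve(series: BinaryBreathSeries) -> np.ndarray:
    """Plot-ready (second, cumulative count) pairs.

    The slope over any window equals breathing-seconds / window-length;
    zero slope means no breathing in the window.
    """
    seconds = np.arange(len(series))
    return np.column_stack([seconds, series.cumulative])


def detect_apnea(
    series: BinaryBreathSeries, min_duration: int = WHO_MIN_APNEA_S
) -> list[ApneaEvent]:
    """Maximal zero-flag runs of at least ``min_duration`` seconds.

    Events are ordered by start and never overlap; a run touching either
    edge of the series counts; a run of exactly ``min_duration`` is an
    event (the 8-s rule is inclusive).
    """
    if min_duration < 1:
        raise ValueError(f"min_duration must be >= 1, got {min_duration}")
    padded = np.concatenate([[1], series.flags, [1]])
    starts = np.flatnonzero(np.diff(padded) == -1)
    ends = np.flatnonzero(np.diff(padded) == 1)
    return [
        ApneaEvent(int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s >= min_duration
    ]


# --- external interfaces ---------------------------------------------------

def series_to_csv(series: BinaryBreathSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "second": np.arange(len(series)),
            "flag": series.flags,
            "cumulative": series.cumulative,
        }
    ).to_csv(path, index=False)


def series_from_csv(path: str | Path, threshold_used: float = float("nan"),
                    source_id: str = "") -> BinaryBreathSeries:
    df = pd.read_csv(path)
    return BinaryBreathSeries(
        flags=df["flag"].to_numpy(),
        cumulative=df["cumulative"].to_numpy(),
        threshold_used=threshold_used,
        source_id=source_id,
    )


def events_to_records(events: list[ApneaEvent]) -> list[dict]:
    return [
        {"start_s": e.start_s, "end_s": e.end_s, "duration_s": e.duration_s}
        for e in events
    ]


def events_to_csv(events: list[ApneaEvent], path: str | Path) -> None:
    pd.DataFrame(events_to_records(events),
                 columns=["start_s", "end_s", "duration_s"]).to_csv(path, index=False)


def events_to_json(events: list[ApneaEvent], path: str | Path) -> None:
    Path(path).write_text(json.dumps(events_to_records(events), indent=2) + "\n")
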