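"""Extraction of per-subject analysis units: fixed-length windows centred
on the loudest breath events.

Each subject contributes ``n_segments`` windows of ``window_s`` seconds
(5 x 15 s by default), centred on the highest peaks of a smoothed RMS
envelope subject to pairwise non-overlap, so segments are independent
observations.  Peaks whose window would cross a recording edge are shifted
inward; the call fails rather than return a partial set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import signal as sps

from .io import write_wav
from .types import BreathRecording, SasFlag

ENVELOPE_WIN_S = 0.2   # RMS smoothing window for peak picking
ENVELOPE_HOP_S = 0.05  # envelope sampling step


@dataclass
class BreathSegment:
    """A windowed slice of a recording centred on a loud breath event."""

    samples: np.ndarray
    rate: float
    center_s: float
    peak_pressure: float
    subject_id: str = ""
    sas_flag: SasFlag = SasFlag.UNKNOWN

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


def smoothed_envelope(recording: BreathRecording,
                      win_s: float = ENVELOPE_WIN_S,
                      hop_s: float = ENVELOPE_HOP_S) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed RMS envelope sampled every ``hop_s`` seconds.

    Returns (times, envelope).
    """
    win = max(int(round(win_s * recording.rate)), 1)
    hop = max(int(round(hop_s * recording.rate)), 1)
    power = ndimage.uniform_filter1d(recording.samples**2, size=win, mode="nearest")
    idx = np.arange(0, recording.samples.size, hop)
    # the moving average can round to tiny negatives on silent stretches
    return idx / recording.rate, np.sqrt(np.maximum(power[idx], 0.0))


def extract_segments(
    recording: BreathRecording,
    n_segments: int = 5,
    window_s: float = 15.0,
) -> list[BreathSegment]:
    """Cut the ``n_segments`` loudest non-overlapping windows.

    Greedy selection by descending envelope peak with a ``window_s``
    exclusion zone; returns exactly ``n_segments`` segments in descending
    ``peak_pressure`` order, or raises.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    dur = recording.duration_s
    needed = n_segments * window_s
    if dur < needed:
        raise ValueError(
            f"recording of {dur:.1f} s too short for {n_segments} "
            f"non-overlapping {window_s:.0f}-s windows; need >= {needed:.0f} s"
        )
    times, env = smoothed_envelope(recording)
    peak_idx, _ = sps.find_peaks(env)
    peak_idx = peak_idx[env[peak_idx] > 0]
    order = peak_idx[np.argsort(env[peak_idx], kind="stable")[::-1]]

    half = window_s / 2.0
    n_win = int(round(window_s * recording.rate))
    chosen: list[tuple[float, float, float]] = []  # (adj_center, start, peak)
    for i in order:
        c = float(np.clip(times[i], half, dur - half))
        start, end = c - half, c + half
        if any(start < e0 + window_s and e0 < end for _, e0, _ in chosen):
            continue
        chosen.append((c, start, float(env[i])))
        if len(chosen) == n_segments:
            break
    if len(chosen) < n_segments:
        raise ValueError(
            f"only {len(chosen)} resolvable non-overlapping breath peaks found; "
            f"{n_segments} requested"
        )

    out = []
    for c, start, peak in chosen:
        i0 = int(round(start * recording.rate))
        i0 = min(max(i0, 0), recording.samples.size - n_win)
        out.append(
            BreathSegment(
                samples=recording.samples[i0 : i0 + n_win].copy(),
                rate=recording.rate,
                center_s=c,
                peak_pressure=peak,
                subject_id=recording.subject_id,
                sas_flag=recording.sas_flag,
            )
        )
    return out


def write_segments(
    segments: list[BreathSegment], outdir: str | Path, prefix: str = "segment"
) -> pd.DataFrame:
    """Write each segment as WAV plus a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments):
        name = f"{prefix}_{seg.subject_id}_{i}.wav"
        write_wav(outdir / name, _as_recording(seg))
        rows.append(
            {
                "file": name,
                "subject_id": seg.subject_id,
                "segment_index": i,
                "center_s": seg.center_s,
                "peak_pressure": seg.peak_pressure,
                "sas_flag": seg.sas_flag.value,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def _as_recording(seg: BreathSegment) -> BreathRecording:
    return BreathRecording(
        samples=np.clip(seg.samples, -1.0, 1.0),
        rate=seg.rate,
        subject_id=seg.subject_id,
        sas_flag=seg.sas_flag,
    )
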