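"""File I/O: 16-bit PCM WAV and the standing-test CSV layout.

The standing-test CSV has columns ``time_s, sbp_mmHg, hr_bpm, phase`` with
phase in {supine, standing}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import BreathRecording, OrthostaticRecord, SasFlag


def write_wav(path: str | Path, recording: BreathRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    pcm = np.clip(recording.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(recording.rate)), (pcm * 32767.0).astype(np.int16))


def read_wav(path: str | Path, subject_id: str | None = None,
             sas_flag: SasFlag = SasFlag.UNKNOWN) -> BreathRecording:
    """Read a mono WAV into a BreathRecording (amplitude scaled to [-1, 1])."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
        peak = np.max(np.abs(data))
        if peak > 1.0:
            data = data / peak
    sid = subject_id if subject_id is not None else Path(path).stem
    return BreathRecording(samples=data, rate=float(rate), subject_id=sid, sas_flag=sas_flag)


def write_orthostatic_csv(path: str | Path, record: OrthostaticRecord) -> None:
    frames = []
    for phase, arr in (("supine", record.supine), ("standing", record.standing)):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": np.arange(arr.shape[0]) * record.dt_s,
                    "sbp_mmHg": arr[:, 0],
                    "hr_bpm": arr[:, 1],
                    "phase": phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_orthostatic_csv(path: str | Path, subject_id: str | None = None) -> OrthostaticRecord:
    df = pd.read_csv(path)
    required = {"time_s", "sbp_mmHg", "hr_bpm", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"standing-test CSV missing columns: {sorted(missing)}")
    phases = {}
    dt = 3.0
    for phase in ("supine", "standing"):
        sub = df[df["phase"] == phase].sort_values("time_s")
        if len(sub) < 2:
            raise ValueError(f"phase {phase!r} needs at least 2 samples")
        dt = float(np.median(np.diff(sub["time_s"].to_numpy())))
        phases[phase] = sub[["sbp_mmHg", "hr_bpm"]].to_numpy()
    sid = subject_id if subject_id is not None else Path(path).stem
    return OrthostaticRecord(supine=phases["supine"], standing=phases["standing"],
                             subject_id=sid, dt_s=dt)


def write_json_sidecar(path: str | Path, params: dict) -> None:
    """Echo generator/analysis parameters next to a data file."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True, default=str) + "\n")
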