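"""Shared domain containers.

The two raw-data containers used across the toolkit: a single-channel
breath-sound recording (amplitude in [-1, 1]) and a two-phase active
standing-test record of systolic blood pressure and heart rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np


class SasFlag(str, enum.Enum):
    """Ground-truth label attached to a recording or segment."""

    SAS = "SAS"
    NON_SAS = "NON_SAS"
    UNKNOWN = "UNKNOWN"


@dataclass
class BreathRecording:
    """Sampled sleep breath-sound audio with subject metadata.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence, dimensionless, all values in [-1, 1].
    rate : float
        Sampling rate in Hz, > 0.
    subject_id : str
        Opaque subject identifier.
    sas_flag : SasFlag
        Optional ground-truth label.
    meta : dict
        Free-form provenance (e.g. the synthetic generator's burst
        schedule); never consumed by analysis code.
    """

    samples: np.ndarray
    rate: float
    subject_id: str = ""
    sas_flag: SasFlag = SasFlag.UNKNOWN
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("recording must be a non-empty 1-D sample array")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")
        peak = float(np.max(np.abs(self.samples))) if self.samples.size else 0.0
        if peak > 1.0 + 1e-9:
            raise ValueError(f"samples must lie in [-1, 1]; max |x| = {peak:.4g}")
        self.sas_flag = SasFlag(self.sas_flag)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class OrthostaticRecord:
    """Active standing-test record: supine and standing (SBP, HR) series.

    Each phase is an (n, 2) array with columns (systolic blood pressure
    in mmHg, heart rate in bpm), sampled every ``dt_s`` seconds
    (3 s by default, 60 samples = 3 min per phase).
    """

    supine: np.ndarray
    standing: np.ndarray
    subject_id: str = ""
    dt_s: float = 3.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("supine", "standing"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} phase must be an (n, 2) array of (SBP, HR)")
            if arr.shape[0] < 2:
                raise ValueError(f"{name} phase needs at least 2 samples")
            if not np.all(arr > 0):
                raise ValueError(f"{name} phase BP and HR must be strictly positive")
            setattr(self, name, arr)
        if not self.dt_s > 0:
            raise ValueError("dt_s must be > 0")
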