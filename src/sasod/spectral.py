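"""Windowed FFT with overlap processing and inverse-transform round trip.

Frames of ``frame_length`` samples are cut every ``hop`` samples,
multiplied by a periodic analysis window and Fourier-transformed.  The
amplitude-correction factor ``frame_length / sum(window)`` is stored with
the frames so corrected spectra can be reported.

Reconstruction is weighted overlap-add: each inverse-transformed frame is
re-weighted by the window and the sum is divided by the per-sample sum of
squared windows.  Wherever that denominator is positive the round trip is
exact up to floating point; where it vanishes (e.g. Hann with no overlap,
whose window touches zero at frame joins) the reconstruction is zeroed and
the deviation from the analysed signal appears exactly there — the
window-discontinuity effect the round-trip utility exists to demonstrate.

Constant-overlap-add (COLA) diagnostics are provided for both the
amplitude sum (sum of shifted windows; constant for periodic Hann at 50 %
and 75 % overlap) and the power sum (sum of shifted squared windows;
constant for periodic Hann at 75 % but not 50 %).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window


class WindowType(str, enum.Enum):
    RECTANGULAR = "RECTANGULAR"
    HANN = "HANN"
    HAMMING = "HAMMING"


_SCIPY_NAMES = {
    WindowType.RECTANGULAR: "boxcar",
    WindowType.HANN: "hann",
    WindowType.HAMMING: "hamming",
}


def window_values(window: WindowType | str, frame_length: int) -> np.ndarray:
    """Periodic (DFT-even) window samples."""
    return get_window(_SCIPY_NAMES[WindowType(window)], frame_length, fftbins=True)


@dataclass
class StftFrames:
    """Windowed FFT frames plus everything needed to invert them."""

    frames: np.ndarray          # (n_frames, frame_length) complex spectra
    frame_length: int
    hop: int
    window: WindowType
    correction: float           # amplitude correction frame_length / sum(window)
    source: np.ndarray = field(repr=False, default=None)  # analysed signal

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def covered(self) -> int:
        """Samples covered by at least one frame."""
        return (self.n_frames - 1) * self.hop + self.frame_length

    def amplitude_spectra(self) -> np.ndarray:
        """|frames| with the window's amplitude correction applied."""
        return np.abs(self.frames) * (self.correction / self.frame_length)


def stft(
    signal: np.ndarray,
    frame_length: int = 1024,
    hop: int = 512,
    window: WindowType | str = WindowType.HANN,
) -> StftFrames:
    """Windowed FFT: frame i = FFT(window * signal[i*hop : i*hop+frame_length])."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if hop <= 0:
        raise ValueError(f"hop must be > 0, got {hop}")
    if hop > frame_length:
        raise ValueError(f"hop ({hop}) must not exceed frame_length ({frame_length})")
    if frame_length > x.size:
        raise ValueError(
            f"frame_length ({frame_length}) exceeds signal length ({x.size})"
        )
    window = WindowType(window)
    w = window_values(window, frame_length)
    n_frames = (x.size - frame_length) // hop + 1
    starts = np.arange(n_frames) * hop
    slices = x[starts[:, None] + np.arange(frame_length)]
    frames = np.fft.fft(slices * w, axis=1)
    wsum = float(w.sum())
    correction = frame_length / wsum if wsum > 0 else float("inf")
    return StftFrames(
        frames=frames,
        frame_length=frame_length,
        hop=hop,
        window=window,
        correction=correction,
        source=x,
    )


def cola_deviation(
    window: WindowType | str, frame_length: int, hop: int,
    n_frames: int = 8, power: bool = False,
) -> float:
    """Max relative deviation of the shifted-window sum from constancy.

    ``power=False`` sums shifted windows (amplitude COLA); ``power=True``
    sums shifted squared windows.  Measured over the fully overlapped
    interior of ``n_frames`` frames; 0 means the COLA condition holds.
    """
    w = window_values(window, frame_length)
    if power:
        w = w**2
    total = np.zeros((n_frames - 1) * hop + frame_length)
    for i in range(n_frames):
        total[i * hop : i * hop + frame_length] += w
    interior = total[frame_length : total.size - frame_length]
    if interior.size == 0:
        raise ValueError("too few frames to expose an interior region")
    mean = interior.mean()
    if mean == 0:
        return float("inf")
    return float(np.max(np.abs(interior - mean)) / mean)


@dataclass
class RoundTrip:
    """Result of an overlap-add inverse-transform verification."""

    signal: np.ndarray          # reconstruction, length = covered samples
    max_abs_error: float        # over the fully overlapped interior
    error: np.ndarray           # |reconstruction - original| over covered range
    interior: tuple[int, int]   # [lo, hi) index range the error is measured on
    cola_ok: bool               # False if the OLA denominator vanishes inside


def istft_roundtrip(frames: StftFrames) -> RoundTrip:
    """Overlap-add reconstruction with window-power normalization.

    Compares the reconstruction against the analysed signal over the
    fully overlapped interior (edges lack full window coverage by
    construction).  Configurations whose per-sample window-power sum
    vanishes somewhere inside the covered range are reconstructed anyway
    and flagged ``cola_ok=False``; their error is the reported
    discontinuity effect.
    """
    L, hop = frames.frame_length, frames.hop
    w = window_values(frames.window, L)
    n = frames.covered
    num = np.zeros(n)
    den = np.zeros(n)
    time_frames = np.real(np.fft.ifft(frames.frames, axis=1))
    for i in range(frames.n_frames):
        sl = slice(i * hop, i * hop + L)
        num[sl] += w * time_frames[i]
        den[sl] += w**2
    ok = den > 1e-12 * den.max()
    recon = np.zeros(n)
    recon[ok] = num[ok] / den[ok]
    lo, hi = min(L, n), max(n - L, 0)
    if hi <= lo:
        lo, hi = 0, n
    err = np.abs(recon - frames.source[:n])
    return RoundTrip(
        signal=recon,
        max_abs_error=float(err[lo:hi].max()) if hi > lo else float("nan"),
        error=err,
        interior=(lo, hi),
        cola_ok=bool(np.all(ok[lo:hi])),
    )
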