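"""Synthetic study-condition generators.

Real sleep breath-sound recordings and standing-test measurements are not
distributable, so the toolkit ships seeded generators that emulate the
statistical structure the analyses rely on:

* breath audio — quasi-periodic breathing bursts for healthy sleepers, and
  SAS-like breathing with silent apneic gaps of at least 8 s, loud
  resumption bursts (>= 2x the median burst amplitude) and irregular
  inter-breath intervals (coefficient of variation >= 0.3);
* standing-test series — bivariate (systolic BP, heart rate) Gaussian
  series with a controllable per-phase coupling correlation, centred on
  physiologic marginals (SBP 110 +/- 10 mmHg, HR 70 +/- 8 bpm);
* feature-space cohorts — labeled multi-mode Gaussian feature vectors used
  to exercise the clustering screen without rendering audio.

All generators are bit-reproducible for a given seed.
"""

from __future__ import annotations

import enum

import numpy as np
from scipy import signal as sps

from .types import BreathRecording, OrthostaticRecord, SasFlag

__all__ = [
    "BreathProfile",
    "gen_breath_recording",
    "gen_breath_cohort",
    "gen_orthostatic_record",
    "gen_feature_cohort",
]


class BreathProfile(str, enum.Enum):
    NORMAL = "NORMAL"
    SAS = "SAS"


# Nominal burst morphology: amplitude-modulated band-limited noise under a
# Hann envelope.  Only loudness and interval statistics matter downstream.
_BASE_PERIOD_S = 4.0
_BURST_WIDTH_S = 1.0
_BASE_AMP = 0.3
_HANN_RMS = 0.612  # RMS of a Hann envelope, sqrt(3/8)


def _burst_carrier(
    rng: np.random.Generator, n: int, rate: float, broadband: bool = False
) -> np.ndarray:
    """Band-limited noise of unit RMS.

    Regular breaths are narrowband around ~500 Hz; post-apneic resumption
    gasps (``broadband=True``) are explosive and spectrally wide.
    """
    center = min(500.0, rate / 4.0)
    if broadband:
        lo, hi = 100.0, min(3.4 * center, 0.45 * rate)
        lo = min(lo, hi / 4.0)
    else:
        half = 0.2 * center
        lo = max(center - half, 1.0)
        hi = min(center + half, 0.45 * rate)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def gen_breath_recording(
    profile: BreathProfile | str,
    duration_s: float = 120.0,
    rate: float = 8000.0,
    seed: int = 0,
    snr_db: float = 20.0,
    subject_id: str = "",
) -> BreathRecording:
    """Generate a seeded synthetic sleep breath-sound recording.

    NORMAL recordings breathe every ~4 s with < 10 % period jitter and
    contain no silent gap of 8 s or longer.  SAS recordings contain at
    least one silent gap >= 8 s per 2 minutes, a loud resumption burst
    after every gap, and irregular inter-breath intervals.

    Parameters
    ----------
    profile : {"NORMAL", "SAS"}
    duration_s : float
        Recording length; must be at least 60 s.
    rate : float
        Sampling rate in Hz; must be at least 1000 Hz.
    seed : int
        Seed for all randomness in this call.
    snr_db : float
        Ratio of nominal burst RMS to background-noise RMS, in dB.

    Returns
    -------
    BreathRecording
        ``meta`` carries the burst schedule (``bursts`` = list of
        (center_s, amplitude, kind) with kind in {"normal", "resumption"})
        and the silent intervals
        (``silent_gaps`` = list of (start_s, end_s)) for verification.
    """
    profile = BreathProfile(profile)
    if duration_s < 60.0:
        raise ValueError(
            f"duration {duration_s} s too short to place one full breath "
            "cycle reliably; need >= 60 s"
        )
    if rate < 1000.0:
        raise ValueError(f"rate must be >= 1000 Hz, got {rate}")
    rng = np.random.default_rng(seed)

    # --- schedule burst centers, amplitudes and kinds ------------------
    bursts: list[tuple[float, float, str]] = []
    t = 1.0 + rng.uniform(0.0, 1.0)
    last_gap_end = 0.0
    while t < duration_s - _BURST_WIDTH_S / 2:
        if profile is BreathProfile.NORMAL:
            amp = _BASE_AMP * (1.0 + rng.uniform(-0.1, 0.1))
            bursts.append((t, amp, "normal"))
            t += _BASE_PERIOD_S * (1.0 + rng.uniform(-0.08, 0.08))
        else:
            force_gap = (t - last_gap_end) > 90.0
            random_gap = rng.uniform() < 0.10
            if force_gap or random_gap:
                silent = rng.uniform(9.0, 14.0)
                t += silent + _BURST_WIDTH_S  # center-to-center step
                last_gap_end = t
                amp = _BASE_AMP * rng.uniform(2.5, 3.5)  # loud resumption
                kind = "resumption"
            else:
                # gamma intervals, CV = 0.5 -> irregular breathing
                t += rng.gamma(4.0, _BASE_PERIOD_S / 4.0)
                amp = _BASE_AMP * (1.0 + rng.uniform(-0.2, 0.2))
                kind = "normal"
            if t < duration_s - _BURST_WIDTH_S / 2:
                bursts.append((t, amp, kind))
    if not bursts:
        raise ValueError("duration too short to place one full breath cycle")

    # --- render --------------------------------------------------------
    n = int(round(duration_s * rate))
    x = np.zeros(n)
    w = int(round(_BURST_WIDTH_S * rate))
    env = np.hanning(w)
    for center, amp, kind in bursts:
        i0 = int(round(center * rate)) - w // 2
        i1 = i0 + w
        lo, hi = max(i0, 0), min(i1, n)
        carrier = _burst_carrier(rng, w, rate, broadband=(kind == "resumption"))
        x[lo:hi] += amp * (env * carrier)[lo - i0 : hi - i0]

    noise_rms = (_BASE_AMP * _HANN_RMS) / 10 ** (snr_db / 20.0)
    x += noise_rms * rng.standard_normal(n)
    np.clip(x, -1.0, 1.0, out=x)

    # silent gaps: intervals between consecutive burst envelopes
    edges = sorted(bursts)
    gaps = []
    prev_end = 0.0
    for center, _, _ in edges:
        start = center - _BURST_WIDTH_S / 2
        if start - prev_end >= 1.0:
            gaps.append((prev_end, start))
        prev_end = center + _BURST_WIDTH_S / 2
    if duration_s - prev_end >= 1.0:
        gaps.append((prev_end, duration_s))

    flag = SasFlag.SAS if profile is BreathProfile.SAS else SasFlag.NON_SAS
    return BreathRecording(
        samples=x,
        rate=rate,
        subject_id=subject_id,
        sas_flag=flag,
        meta={
            "profile": profile.value,
            "seed": seed,
            "snr_db": snr_db,
            "bursts": bursts,
            "silent_gaps": gaps,
        },
    )


def gen_breath_cohort(
    n_sas: int = 37,
    n_non_sas: int = 5,
    duration_s: float = 180.0,
    rate: float = 8000.0,
    seed: int = 0,
) -> list[BreathRecording]:
    """A labeled cohort of recordings (default 37 SAS + 5 healthy = 42)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sas + n_non_sas)]
    out = []
    for i in range(n_sas + n_non_sas):
        profile = BreathProfile.SAS if i < n_sas else BreathProfile.NORMAL
        out.append(
            gen_breath_recording(
                profile,
                duration_s=duration_s,
                rate=rate,
                seed=child_seeds[i],
                subject_id=f"subj{i:03d}",
            )
        )
    return out


def _coupled_phase(
    rng: np.random.Generator,
    r: float,
    n: int,
    bp_mean: float,
    bp_sd: float,
    hr_mean: float,
    hr_sd: float,
    exact: bool,
) -> np.ndarray:
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    if exact:
        # orthogonalize and standardize so the sample correlation is exact
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)
        z2 /= z2.std()
    y = r * z1 + np.sqrt(1.0 - r**2) * z2
    bp = bp_mean + bp_sd * z1
    hr = hr_mean + hr_sd * y
    return np.column_stack([bp, hr])


def gen_orthostatic_record(
    r_supine: float,
    r_standing: float,
    n_per_phase: int = 60,
    seed: int = 0,
    bp_mean: float = 110.0,
    bp_sd: float = 10.0,
    hr_mean: float = 70.0,
    hr_sd: float = 8.0,
    exact: bool = False,
    subject_id: str = "",
) -> OrthostaticRecord:
    """Generate a standing-test record with requested per-phase BP-HR coupling.

    Uses a Cholesky-style linear mixing of independent Gaussians, so the
    realized sample correlation fluctuates around the request (``exact=True``
    orthogonalizes the residual for an exact sample correlation).  Default
    60 samples/phase = 3 min at 3-s intervals.
    """
    for name, r in (("r_supine", r_supine), ("r_standing", r_standing)):
        if not abs(r) < 1.0:
            raise ValueError(f"{name} must satisfy |r| < 1 strictly, got {r}")
    if n_per_phase < 10:
        raise ValueError(f"n_per_phase must be >= 10, got {n_per_phase}")
    rng = np.random.default_rng(seed)
    supine = _coupled_phase(rng, r_supine, n_per_phase, bp_mean, bp_sd, hr_mean, hr_sd, exact)
    standing = _coupled_phase(rng, r_standing, n_per_phase, bp_mean, bp_sd, hr_mean, hr_sd, exact)
    return OrthostaticRecord(
        supine=supine,
        standing=standing,
        subject_id=subject_id,
        dt_s=3.0,
        meta={"r_supine": r_supine, "r_standing": r_standing, "seed": seed},
    )


def gen_feature_cohort(
    n_sas: int = 37,
    n_non_sas: int = 5,
    n_segments: int = 5,
    n_features: int = 15,
    seed: int = 0,
    separation: float = 8.0,
    spread: float = 1.0,
    n_sas_modes: int = 3,
    n_non_modes: int = 2,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Labeled feature-space cohort: class-separated multi-mode Gaussians.

    Emulates the clustering screen's working assumption that SAS breath
    segments occupy acoustic-feature modes disjoint from healthy ones
    (SAS segments spread over ``n_sas_modes`` modes, healthy over
    ``n_non_modes``), without rendering audio.  Mode centres sit on
    mutually orthogonal axes at ``separation`` from the origin, so every
    pair of modes is equidistant and unambiguously separated relative to
    the within-mode ``spread``.

    Returns
    -------
    X : (n_subjects * n_segments, n_features) array
    subject_ids : list of str, one per row
    is_sas : boolean array, one per row
    """
    n_modes = n_sas_modes + n_non_modes
    if n_modes > n_features:
        raise ValueError("need n_features >= number of modes for orthogonal centres")
    rng = np.random.default_rng(seed)
    modes = separation * np.eye(n_modes, n_features)
    rows, ids, flags = [], [], []
    for s in range(n_sas + n_non_sas):
        sas = s < n_sas
        sid = f"subj{s:03d}"
        for _ in range(n_segments):
            if sas:
                m = modes[rng.integers(0, n_sas_modes)]
            else:
                m = modes[n_sas_modes + rng.integers(0, n_non_modes)]
            rows.append(m + spread * rng.standard_normal(n_features))
            ids.append(sid)
            flags.append(sas)
    return np.asarray(rows), ids, np.asarray(flags, dtype=bool)
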