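# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the synthetic study conditions it is tested under, and
the design decisions taken where the underlying method left choices open.

## Breath binarization and apnea events

A recording is reduced to one flag per second: 1 ("breathing") when the
second's RMS envelope exceeds `threshold` × the global envelope maximum,
else 0. The envelope is a 0.25-s sliding RMS; each second is scored by
the envelope maximum within it. The sub-second window matters: a whole-
second RMS halves when the loudest breath burst straddles a second
boundary, which makes the relative threshold alignment-sensitive, while
the sliding maximum does not. The default threshold is 0.05 (5 % of the
loudest event); the underlying method does not fix a value, so it is a
parameter.

The cumulative curve is the running sum of flags; an interval of zero
slope is apneic. Apnea events are the maximal zero-flag runs of at least
`min_duration` seconds — 8 s by default, inclusive (a run of exactly 8 s
is an event), per the WHO apnea definition. Events are half-open
`[start, end)` in integer seconds, and a run touching either edge of the
recording counts. With these conventions, breathing seconds plus seconds
covered by maximal zero-runs partition the series exactly.

## Segment extraction

Each subject contributes `n_segments` (default 5) windows of `window_s`
(default 15 s), centred on the highest peaks of a smoothed RMS envelope
(0.2-s window, 0.05-s hop). Selection is greedy by descending peak with a
full-window exclusion zone, so returned windows never overlap and the
segments can be treated as independent observations. A peak whose window
would cross a recording edge is shifted inward rather than discarded. The
call either returns exactly `n_segments` segments or raises — never a
silent partial result. Non-overlap of 15-s windows means a recording must
be at least `n_segments × window_s` long, and in practice somewhat longer
when apneic gaps consume span; the default synthetic cohort uses 180-s
recordings, far shorter than real overnight audio but ample for five
windows.

## Continuous wavelet transform

`W(α, β)` is approximated by a Riemann sum on the signal's sample grid,
with the signal taken as zero outside its support. Two paths exist:
DIRECT evaluates the sum per (scale, time) pair and is the quadratic-cost
oracle for short signals; CONVOLUTION computes each scale row by FFT
cross-correlation with the wavelet truncated where its envelope falls
below 1e-8 of its peak. The two agree to better than 1e-6 relative
(max-normalized) error on 2-s signals.

Conventions, fixed deliberately:

* the carrier is `e^{i2πt}` — a unit-frequency modulation, so a wavelet
  dilated by α responds at 1/α Hz;
* the Gabor prefactor is `1/(π^{1/4} δ)` (amplitude-style), not the
  L²-unit `1/(π^{1/4} √δ)` of textbook treatments; the DMS prefactor
  `1/(π^{1/4} δ_D (A+B))` likewise, which makes DMS collapse exactly to
  Gabor at A = B = 1, δ_D = δ;
* `ψ̄` in the transform is the complex conjugate;
* the default scale grid is logarithmic in 1/α, user-overridable.

Reference scalogram parameters: δ = 1.0 (Gabor), A = 1.0, B = 0.5,
δ_D = 0.5 (DMS). At these values the DMS mixture has Gaussian widths
δ_D/√A = 0.5 and δ_D/√B ≈ 0.71 — shorter in time and broader in
frequency than the Gabor reference. That bandwidth difference is what
makes DMS emphasize broadband post-apneic resumption gasps relative to
narrowband regular breathing, the qualitative contrast the test suite
checks on synthetic segments.

## Clustering screen

Features default to `RMS_ENVELOPE_1S`: per-second RMS over the 15-s
segment (15 values), z-normalized within the segment; a near-constant
vector (relative spread below 1e-9) maps to the zero vector instead of
amplifying rounding noise, and an all-zero segment is rejected. A
`BAND_ENERGY` alternative (log octave-band energies) is provided; the
scheme is recorded in run metadata because the underlying method does not
pin down a representation.

k-means is Lloyd's algorithm with Euclidean distance, written in full:
k-means++ seeding, best of `n_init = 10` restarts by inertia, iteration
cap 300, convergence on unchanged assignments, empty clusters reseeded
from the farthest point. Seeding draws over a lexicographically sorted
view of the data, so a fitted model is invariant under permutation of the
input rows at fixed seed. The objective recorded after every assignment
step is non-increasing — asserted in tests. The mean silhouette
coefficient is likewise computed from first principles (O(n²) pairwise
distances; singleton clusters contribute 0) and cross-checked against an
independent implementation in the tests.

Model selection fits k = 4..7 and keeps the maximum-silhouette model,
breaking ties toward smaller k. The decision rule labels a cluster
SAS-indicative when the majority of its member segments carry the SAS
flag, and calls a subject SAS when at least one of their segments falls
in an indicative cluster. The source description of which clusters
indicate SAS is ambiguous; this majority-composition / any-segment rule
is this package's generalization and is recorded in output rather than
asserted as canonical.

## Positioning map

Phase correlations are Pearson product-moment correlations of
(systolic BP, HR) pairs; series at other sampling intervals are linearly
resampled to 3-s spacing first. "Fisher's correlation coefficient" is
read as the Pearson r, with the 0.59 ± 0.11 band applied on the r scale
as the map draws it; `fisher_z=True` applies the band on the
z = atanh(r) scale (half-width in z units) as a sensitivity analysis.

The distance to the reference square generalizes the perpendicular
distance: `d = hypot(max(|x−c|−h, 0), max(|y−c|−h, 0))`, zero on the
closed square, the axis gap for axis-aligned exterior points, and the
corner distance elsewhere. The square is a population reference, not a
validated boundary, so the calls are labelled
CONSISTENT_WITH_HEALTHY_COUPLING / OD_PATTERN rather than healthy/ill.

## Windowed FFT round trip

Frames are `FFT(window ⊙ slice)` every `hop` samples with periodic
(DFT-even) windows; the stored amplitude correction is
`frame_length / Σ window`. Reconstruction is weighted overlap-add
normalized by the per-sample sum of squared windows, which is exact
wherever that sum is positive; where it vanishes (periodic Hann with no
overlap has a zero at every frame join) the output is zeroed and the
deviation appears exactly at the joins — the discontinuity effect the
utility demonstrates. Round-trip error is measured over the fully
overlapped interior only, because edges lack full window coverage by
construction.

One point worth stating precisely: periodic Hann satisfies the
constant-overlap-add condition on the *amplitude* sum at both 50 % and
75 % overlap, but on the *power* sum only at 75 % (at 50 % the shifted
squared-window sum oscillates as 0.75 + 0.25·cos(4πn/L)). The
`cola_deviation` diagnostic exposes both modes; exactness of the round
trip does not depend on either, only on the positivity of the
normalizer.

## Synthetic study conditions

The generators define the conditions everything is tested under.

Breath audio: breaths are 1-s Hann-enveloped bursts of band-limited
noise. NORMAL profiles breathe every 4 s with < 10 % period jitter at
amplitude 0.3 ± 10 %. SAS profiles draw inter-breath intervals from a
gamma distribution (CV 0.5), insert a silent gap of 9–14 s at least every
~90 s (≥ 1 per 2 min) plus occasional random gaps, and follow every gap
with a resumption burst at 2.5–3.5× the base amplitude. Regular breaths
are narrowband (~400–600 Hz); resumption gasps are broadband
(100 Hz–1.7 kHz), reflecting their explosive character — this spectral
distinction, not just loudness, is what a broader-bandwidth wavelet keys
on. Background Gaussian noise sits at 20 dB below nominal burst RMS by
default. Defaults 8000 Hz / 16-bit WAV; the source recordings' format is
unknown, so these are ordinary IC-recorder values. What the generator
does **not** model: snoring harmonics, body movement, bed noise, room
reverberation, hypopnea (partial obstruction), or hours-long recordings;
passing tests show the analysis chain is correct under the stated
structure, not that the screen is clinically validated.

Standing-test series: (BP, HR) are a linear (Cholesky-style) mixing of
independent Gaussians with the requested correlation, BP 110 ± 10 mmHg
and HR 70 ± 8 bpm marginals, 60 samples per phase at 3-s spacing. The
sample correlation fluctuates around the request (mean absolute error
< 0.15 at n = 60, checked over 200 replicates); `exact=True`
orthogonalizes residuals for an exact sample correlation. No diastolic
pressure, trends, or autocorrelation are modelled.

Feature-space cohorts: for clustering tests, labeled feature vectors are
drawn around mode centres placed on mutually orthogonal axes (3 SAS
modes, 2 healthy modes; separation 8, within-mode spread 1 in 15
dimensions), making every mode pair equidistant and cleanly separated —
the idealized regime in which the screen's 100 % subject-level recovery
is a meaningful correctness check of the rule, not a clinical claim.

## Known limitations

* The clustering screen requires a labeled reference cohort and equal
  segment counts per subject; missing-segment handling is out of scope.
* The apnea detector scores breath absence only — no hypopnea, AHI, or
  oxygen-desaturation integration.
* The OD square is a screening reference; no OD subtype classification.
* The inverse CWT is not implemented; scalograms are for visualization
  and comparison only.
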