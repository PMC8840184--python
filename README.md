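# sasod

Diagnostic-support signal processing for two conditions that are routinely
under-diagnosed because the gold-standard work-up is burdensome:

* **Sleep apnea syndrome (SAS).** Instead of an overnight polysomnogram,
  the screen works from a plain single-channel recording of sleep breath
  sounds. Breath presence is binarized second by second, the cumulative
  breathing curve makes apneic intervals visible as zero-slope stretches,
  and maximal no-breathing runs of ≥ 8 s (the WHO apnea rule) are reported
  as events. For cohort-level screening, the five loudest 15-s breath
  segments per subject are clustered (k-means, k = 4..7, silhouette
  selection) and a subject is flagged when any of their segments lands in
  a cluster dominated by known-SAS segments.
* **Orthostatic dysregulation (OD).** In an active standing test
  (3 min supine, 3 min standing, samples every 3 s) healthy autonomic
  regulation couples systolic blood pressure and heart rate with a Pearson
  correlation of about 0.59 ± 0.11. Each subject becomes a point
  (r_supine, r_standing) on a positioning map; points outside the healthy
  reference square [0.59 − 0.11, 0.59 + 0.11]² show an OD-consistent
  decoupling pattern, quantified by the minimal distance to the square.

For visualisation the package implements the continuous wavelet transform

```
W(α, β) = ∫ α^(−1/2) · conj(ψ((t − β)/α)) · f(t) dt ,   1/α = frequency, β = time
```

with two mother wavelets: the classical Gabor wavelet
`ψ_G(t) = π^(−1/4) δ^(−1) exp(−t²/2δ²) e^{i2πt}` and a two-Gaussian blend
designed for apneic breath sounds ("DMS"),

```
ψ_D(t) = π^(−1/4) / (δ_D (A + B)) · [exp(−A t²/2δ_D²) + exp(−B t²/2δ_D²)] · e^{i2πt},
```

which reduces to Gabor for A = B = 1, δ_D = δ. A windowed-FFT
overlap-add round-trip utility (Hann/Hamming/rectangular, COLA
diagnostics) verifies window-correction effects on test signals.

Real study data are not distributable, so `sasod.synthetic` generates
seeded breath recordings (quasi-periodic healthy breathing vs. SAS-like
breathing with ≥ 8-s silent gaps and loud broadband resumption gasps) and
coupled BP/HR standing-test series; every analysis is exercised end to end
on these.

## Worked example

```python
import sasod

rec = sasod.gen_breath_recording("SAS", duration_s=120, rate=8000, seed=1)
series = sasod.binarize_breath(rec)           # one 0/1 flag per second
events = sasod.detect_apnea(series)           # WHO rule: >= 8 s, inclusive
print("apnea events:", [(e.start_s, e.end_s, e.duration_s) for e in events])

od = sasod.gen_orthostatic_record(0.59, 0.15, n_per_phase=60, seed=3)
point, dist, call = sasod.position_and_classify(od)
print(f"r_supine={point.r_supine:.3f} r_standing={point.r_standing:.3f} "
      f"distance={dist:.3f} call={call.value}")
```

prints

```
apnea events: [(10, 21, 11), (67, 78, 11)]
r_supine=0.499 r_standing=0.029 distance=0.451 call=OD_PATTERN
```

The recording contains two apneic runs of 11 s each, caught by the
detector. The standing-test subject was generated with healthy supine
coupling but a decoupled standing phase; at n = 60 samples per phase the
realized correlations are (0.499, 0.029), which lies 0.451 outside the
healthy reference square, so the screen reports an OD-consistent pattern.

The same functionality is exposed as a CLI (`sasod synth breath`,
`sasod breath detect`, `sasod sas segment|scalogram|cluster|pipeline`,
`sasod od map`, `sasod spectral verify`); run `sasod --help`.

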