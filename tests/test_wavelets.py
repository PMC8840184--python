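"""Mother-wavelet algebra and CWT path equivalence."""

import numpy as np
import pytest

import sasod
from sasod.wavelets import (
    CwtMethod,
    MotherWavelet,
    compute_cwt,
    evaluate_mother_wavelet,
    log_scales,
)


class TestMotherWavelet:
    def test_dms_reduces_to_gabor_when_a_equals_b(self):
        t = np.linspace(-5, 5, 401)
        for delta in (0.5, 1.0, 2.0):
            g = MotherWavelet("GABOR", delta=delta)
            d = MotherWavelet("DMS", A=1.0, B=1.0, delta_d=delta)
            np.testing.assert_allclose(d(t), g(t), rtol=1e-12)

    def test_dms_center_magnitude_reference_parameters(self):
        # hand evaluation: 2 / (pi^(1/4) * 0.5 * 1.5)
        spec = MotherWavelet("DMS", A=1.0, B=0.5, delta_d=0.5)
        expected = 2.0 / (np.pi**0.25 * 0.5 * 1.5)
        assert abs(evaluate_mother_wavelet(spec, 0.0)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.003, abs=5e-4)

    def test_gabor_center_magnitude(self):
        spec = MotherWavelet("GABOR", delta=1.0)
        assert abs(spec(0.0)) == pytest.approx(np.pi**-0.25, rel=1e-12)

    def test_envelope_decays_in_tails(self):
        for spec in (MotherWavelet("GABOR", delta=1.0),
                     MotherWavelet("DMS", A=1.0, B=0.5, delta_d=0.5)):
            assert abs(spec(20.0)) < 1e-12
            assert abs(spec(-20.0)) < 1e-12
            half = spec.support_halfwidth()
            assert spec.envelope(half) <= 1e-8 * spec.envelope(0.0) * 1.01

    def test_nonpositive_parameters_rejected(self):
        for kw in ({"delta": 0.0}, {"A": -1.0}, {"B": 0.0}, {"delta_d": -2.0}):
            with pytest.raises(ValueError):
                MotherWavelet("GABOR", **kw)


class TestComputeCwt:
    def test_zero_signal_gives_zero_coefficients(self):
        sg = compute_cwt(np.zeros(256), 128.0, [0.1, 0.5], MotherWavelet("GABOR"))
        assert not np.any(sg.coefficients)

    def test_linearity(self, rng):
        g = rng.standard_normal(300)
        h = rng.standard_normal(300)
        spec = MotherWavelet("DMS")
        scales = log_scales(2, 30, 5)
        Wg = compute_cwt(g, 150.0, scales, spec).coefficients
        Wh = compute_cwt(h, 150.0, scales, spec).coefficients
        Wgh = compute_cwt(g + h, 150.0, scales, spec).coefficients
        np.testing.assert_allclose(Wgh, Wg + Wh, atol=1e-10)

    @pytest.mark.parametrize("family,kwargs", [
        ("GABOR", {"delta": 1.0}),
        ("DMS", {"A": 1.0, "B": 0.5, "delta_d": 0.5}),
    ])
    def test_direct_and_convolution_paths_agree(self, family, kwargs, rng):
        spec = MotherWavelet(family, **kwargs)
        scales = log_scales(2, 50, 6)
        for _ in range(5):
            f = rng.standard_normal(600)  # 2 s at 300 Hz
            Wd = compute_cwt(f, 300.0, scales, spec, CwtMethod.DIRECT).coefficients
            Wc = compute_cwt(f, 300.0, scales, spec, CwtMethod.CONVOLUTION).coefficients
            rel = np.max(np.abs(Wd - Wc)) / np.max(np.abs(Wd))
            assert rel < 1e-6

    def test_sinusoid_peaks_at_matching_scale(self):
        rate = 400.0
        t = np.arange(0, 2, 1 / rate)
        x = np.sin(2 * np.pi * 5.0 * t)
        scales = log_scales(1, 20, 40)
        sg = compute_cwt(x, rate, scales, MotherWavelet("GABOR", delta=1.0))
        interior = np.abs(sg.coefficients[:, 200:600])
        best = sg.frequencies[int(np.argmax(interior.max(axis=1)))]
        # nearest grid frequency to 5 Hz
        nearest = sg.frequencies[np.argmin(np.abs(sg.frequencies - 5.0))]
        assert best == pytest.approx(nearest)

    def test_time_shift_covariance(self, rng):
        rate, n, shift = 200.0, 800, 50
        f = np.zeros(n)
        f[200:400] = rng.standard_normal(200)
        g = np.roll(f, shift)
        scales = log_scales(5, 40, 4)
        spec = MotherWavelet("GABOR", delta=1.0)
        Wf = np.abs(compute_cwt(f, rate, scales, spec).coefficients)
        Wg = np.abs(compute_cwt(g, rate, scales, spec).coefficients)
        lo, hi = 150, 550  # region far from both boundaries
        np.testing.assert_allclose(Wg[:, lo + shift : hi + shift], Wf[:, lo:hi],
                                   atol=1e-8 * Wf.max())

    def test_invalid_inputs_rejected(self):
        spec = MotherWavelet("GABOR")
        with pytest.raises(ValueError):
            compute_cwt(np.array([]), 100.0, [0.1], spec)
        with pytest.raises(ValueError):
            compute_cwt(np.ones(10), 100.0, [], spec)
        with pytest.raises(ValueError):
            compute_cwt(np.ones(10), 100.0, [-0.1], spec)


class TestScalogramContrast:
    def test_dms_emphasizes_post_apnea_burst_more_than_gabor(self):
        """Contrast ratio (resumption peak |W|) / (normal peak |W|) is
        larger under the DMS wavelet than under Gabor, averaged over
        seeded synthetic segments."""
        rate = 4000.0
        gab = MotherWavelet("GABOR", delta=1.0)
        dms = MotherWavelet("DMS", A=1.0, B=0.5, delta_d=0.5)
        scales = log_scales(100, 1200, 12)
        ratios = {"G": [], "D": []}
        for seed in range(4):
            rec_s = sasod.gen_breath_recording("SAS", 120.0, rate, seed=seed)
            rec_n = sasod.gen_breath_recording("NORMAL", 120.0, rate, seed=seed + 50)
            resum = min((b for b in rec_s.meta["bursts"] if b[2] == "resumption"),
                        key=lambda b: b[0])
            i0 = int((resum[0] - 1) * rate)
            seg_s = rec_s.samples[i0 : i0 + int(2 * rate)]
            t_n = rec_n.meta["bursts"][3][0]
            j0 = int((t_n - 1) * rate)
            seg_n = rec_n.samples[j0 : j0 + int(2 * rate)]
            for key, spec in (("G", gab), ("D", dms)):
                ps = np.abs(compute_cwt(seg_s, rate, scales, spec).coefficients).max()
                pn = np.abs(compute_cwt(seg_n, rate, scales, spec).coefficients).max()
                ratios[key].append(ps / pn)
        assert np.mean(ratios["D"]) > np.mean(ratios["G"])


def test_scalogram_export_and_plot(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    sg = compute_cwt(np.sin(np.linspace(0, 60, 400)), 100.0,
                     log_scales(1, 10, 8), MotherWavelet("DMS"))
    sg.save(tmp_path / "scal")
    assert (tmp_path / "scal.csv").exists()
    assert (tmp_path / "scal.json").exists()
    ax = sg.plot()
    assert ax is not None
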