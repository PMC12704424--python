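"""Raman preprocessing and 13C-shift classification."""

import numpy as np
import pytest

import sipracs as sp
from sipracs.errors import DegenerateInputError, InputError, ParameterError


def _flat(intensities, lo=500.0):
    y = np.asarray(intensities, dtype=float)
    return sp.RamanSpectrum(wavenumbers=lo + np.arange(y.size, dtype=float), intensities=y)


class TestBaselineCorrection:
    def test_all_zero_spectrum_stays_zero(self):
        s = _flat(np.zeros(100))
        out = sp.correct_baseline(s)
        assert np.allclose(out.intensities, 0.0, atol=1e-9)
        assert "baseline_corrected" in out.state

    def test_known_baseline_oracle(self):
        # oracle: the generating quadratic baseline is known exactly, so the
        # corrected spectrum should match the pure Gaussian peak off-peak
        model = sp.PeakModel(components=((1105.0, 8.0, 1.0),), noise_sd=0.0)
        raw = sp.make_spectrum(model, seed=0)
        corrected = sp.correct_baseline(raw)
        true_peak = 1.0 * np.exp(-0.5 * ((raw.wavenumbers - 1105.0) / 8.0) ** 2)
        off_peak = np.abs(raw.wavenumbers - 1105.0) > 5 * 8.0
        residual = np.abs(corrected.intensities - true_peak)
        assert residual[off_peak].mean() < 0.02 * 1.0
        assert abs(corrected.intensities.max() - 1.0) < 0.02 * 1.0

    def test_original_spectrum_unmodified(self, noiseless_unlabeled):
        before = noiseless_unlabeled.intensities.copy()
        sp.correct_baseline(noiseless_unlabeled)
        assert np.array_equal(noiseless_unlabeled.intensities, before)

    def test_short_spectrum_rejected(self):
        with pytest.raises(InputError):
            sp.correct_baseline(_flat(np.ones(5)))

    @pytest.mark.parametrize(
        "kwargs", [{"smoothness": 0.0}, {"asymmetry": 0.7}, {"iterations": 0}]
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            sp.correct_baseline(_flat(np.ones(50)), **kwargs)


class TestNormalization:
    def test_unit_norm_and_state(self, noiseless_unlabeled):
        out = sp.normalize_vector(noiseless_unlabeled)
        assert abs(np.linalg.norm(out.intensities) - 1.0) < 1e-9
        assert "normalized" in out.state

    def test_scale_invariance(self, noiseless_unlabeled):
        scaled = noiseless_unlabeled.replace(
            intensities=10.0 * noiseless_unlabeled.intensities
        )
        a = sp.normalize_vector(noiseless_unlabeled).intensities
        b = sp.normalize_vector(scaled).intensities
        assert np.allclose(a, b, atol=1e-12)

    def test_idempotent(self, noiseless_unlabeled):
        once = sp.normalize_vector(noiseless_unlabeled)
        twice = sp.normalize_vector(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            sp.normalize_vector(_flat(np.zeros(20)))


class TestBandLocalization:
    def test_unlabeled_band_at_1105(self, noiseless_unlabeled):
        pos = sp.locate_band(sp.preprocess(noiseless_unlabeled))
        assert pos == pytest.approx(1105.0, abs=0.5)

    def test_labeled_band_at_1082(self, noiseless_labeled):
        pos = sp.locate_band(sp.preprocess(noiseless_labeled))
        assert pos == pytest.approx(1082.0, abs=0.5)

    def test_subgrid_resolution_on_off_grid_center(self):
        # a peak centered between grid points should be recovered to well
        # under the 1 cm-1 grid step by parabolic refinement
        model = sp.PeakModel(
            components=((1104.4, 8.0, 1.0),), baseline_coeffs=(0.0,), noise_sd=0.0
        )
        pos = sp.locate_band(sp.make_spectrum(model, 0))
        assert pos == pytest.approx(1104.4, abs=0.05)

    def test_monotone_ramp_has_no_band(self):
        s = sp.RamanSpectrum(
            wavenumbers=np.arange(500.0, 2001.0), intensities=np.arange(1501.0)
        )
        assert sp.locate_band(s) is None

    def test_window_outside_range_rejected(self, noiseless_unlabeled):
        with pytest.raises(InputError):
            sp.locate_band(noiseless_unlabeled, 100.0, 300.0)


class TestClassification:
    def test_labeled_call_with_minus_23_shift(self, noiseless_labeled):
        res = sp.classify_labeling(sp.preprocess(noiseless_labeled))
        assert res.labeled is True and res.call == "labeled"
        assert res.shift == pytest.approx(-23.0, abs=0.5)
        assert res.shift == res.observed_position - res.reference_position

    def test_unlabeled_call_zero_shift(self, noiseless_unlabeled):
        res = sp.classify_labeling(sp.preprocess(noiseless_unlabeled))
        assert res.labeled is False and res.call == "unlabeled"
        assert res.shift == pytest.approx(0.0, abs=0.5)

    def test_band_exactly_on_boundary_is_unlabeled(self):
        model = sp.PeakModel(
            components=((1093.5, 8.0, 1.0),), baseline_coeffs=(0.0,), noise_sd=0.0
        )
        res = sp.classify_labeling(sp.make_spectrum(model, 0))
        assert res.observed_position == pytest.approx(1093.5, abs=1e-6)
        assert res.labeled is False

    def test_no_band_is_indeterminate(self):
        s = sp.RamanSpectrum(
            wavenumbers=np.arange(500.0, 2001.0), intensities=np.arange(1501.0)
        )
        res = sp.classify_labeling(s)
        assert res.call == "indeterminate"
        assert res.labeled is None and res.shift is None

    @pytest.mark.parametrize("scale", [1e-3, 1.0, 37.0, 1e4])
    def test_rescaling_invariance(self, noiseless_labeled, scale):
        base = sp.classify_labeling(sp.preprocess(noiseless_labeled))
        scaled = noiseless_labeled.replace(
            intensities=scale * noiseless_labeled.intensities
        )
        res = sp.classify_labeling(sp.preprocess(scaled))
        assert res.labeled == base.labeled
        assert res.observed_position == pytest.approx(base.observed_position, abs=1e-6)

    @pytest.mark.parametrize("proportion", [0.0, 0.3, 1.0])
    def test_perfect_accuracy_at_zero_noise(self, proportion):
        n = 10
        n_labeled = int(round(proportion * n))
        cohort = sp.make_screen_cohort(n, n_labeled, noise_sd=0.0, seed=7)
        calls = [sp.classify_labeling(sp.preprocess(s)).labeled for s in cohort]
        assert sum(calls) == n_labeled

    def test_planted_shift_recovery_under_noise(self):
        # planted -23 cm-1 shift recovered with MAE < 1 cm-1 at 5% noise
        errors = []
        for seed in range(1, 101):
            s = sp.make_spectrum(sp.PeakModel(noise_sd=0.05, labeled=True), seed)
            res = sp.classify_labeling(sp.preprocess(s))
            assert res.labeled is True
            errors.append(abs(res.shift - (-23.0)))
        assert np.mean(errors) < 1.0


class TestBandIntensityComparison:
    def _groups(self, n=60, noise_sd=0.02):
        labeled = [
            sp.preprocess(sp.make_spectrum(sp.PeakModel(noise_sd=noise_sd, labeled=True), s))
            for s in range(n)
        ]
        unlabeled = [
            sp.preprocess(sp.make_spectrum(sp.PeakModel(noise_sd=noise_sd), 1000 + s))
            for s in range(n)
        ]
        return labeled, unlabeled

    def test_identical_groups_give_f_zero_p_one(self):
        group = [
            sp.preprocess(sp.make_spectrum(sp.PeakModel(noise_sd=0.02), s))
            for s in range(5)
        ]
        out = sp.compare_band_intensities(group, list(group))
        for res in out.values():
            assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_f_equals_t_squared_for_two_groups(self):
        labeled, unlabeled = self._groups(n=8)
        out = sp.compare_band_intensities(labeled, unlabeled)
        for pos, res in out.items():
            xa = np.array(
                [s.intensities[np.argmin(np.abs(s.wavenumbers - pos))] for s in labeled]
            )
            xb = np.array(
                [s.intensities[np.argmin(np.abs(s.wavenumbers - pos))] for s in unlabeled]
            )
            t, _ = sp.compare_treatments(xa, xb, equal_var=True)
            assert res.f_statistic == pytest.approx(t**2, abs=1e-9)

    def test_separated_groups_highly_significant(self):
        # 60 cells per group at 2% noise: both band positions discriminate
        labeled, unlabeled = self._groups(n=60, noise_sd=0.02)
        out = sp.compare_band_intensities(labeled, unlabeled)
        assert out[1105.0].p_value < 1e-3
        assert out[1082.0].p_value < 1e-3

    def test_small_group_rejected(self):
        labeled, unlabeled = self._groups(n=2)
        with pytest.raises(InputError):
            sp.compare_band_intensities(labeled[:1], unlabeled)
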