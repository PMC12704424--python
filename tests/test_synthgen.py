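"""Synthetic-data generator contracts: spectra, SIP tables, decay, enzymes."""

import math

import numpy as np
import pytest

import sipracs as sp
from sipracs.errors import ParameterError


class TestSpectrumGeneration:
    def test_unlabeled_maximum_at_1105(self):
        model = sp.PeakModel(noise_sd=0.0, baseline_coeffs=(0.0,))
        s = sp.make_spectrum(model, seed=0)
        window = (s.wavenumbers >= 1040) & (s.wavenumbers <= 1140)
        peak = s.wavenumbers[window][np.argmax(s.intensities[window])]
        assert peak == pytest.approx(1105.0, abs=0.5)

    def test_labeled_amide_band_moves_to_1082(self):
        model = sp.PeakModel(noise_sd=0.0, baseline_coeffs=(0.0,), labeled=True)
        s = sp.make_spectrum(model, seed=0)
        window = (s.wavenumbers >= 1040) & (s.wavenumbers <= 1140)
        peak = s.wavenumbers[window][np.argmax(s.intensities[window])]
        assert peak == pytest.approx(1082.0, abs=0.5)
        # the other bands do not move
        for center in (1003.0, 1450.0, 1660.0):
            near = np.abs(s.wavenumbers - center) <= 20
            local = s.wavenumbers[near][np.argmax(s.intensities[near])]
            assert local == pytest.approx(center, abs=0.5)

    def test_empty_model_gives_zero_spectrum(self):
        model = sp.PeakModel(
            components=((1105.0, 8.0, 0.0),), baseline_coeffs=(0.0,), noise_sd=0.0
        )
        s = sp.make_spectrum(model, seed=0)
        assert np.all(s.intensities == 0.0)

    def test_partial_labeling_splits_amide_band(self):
        model = sp.PeakModel(
            components=((1105.0, 5.0, 1.0),),
            baseline_coeffs=(0.0,),
            noise_sd=0.0,
            labeled=True,
            label_fraction=0.5,
        )
        s = sp.make_spectrum(model, seed=0)
        at = lambda w: s.intensities[np.argmin(np.abs(s.wavenumbers - w))]
        assert at(1105.0) == pytest.approx(at(1082.0), rel=0.02)

    def test_seed_determinism(self):
        a = sp.make_spectrum(sp.PeakModel(), seed=5)
        b = sp.make_spectrum(sp.PeakModel(), seed=5)
        assert np.array_equal(a.intensities, b.intensities)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"grid": (2000.0, 500.0, 1.0)},
            {"grid": (500.0, 2000.0, -1.0)},
            {"components": ((1105.0, -1.0, 1.0),)},
            {"components": ((1105.0, 8.0, -0.5),)},
            {"label_fraction": 1.5},
        ],
    )
    def test_invalid_model_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            sp.PeakModel(**kwargs)

    def test_cohort_plants_exact_label_count(self):
        cohort = sp.make_screen_cohort(n_cells=40, n_labeled=7, noise_sd=0.0, seed=1)
        calls = [sp.classify_labeling(sp.preprocess(s)).labeled for s in cohort]
        assert sum(calls) == 7
        assert all(s.treatment == "13C" for s in cohort)


def _expected_ref_asv1(design: sp.SIPDesign) -> float:
    """Closed-form expected REF of the first (active) ASV.

    Derived independently from the partition algebra: each ASV's mass splits
    heavy:light; relative abundance in a fraction-class sample is its mass
    over the class total, so with one active ASV of baseline abundance b and
    labeled heavy share hs (baseline h), the 12C ratio is 1 and

        REF = [hs / (h(1-b) + b hs)] / [ls / (l(1-b) + b ls)].
    """
    b = design.abundances()[0]
    h = design.p_heavy_baseline
    s = design.labeling_strength
    hs = (1 - s) * h + s * design.p_heavy_labeled
    ls = 1 - hs
    l = 1 - h
    a13h = hs / (h * (1 - b) + b * hs)
    a13l = ls / (l * (1 - b) + b * ls)
    return a13h / a13l


class TestSIPExperiment:
    def test_samples_are_exact_compositions(self):
        t12, t13 = sp.make_sip_experiment(sp.SIPDesign(seed=0))
        for table in (t12, t13):
            sums = table.abundance.sum(axis=0)
            assert np.allclose(sums, 1.0, atol=1e-12)
            assert set(table.samples["fraction_class"]) == {"heavy", "light"}

    def test_densities_inside_published_windows(self):
        _, t13 = sp.make_sip_experiment(sp.SIPDesign(seed=0))
        for _, row in t13.samples.iterrows():
            lo, hi = (
                sp.HEAVY_WINDOW if row["fraction_class"] == "heavy" else sp.LIGHT_WINDOW
            )
            assert lo <= row["density_g_ml"] <= hi

    def test_determinism(self):
        d = sp.SIPDesign(seed=9)
        a12, a13 = sp.make_sip_experiment(d)
        b12, b13 = sp.make_sip_experiment(d)
        assert a12.abundance.equals(b12.abundance)
        assert a13.samples.equals(b13.samples)

    def test_null_design_mean_ref_near_one(self):
        # strength 0: expected REF of every ASV is 1 (mean over 200 runs)
        refs = []
        for seed in range(200):
            t12, t13 = sp.make_sip_experiment(
                sp.SIPDesign(labeling_strength=0.0, seed=seed)
            )
            refs.append([r.ref for r in sp.compute_ref(t12, t13)])
        mean_per_asv = np.asarray(refs).mean(axis=0)
        assert np.all(np.abs(mean_per_asv - 1.0) < 0.05)

    def test_fully_labeled_asv_matches_closed_form(self):
        # simulation mean against the independent partition-algebra oracle;
        # high dispersion isolates the partition model (at low dispersion the
        # ratio estimator carries a small upward Jensen bias)
        expected = _expected_ref_asv1(sp.SIPDesign(labeling_strength=1.0))
        for dispersion, rel in ((5000.0, 0.02), (500.0, 0.10)):
            sims = []
            for seed in range(200):
                t12, t13 = sp.make_sip_experiment(
                    sp.SIPDesign(labeling_strength=1.0, dispersion=dispersion, seed=seed)
                )
                sims.append(sp.compute_ref(t12, t13)[0].ref)
            assert np.mean(sims) == pytest.approx(expected, rel=rel)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ParameterError):
            sp.SIPDesign(n_replicates=0)
        with pytest.raises(ParameterError):
            sp.SIPDesign(n_asvs=5, active_ids=frozenset({9}))
        with pytest.raises(ParameterError):
            sp.SIPDesign(labeling_strength=1.2)
        with pytest.raises(ParameterError):
            sp.SIPDesign(n_asvs=3, baseline_abundances=(0.5, 0.4))


class TestDecayGeneration:
    def test_zero_rate_zero_noise_is_constant(self):
        d = sp.DecayDesign(c0=5.0, k=0.0, noise_sd=0.0)
        series = sp.make_decay_series(d)
        assert np.all(series.concentrations == 5.0)

    def test_closed_form_day7_concentration(self):
        # k chosen from the closed form so C(7) = 2.01 exactly -> 59.8% removal
        k = math.log(5.0 / 2.01) / 7.0
        series = sp.make_decay_series(sp.DecayDesign(c0=5.0, k=k, noise_sd=0.0))
        c7 = series.replicate_means[series.times == 7.0][0]
        assert c7 == pytest.approx(2.01, rel=1e-12)
        assert sp.format_percent(sp.removal_percent(5.0, c7)) == "59.8"

    def test_noiseless_series_refit_recovers_rate(self):
        d = sp.DecayDesign(noise_sd=0.0)
        fit = sp.fit_first_order(sp.make_decay_series(d))
        assert fit.k == pytest.approx(d.k, rel=1e-10)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ParameterError):
            sp.DecayDesign(c0=-5.0)
        with pytest.raises(ParameterError):
            sp.DecayDesign(times=(3.0, 1.0))


class TestEnzymeGeneration:
    def test_noiseless_panel_is_exactly_linear(self):
        removals = np.linspace(10, 90, 8)
        panel = sp.make_enzyme_panel(0.15, 1.0, 0.0, removals, seed=0)
        corr = sp.correlate_activity_removal(panel, removals)
        assert corr.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_null_slope_gives_near_zero_r_squared(self):
        # slope 0: mean sample R^2 over 200 draws approaches E[R^2] = 1/(n-1)
        removals = np.linspace(5, 95, 10)
        r2 = [
            sp.correlate_activity_removal(
                sp.make_enzyme_panel(0.0, 5.0, 1.0, removals, seed=s), removals
            ).r_squared
            for s in range(200)
        ]
        assert np.mean(r2) == pytest.approx(1.0 / 9.0, abs=0.05)

    def test_out_of_range_removals_rejected(self):
        with pytest.raises(ParameterError):
            sp.make_enzyme_panel(0.1, 1.0, 0.0, np.array([-5.0, 50.0]), seed=0)
        with pytest.raises(ParameterError):
            sp.make_enzyme_panel(0.1, 1.0, 0.0, np.array([50.0, 120.0]), seed=0)
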