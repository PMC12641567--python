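"""Scenario presets, ensemble sampling, and trace synthesis."""

import numpy as np
import pytest
from scipy import stats

from cdmspipe.instrument import AcquisitionConfig, IonGroundTruth, TrapCalibration
from cdmspipe.simulate import (
    PRESET_NAMES,
    build_scenario,
    emulate_measurements,
    ensemble_to_dataframe,
    sample_ion_ensemble,
    synthesize_trace,
)


class TestBuildScenario:
    def test_aa_neutral_structure(self):
        sc = build_scenario("aa_neutral")
        comp = sc.components[0]
        assert comp.mass_da == pytest.approx(4.93e6)
        peaks = comp.charge_peaks
        assert [p.center_e for p in peaks] == [165.0, 150.0]
        assert [p.weight for p in peaks] == [0.85, pytest.approx(0.15)]

    def test_pbs_neutral_centroids_and_adduct(self):
        sc = build_scenario("pbs_neutral")
        comp = sc.components[0]
        assert sorted((p.center_e for p in comp.charge_peaks), reverse=True) == [
            171, 159, 147, 137, 128, 117, 102]
        assert comp.mass_da == pytest.approx(4.9105e6 + 0.38e6)

    def test_freeze_thaw_override_to_intact_only(self):
        sc = build_scenario("freeze_thaw", {"degraded_weight": 0.0, "empty_weight": 0.0})
        assert len(sc.components) == 1
        assert sc.components[0].label == "INTACT_FULL"

    def test_unknown_preset_lists_names(self):
        with pytest.raises(ValueError, match="aa_neutral"):
            build_scenario("no_such_preset")

    def test_unknown_override_key_rejected(self):
        with pytest.raises(ValueError, match="degraded_weight"):
            build_scenario("freeze_thaw", {"bogus_key": 1.0})


class TestSampleIonEnsemble:
    def test_mixture_mean_charge(self, cal):
        sc = build_scenario("aa_neutral")
        ions = sample_ion_ensemble(sc, 10_000, cal, seed=3)
        mean_z = np.mean([i.charge_e for i in ions])
        assert mean_z == pytest.approx(165 * 0.85 + 150 * 0.15, abs=0.2)

    def test_fragment_mass_range(self, cal):
        sc = build_scenario("aa_ph4_37c")
        ions = sample_ion_ensemble(sc, 4000, cal, seed=5)
        frag = [i for i in ions if i.population_label == "FRAGMENT"]
        assert frag
        assert all(1e6 <= i.mass_da <= 1.2e7 for i in frag)

    def test_single_ion(self, cal):
        assert len(sample_ion_ensemble(build_scenario("aa_neutral"), 1, cal, 1)) == 1

    def test_seed_determinism_byte_for_byte(self, cal):
        sc = build_scenario("freeze_thaw")
        a = ensemble_to_dataframe(sample_ion_ensemble(sc, 500, cal, 11))
        b = ensemble_to_dataframe(sample_ion_ensemble(sc, 500, cal, 11))
        assert a.equals(b)

    def test_frequency_consistent_with_calibration(self, cal):
        ions = sample_ion_ensemble(build_scenario("aa_neutral"), 50, cal, 2)
        for i in ions:
            assert i.f0_hz == pytest.approx(np.sqrt(cal.mass_cal_c * i.charge_e / i.mass_da))

    def test_component_weights_converge(self, cal):
        """Chi-square goodness of fit of empirical component counts vs the
        configured weights, alpha=0.01 across seeds."""
        sc = build_scenario("nuclease")  # fixed-label components: 0.97 / 0.03
        n = 2000
        rejected = 0
        n_seeds = 40
        for seed in range(n_seeds):
            ions = sample_ion_ensemble(sc, n, cal, seed=seed)
            labels = [i.population_label for i in ions]
            n_trend = labels.count("BOUND")
            chi2, p = stats.chisquare([n_trend, n - n_trend], np.array([0.97, 0.03]) * n)
            rejected += p < 0.01
        assert rejected <= 2  # >=95% of seeds not rejected


class TestSynthesizeTrace:
    def test_noiseless_dc_level(self, cal0, acq100):
        ion = IonGroundTruth(mass_da=4.93e6, charge_e=165.0, f0_hz=10_000.0)
        tr = synthesize_trace(ion, cal0, acq100, seed=1)
        assert tr.samples.mean() == pytest.approx(165 * 0.45, abs=1e-6)

    def test_noiseless_fundamental_fourier_amplitude(self, cal0, acq100):
        ion = IonGroundTruth(mass_da=4.93e6, charge_e=165.0, f0_hz=10_000.0)
        tr = synthesize_trace(ion, cal0, acq100, seed=1)
        t = np.arange(len(tr.samples)) / tr.sample_rate_hz
        x = tr.samples - tr.samples.mean()
        a1 = 2 * abs(np.dot(x, np.exp(-2j * np.pi * 1e4 * t))) / len(x)
        assert a1 == pytest.approx(165 * 2 * np.sin(0.45 * np.pi) / np.pi, abs=0.05)

    def test_zero_charge_zero_trace(self, cal0, acq100):
        ion = IonGroundTruth(mass_da=4.93e6, charge_e=0.0, f0_hz=10_000.0)
        tr = synthesize_trace(ion, cal0, acq100, seed=1)
        assert np.all(tr.samples == 0.0)

    def test_even_harmonics_vanish_at_half_duty(self, acq100):
        cal = TrapCalibration(duty_cycle=0.5, noise_rms=0.0)
        ion = IonGroundTruth(mass_da=4.93e6, charge_e=165.0, f0_hz=10_000.0)
        tr = synthesize_trace(ion, cal, acq100, seed=1)
        t = np.arange(len(tr.samples)) / tr.sample_rate_hz
        x = tr.samples - tr.samples.mean()
        a = [2 * abs(np.dot(x, np.exp(-2j * np.pi * n * 1e4 * t))) / len(x) for n in (1, 2, 4)]
        assert a[1] < 1e-9 * a[0]
        assert a[2] < 1e-9 * a[0]

    def test_aliasing_precondition(self, cal0, acq100):
        ion = IonGroundTruth(mass_da=1e6, charge_e=200.0, f0_hz=2e5)
        with pytest.raises(ValueError, match="alias"):
            synthesize_trace(ion, cal0, acq100, seed=1)

    def test_mass_loss_raises_frequency(self, cal0, acq100):
        ion = IonGroundTruth(
            mass_da=5.1e6, charge_e=165.0, f0_hz=9830.0, mass_loss_rate_da_per_s=3.19e5
        )
        tr = synthesize_trace(ion, cal0, acq100, seed=1)
        # instantaneous frequency at the end exceeds the start
        n = len(tr.samples)
        t = np.arange(n) / tr.sample_rate_hz
        first, last = tr.samples[: n // 4], tr.samples[-n // 4 :]
        zc_first = np.sum(np.diff(first > first.mean()) > 0)
        zc_last = np.sum(np.diff(last > last.mean()) > 0)
        assert zc_last > zc_first


def test_emulate_measurements_tracks_truth(cal, acq):
    ions = sample_ion_ensemble(build_scenario("aa_neutral"), 300, cal, 9)
    meas = emulate_measurements(ions, cal, acq, seed=10)
    dz = np.array([m.charge_e - i.charge_e for m, i in zip(meas, ions)])
    assert abs(dz.mean()) < 0.2
    assert 0.7 < dz.std() < 1.3
    for m in meas[:10]:
        assert m.mass_da == pytest.approx(m.mz_th * m.charge_e, rel=1e-12)


def test_all_presets_buildable_and_sampleable(cal):
    for name in PRESET_NAMES:
        ions = sample_ion_ensemble(build_scenario(name), 50, cal, 1)
        assert len(ions) == 50
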