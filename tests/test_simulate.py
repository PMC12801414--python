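"""Synthetic-study generator: determinism, design arithmetic, and
calibration of the marginal distributions against the intended study
conditions."""

import numpy as np
import pandas as pd
import pytest

from oxiskin.simulate import (DEFAULT_ITA_MIXTURE, DeviceProfile,
                              GeneratorConfig, generate_dataset,
                              generate_spo2, sample_patients, sample_sao2)


class TestPatients:
    def test_point_mass_mixture(self):
        cfg = GeneratorConfig(n_patients=200, ita_mixture={"dark": 1.0},
                              seed=1)
        pats = sample_patients(cfg)
        assert (pats["ita_true"] < -30).all()
        assert (pats["ita_true"] >= -60).all()

    def test_category_frequencies_match_mixture(self):
        cfg = GeneratorConfig(n_patients=10_000, seed=2)
        pats = sample_patients(cfg)
        freq = pats["category_true"].replace(
            {"very_light": "light"}).value_counts(normalize=True)
        for cat, p in DEFAULT_ITA_MIXTURE.items():
            se = np.sqrt(p * (1 - p) / len(pats))
            assert freq[cat] == pytest.approx(p, abs=3 * se), cat

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_patients=50, seed=11)
        pd.testing.assert_frame_equal(sample_patients(cfg),
                                      sample_patients(cfg))

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(ita_mixture={"dark": 0.4, "light": 0.4})

    def test_haemoglobin_distribution(self):
        pats = sample_patients(GeneratorConfig(n_patients=20_000, seed=3))
        q = np.percentile(pats["haemoglobin_g_per_l"], [25, 50, 75])
        assert q[1] == pytest.approx(101, abs=2)
        assert q[0] == pytest.approx(86, abs=3)
        assert q[2] == pytest.approx(117, abs=3)


class TestSao2:
    def test_marginal_median_and_iqr(self, rng):
        s = sample_sao2(20_000, 5, rng).ravel()
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        assert round(med) == 96
        assert round(q1) == 94
        assert round(q3) == 97

    def test_band_masses_match_study_margins(self, rng):
        """Rounded SaO2 strata: <88 ~1.7%, 88-92 ~14.1%, 93-94 ~16.6%."""
        n_pat, n_samp = 17_000, 6   # ~1e5 draws
        s = sample_sao2(n_pat, n_samp, rng)
        r = np.floor(s + 0.5)
        targets = {"lt88": (r < 88, 0.017), "b8892": ((r >= 88) & (r <= 92),
                                                      0.141),
                   "b9394": ((r >= 93) & (r <= 94), 0.166)}
        for name, (mask, p) in targets.items():
            # within-patient correlation inflates the binomial SE: use the
            # patient-level (cluster) SE for the 3-SE band
            per_pat = mask.mean(axis=1)
            se = per_pat.std(ddof=1) / np.sqrt(n_pat)
            assert per_pat.mean() == pytest.approx(p, abs=3 * se), name

    def test_zero_ar_exchangeability_bounds(self, rng):
        s = sample_sao2(500, 4, rng)
        assert s.min() >= 80.0 and s.max() <= 100.0


class TestSpo2:
    def test_identity_device(self, identity_device, rng):
        sao2 = np.array([91.2, 95.7, 99.4])
        out = generate_spo2(sao2, 0.0, identity_device, 0.0, rng)
        np.testing.assert_allclose(out, np.round(sao2))

    def test_zero_bias_at_tipping_point_and_reference(self, rng):
        dev = DeviceProfile("d", 94.0, 0.4, 1.2, noise_sd_pp=0.0)
        out = generate_spo2(np.array([94.0]), 46.0, dev, 0.0, rng,
                            ita_ref=46.0)
        assert out[0] == 94.0

    def test_monte_carlo_mean_matches_formula(self, rng):
        dev = DeviceProfile("d", 93.0, 0.3, 1.0, noise_sd_pp=2.0)
        n = 200_000
        sao2 = np.full(n, 95.0)
        out = generate_spo2(sao2, -44.0, dev, 0.0, rng)
        expected = dev.mean_reading(95.0, -44.0)
        se = (np.sqrt(dev.noise_sd_pp**2 + 1 / 12) / np.sqrt(n))
        assert out.mean() == pytest.approx(expected, abs=4 * se)

    def test_integer_and_clipped(self, rng):
        dev = DeviceProfile("d", 90.0, 0.5, 0.0, noise_sd_pp=5.0)
        out = generate_spo2(np.full(500, 80.0), 0.0, dev, -30.0, rng)
        assert np.all(out == np.round(out))
        assert out.min() >= 70.0 and out.max() <= 100.0


class TestDataset:
    def test_default_design_arithmetic(self):
        cfg = GeneratorConfig()
        assert cfg.n_pairs == 10_800
        assert cfg.pairs_per_patient == 12

    def test_single_pair(self):
        cfg = GeneratorConfig(n_patients=1, n_sites=1, samples_per_patient=1,
                              devices_per_patient=1, seed=4)
        study = generate_dataset(cfg, with_readings=False)
        assert len(study.observations) == 1

    def test_pair_count_and_schema(self, small_study):
        obs = small_study.observations
        cfg = GeneratorConfig(n_patients=200, n_sites=6, seed=314)
        assert len(obs) == cfg.n_pairs
        assert not obs.duplicated(
            ["patient_id", "device_model", "sample_index"]).any()
        assert obs.groupby("patient_id")["device_model"].nunique().eq(2).all()
        # each site offers exactly two device models
        assert obs.groupby("site_id")["device_model"].nunique().eq(2).all()

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_patients=20, n_sites=2, seed=9)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.observations.to_csv(pa, index=False)
        b.observations.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()
        pd.testing.assert_frame_equal(a.readings, b.readings)

    def test_tone_gradient_direction(self):
        """Darker tones read higher: empirical errors decrease with ITA."""
        cfg = GeneratorConfig(n_patients=2000, n_sites=4, seed=12)
        df = generate_dataset(cfg, with_readings=False).merged()
        df["err"] = df["spo2_pct"] - df["sao2_pct"]
        dark = df[df["ita_degrees"] < -30]["err"].mean()
        light = df[df["ita_degrees"] > 41]["err"].mean()
        assert dark > light
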