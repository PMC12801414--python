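"""Model-free accuracy metrics against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxiskin.empirical import (empirical_accuracy, empirical_auc,
                               evaluate_by, occult_hypoxaemia_rate,
                               threshold_diagnostics)

from conftest import make_pairs


class TestAccuracy:
    def test_perfect_agreement(self):
        p = make_pairs([95, 92, 88], [95, 92, 88])
        acc = empirical_accuracy(p)
        assert (acc.bias_pp, acc.precision_pp, acc.arms_pp) == (0, 0, 0)

    def test_symmetric_errors(self):
        p = make_pairs([94, 90], [92, 92])
        acc = empirical_accuracy(p)
        assert acc.bias_pp == pytest.approx(0.0)
        assert acc.precision_pp == pytest.approx(2.0)
        assert acc.arms_pp == pytest.approx(2.0)

    def test_closed_form_moments(self, rng):
        err = rng.normal(1.0, 2.0, size=10_000)
        p = make_pairs(95 + err, np.full(10_000, 95.0))
        acc = empirical_accuracy(p)
        assert acc.bias_pp == pytest.approx(1.0, abs=0.07)
        assert acc.precision_pp == pytest.approx(2.0, abs=0.06)
        assert acc.arms_pp == pytest.approx(np.sqrt(5.0), abs=0.06)

    def test_pythagorean_identity(self, rng):
        err = rng.normal(0.7, 1.3, size=500)
        acc = empirical_accuracy(make_pairs(90 + err, np.full(500, 90.0)))
        assert acc.arms_pp**2 == pytest.approx(
            acc.bias_pp**2 + acc.precision_pp**2, abs=1e-10)

    def test_shift_property(self, rng):
        """Adding c to every SpO2 shifts bias by c, precision unchanged."""
        spo2 = rng.integers(85, 100, size=200).astype(float)
        sao2 = spo2 + rng.normal(0, 2, size=200)
        a = empirical_accuracy(make_pairs(spo2, sao2))
        b = empirical_accuracy(make_pairs(spo2 + 3.0, sao2))
        assert b.bias_pp == pytest.approx(a.bias_pp + 3.0)
        assert b.precision_pp == pytest.approx(a.precision_pp)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_accuracy(make_pairs([], []))


class TestThresholds:
    def test_direct_counts(self):
        p = make_pairs([93, 95, 91], [92, 91, 90])
        d = threshold_diagnostics(p, 92)
        assert (d.fn, d.tp) == (2, 1)
        assert d.fnr == pytest.approx(2 / 3)

    def test_degenerate_stratum_flagged(self):
        p = make_pairs([95, 96], [95, 96])
        with pytest.warns(UserWarning):
            d = threshold_diagnostics(p, 92)
        assert np.isnan(d.fnr)
        assert d.fpr == 0.0

    def test_counts_match_bruteforce(self, rng):
        spo2 = rng.integers(80, 101, size=1000).astype(float)
        sao2 = rng.uniform(80, 100, size=1000)
        p = make_pairs(spo2, sao2)
        d = threshold_diagnostics(p, 94)
        fn = tp = fp = tn = 0
        for s, a in zip(spo2, sao2):
            if a <= 92:
                if s <= 94:
                    tp += 1
                else:
                    fn += 1
            elif s <= 94:
                fp += 1
            else:
                tn += 1
        assert (d.fn, d.tp, d.fp, d.tn) == (fn, tp, fp, tn)
        assert d.fn + d.tp + d.fp + d.tn == 1000

    def test_monotone_in_threshold(self, rng):
        spo2 = rng.integers(80, 101, size=400).astype(float)
        sao2 = rng.uniform(85, 100, size=400)
        p = make_pairs(spo2, sao2)
        d92, d94 = threshold_diagnostics(p, 92), threshold_diagnostics(p, 94)
        assert d94.fnr <= d92.fnr
        assert d94.fpr >= d92.fpr

    def test_rounding_convention(self):
        # SaO2 92.4 rounds to 92 => condition positive only under rounding
        p = make_pairs([95.0], [92.4])
        with pytest.warns(UserWarning):
            assert threshold_diagnostics(p, 92).tn == 1
        d = threshold_diagnostics(p, 92, round_sao2=True)
        assert d.fn == 1


class TestAuc:
    def test_perfect_separation(self):
        p = make_pairs([85, 86, 99, 100], [90, 91, 95, 96])
        assert empirical_auc(p) == 1.0

    def test_uninformative(self):
        p = make_pairs([90, 95, 90, 95], [90, 90, 95, 95])
        assert empirical_auc(p) == 0.5

    def test_matches_pairwise_bruteforce(self, rng):
        spo2 = rng.integers(85, 100, size=200).astype(float)
        sao2 = rng.uniform(85, 100, size=200)
        p = make_pairs(spo2, sao2)
        auc = empirical_auc(p)
        pos, neg = spo2[sao2 <= 92], spo2[sao2 > 92]
        total = 0.0
        for a in pos:
            for b in neg:
                total += 1.0 if a < b else (0.5 if a == b else 0.0)
        assert auc == pytest.approx(total / (len(pos) * len(neg)), abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=3.0))
    @settings(max_examples=20, derandomize=True)
    def test_monotone_transform_invariance(self, power):
        rng = np.random.default_rng(5)
        spo2 = rng.uniform(70, 100, size=150)
        sao2 = rng.uniform(85, 100, size=150)
        p1 = make_pairs(spo2, sao2)
        p2 = make_pairs(spo2**power, sao2)  # strictly increasing transform
        assert empirical_auc(p1) == pytest.approx(empirical_auc(p2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc(make_pairs([95, 96], [95, 96]))


class TestOccult:
    def test_direct_fraction(self):
        p = make_pairs([93, 91], [87, 86])
        assert occult_hypoxaemia_rate(p) == 0.5

    def test_all_detected(self):
        p = make_pairs([90, 88], [87, 85])
        assert occult_hypoxaemia_rate(p) == 0.0

    def test_empty_stratum_flagged(self):
        p = make_pairs([95], [95])
        with pytest.warns(UserWarning):
            assert np.isnan(occult_hypoxaemia_rate(p))

    def test_matches_filtered_count(self, rng):
        sao2 = rng.uniform(82, 95, size=500)
        spo2 = np.round(sao2 + rng.normal(2, 2, size=500))
        p = make_pairs(spo2, sao2)
        mask = sao2 < 88
        expected = float(np.mean(spo2[mask] > 92))
        assert occult_hypoxaemia_rate(p) == pytest.approx(expected)

    def test_per_patient_variant(self):
        p = make_pairs([93, 90, 95], [87, 86, 87],
                       patient_id=["a", "a", "b"])
        assert occult_hypoxaemia_rate(p) == pytest.approx(2 / 3)
        assert occult_hypoxaemia_rate(p, per_patient=True) == 1.0


def test_evaluate_by_device(small_df):
    tab = evaluate_by(small_df, ["device_model"])
    assert len(tab) == small_df["device_model"].nunique()
    assert {"bias_pp", "fnr92", "fpr94", "auc", "occult"} <= set(tab.columns)
    assert tab["n"].sum() == len(small_df)
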