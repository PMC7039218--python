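import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgnet.classic_features import (
    DB7_DEC_HI,
    DB7_DEC_LO,
    FeatureVector,
    ar_coefficients,
    dwt_detail_marginals,
    export_features_csv,
    extract_feature_set,
    feature_names,
    features_per_channel,
    fit_baseline,
    predict,
    rms,
    sample_entropy,
    td_features,
)
from emgnet.signal_io import WindowSample


def td_oracle(x, zc_thr=0.0, ssc_thr=0.0):
    """Plain-loop reimplementation of MAV/ZC/SSC/WL."""
    x = list(map(float, x))
    n = len(x)
    mav = sum(abs(v) for v in x) / n
    zc = 0
    for i in range(n - 1):
        if (x[i] > 0 > x[i + 1] or x[i] < 0 < x[i + 1]) and abs(
            x[i] - x[i + 1]
        ) >= zc_thr:
            zc += 1
    ssc = 0
    for i in range(1, n - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0 and max(
            abs(x[i] - x[i - 1]), abs(x[i] - x[i + 1])
        ) >= ssc_thr:
            ssc += 1
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    return mav, zc, ssc, wl


def sampen_oracle(x, m=2, r=0.2):
    """Naive O(N^2) double-loop sample entropy."""
    x = list(map(float, x))
    n_templates = len(x) - m
    a = b = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if b == 0:
        return 0.0
    if a == 0:
        return float("inf")
    return -np.log(a / b)


class TestTdFeatures:
    def test_alternating_signal(self):
        # hand enumeration: x = [1,-1,1,-1]
        assert td_features([1, -1, 1, -1]) == (1.0, 3, 2, 6.0)

    def test_constant(self):
        mav, zc, ssc, wl = td_features([2.5] * 10)
        assert (mav, zc, ssc, wl) == (2.5, 0, 0, 0.0)

    def test_monotone_ramp(self):
        mav, zc, ssc, wl = td_features([0, 1, 2, 3])
        assert (zc, ssc, wl) == (0, 0, 3.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            td_features([1.0, 2.0])

    def test_wl_shift_invariant_mav_not(self, rng):
        x = rng.normal(size=52)
        mav0, _, _, wl0 = td_features(x)
        mav1, _, _, wl1 = td_features(x + 3.0)
        assert wl1 == pytest.approx(wl0)
        assert mav1 != pytest.approx(mav0)

    @given(
        data=st.lists(
            st.floats(-5, 5, allow_nan=False, allow_infinity=False),
            min_size=3,
            max_size=60,
        ),
        zc_thr=st.floats(0, 1),
        ssc_thr=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence(self, data, zc_thr, ssc_thr):
        got = td_features(data, zc_thr, ssc_thr)
        want = td_oracle(data, zc_thr, ssc_thr)
        assert got[1] == want[1] and got[2] == want[2]
        assert got[0] == pytest.approx(want[0])
        assert got[3] == pytest.approx(want[3])


class TestRms:
    def test_closed_form(self):
        assert rms([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_constant(self):
        assert rms([-2.0] * 7) == pytest.approx(2.0)

    def test_homogeneity(self, rng):
        x = rng.normal(size=30)
        assert rms(-3.0 * x) == pytest.approx(3.0 * rms(x))

    def test_empty(self):
        with pytest.raises(ValueError):
            rms([])


class TestArCoefficients:
    def test_order1_is_autocorrelation_ratio(self, rng):
        x = rng.normal(size=200)
        xc = x - x.mean()
        r0 = float(np.dot(xc, xc)) / xc.size
        r1 = float(np.dot(xc[:-1], xc[1:])) / xc.size
        got = ar_coefficients(x, order=1)
        assert got[0] == pytest.approx(r1 / r0)

    def test_recovers_ar1_process(self):
        rng = np.random.default_rng(7)
        x = np.zeros(20000)
        for t in range(1, x.size):
            x[t] = 0.8 * x[t - 1] + rng.standard_normal()
        assert ar_coefficients(x, order=1)[0] == pytest.approx(0.8, abs=0.05)

    def test_zero_signal_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning):
            got = ar_coefficients(np.zeros(30), order=4)
        np.testing.assert_array_equal(got, 0.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            ar_coefficients([1.0, 2.0], order=4)


class TestSampleEntropy:
    def test_strict_period_two_is_zero(self):
        x = np.tile([1.0, 2.0], 50)
        assert sample_entropy(x, m=2, r=0.1) == 0.0

    def test_constant_is_zero(self):
        assert sample_entropy(np.ones(40)) == 0.0

    def test_oracle_equivalence_random_windows(self, rng):
        for _ in range(20):
            x = rng.normal(size=40)
            got = sample_entropy(x, m=2, r=0.25)
            want = sampen_oracle(x, m=2, r=0.25)
            assert got == want or got == pytest.approx(want, rel=1e-12)

    def test_oracle_equivalence_varied_m(self, rng):
        for m in (1, 2, 3):
            x = rng.normal(size=30)
            assert sample_entropy(x, m=m, r=0.3) == pytest.approx(
                sampen_oracle(x, m=m, r=0.3), rel=1e-12
            )

    def test_no_extended_matches_is_inf(self):
        # one m-match exists but its extension is broken by opposite spikes
        x = np.array([0.0, 5.0, 0.01, -5.0])
        got = sample_entropy(x, m=1, r=0.05)
        assert got == float("inf")
        assert sampen_oracle(x, m=1, r=0.05) == float("inf")

    def test_too_short(self):
        with pytest.raises(ValueError):
            sample_entropy([1.0, 2.0, 3.0], m=2)


class TestDb7:
    def test_filter_is_orthonormal_qmf(self):
        assert DB7_DEC_LO.sum() == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert (DB7_DEC_LO**2).sum() == pytest.approx(1.0, abs=1e-12)
        for k in range(1, 7):
            shifted = np.dot(DB7_DEC_LO[2 * k :], DB7_DEC_LO[: -2 * k])
            assert shifted == pytest.approx(0.0, abs=1e-12)
        assert DB7_DEC_HI.sum() == pytest.approx(0.0, abs=1e-12)

    def test_high_pass_has_seven_vanishing_moments(self):
        k = np.arange(DB7_DEC_HI.size, dtype=float)
        for p in range(7):
            assert np.dot(DB7_DEC_HI, k**p) == pytest.approx(0.0, abs=1e-7)

    def test_single_level_matches_frozen_reference(self):
        # frozen from an independent wavelet library: db7, mode="zero",
        # detail coefficients of arange(10)
        x = np.arange(10.0)
        detail = np.convolve(x, DB7_DEC_HI, "full")[1::2]
        expected = np.array(
            [-0.07785205408500918, -0.16960961413742814, 0.09297131370286946,
             -0.01992334378284932, -0.00487206529821638, -3.106511531580075,
             -0.42376500542123313, 0.11495587739156958, 0.13481663603475955,
             -0.09478859549334807, 0.01904447673622358]
        )
        np.testing.assert_allclose(detail, expected, atol=1e-12)

    def test_marginals_shape_and_positivity(self, rng):
        out = dwt_detail_marginals(rng.normal(size=52))
        assert out.shape == (3,)
        assert np.all(out >= 0)


class TestFeatureSets:
    def test_td_length(self, random_window):
        vec = extract_feature_set(random_window, "td")
        assert vec.values.shape == (32,)

    def test_enhanced_td_length(self, random_window):
        # 4 TD + RMS + AR(4) = 9 per channel
        vec = extract_feature_set(random_window, "enhanced_td")
        assert vec.values.shape == (72,)

    def test_ninapro_and_sampen_lengths(self, random_window):
        assert extract_feature_set(random_window, "ninapro").values.shape == (64,)
        assert extract_feature_set(random_window, "sampen").values.shape == (24,)

    def test_zero_window_td_is_zero(self):
        w = WindowSample(np.zeros((8, 52)), gesture_label=0)
        np.testing.assert_array_equal(extract_feature_set(w, "td").values, 0.0)

    def test_channel_order_preserved(self, random_window):
        vec = extract_feature_set(random_window, "td")
        ch3 = td_features(random_window.window[3])
        np.testing.assert_allclose(vec.values[12:16], ch3)

    def test_deterministic(self, random_window):
        a = extract_feature_set(random_window, "enhanced_td").values
        b = extract_feature_set(random_window, "enhanced_td").values
        np.testing.assert_array_equal(a, b)

    def test_unknown_set(self, random_window):
        with pytest.raises(ValueError):
            extract_feature_set(random_window, "bogus")

    def test_names_match_lengths(self):
        for name in ("td", "enhanced_td", "ninapro", "sampen"):
            assert len(feature_names(name, 8)) == 8 * features_per_channel(name)


def _blob_features(rng, n=40, sep=10.0):
    feats = []
    for label, centre in enumerate((-sep / 2, sep / 2)):
        for _ in range(n):
            feats.append(
                FeatureVector(
                    values=rng.normal(loc=centre, size=6),
                    set_name="td",
                    gesture_label=label,
                )
            )
    return feats


class TestBaselines:
    @pytest.mark.parametrize("kind", ["lda", "svm"])
    def test_separable_blobs_are_perfect(self, rng, kind):
        feats = _blob_features(rng)
        model = fit_baseline(feats[::2], kind=kind)
        preds = predict(model, feats[1::2])
        truth = [f.gesture_label for f in feats[1::2]]
        assert np.mean(np.asarray(preds) == truth) == 1.0

    def test_permuted_labels_are_chance(self, rng):
        feats = _blob_features(rng, n=150)
        labels = np.array([f.gesture_label for f in feats])
        rng.shuffle(labels)
        shuffled = [
            FeatureVector(values=f.values, set_name="td", gesture_label=int(l))
            for f, l in zip(feats, labels)
        ]
        model = fit_baseline(shuffled[::2], kind="lda")
        preds = predict(model, shuffled[1::2])
        truth = [f.gesture_label for f in shuffled[1::2]]
        acc = float(np.mean(np.asarray(preds) == truth))
        # 150 held-out samples, 2 classes: 3-sigma binomial band around 0.5
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 150)

    def test_fit_beats_chance_control(self, rng):
        feats = _blob_features(rng)
        model = fit_baseline(feats, kind="lda")
        preds = predict(model, feats)
        truth = [f.gesture_label for f in feats]
        assert np.mean(np.asarray(preds) == truth) >= 0.5

    def test_single_class_rejected(self, rng):
        feats = [
            FeatureVector(rng.normal(size=4), "td", gesture_label=0)
            for _ in range(10)
        ]
        with pytest.raises(ValueError):
            fit_baseline(feats)

    def test_csv_export_round_trip(self, rng, tmp_path, random_window):
        feats = [extract_feature_set(random_window, "td") for _ in range(3)]
        path = tmp_path / "features.csv"
        export_features_csv(feats, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split(",")[0] == "gesture_label"
        assert len(lines) == 4
        assert len(lines[1].split(",")) == 33
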