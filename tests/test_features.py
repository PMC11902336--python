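"""Feature extraction against hand computations and brute-force references."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasbls.features import (
    FeatureError,
    GLOBAL_FEATURES,
    SAMPLE_FEATURES,
    approx_entropy,
    ctm,
    detect_desaturations,
    dfa_alpha,
    global_features,
    lz76_complexity,
    perm_entropy,
    sample_entropy,
    sample_features,
)
from sasbls.synth import Recording


# --- brute-force reference implementations ---------------------------------

def sampen_bf(x, m, r):
    n = len(x)

    def count(mm):
        tpl = [x[i:i + mm] for i in range(n - m)]
        return sum(
            1
            for i in range(len(tpl))
            for j in range(len(tpl))
            if i != j and max(abs(a - b) for a, b in zip(tpl[i], tpl[j])) <= r
        )

    b, a = count(m), count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return -math.log(2 / ((n - m - 1) * (n - m)))
    return -math.log(a / b)


def apen_bf(x, m, r):
    n = len(x)

    def phi(mm):
        tpl = [x[i:i + mm] for i in range(n - mm + 1)]
        tot = 0.0
        for i in range(len(tpl)):
            c = sum(
                1 for j in range(len(tpl))
                if max(abs(a - b) for a, b in zip(tpl[i], tpl[j])) <= r
            )
            tot += math.log(c / len(tpl))
        return tot / len(tpl)

    return phi(m) - phi(m + 1)


def permen_bf(x, order, delay):
    from collections import Counter

    patterns = Counter()
    for i in range(len(x) - (order - 1) * delay):
        window = [x[i + k * delay] for k in range(order)]
        patterns[tuple(np.argsort(window, kind="stable"))] += 1
    total = sum(patterns.values())
    h = -sum((c / total) * math.log(c / total) for c in patterns.values())
    return h / math.log(math.factorial(order))


def lz76_ks(bits):
    """Kaspar-Schuster 1987 reference algorithm."""
    ss = "".join("1" if b else "0" for b in bits)
    i, k, l = 0, 1, 1
    c, k_max = 1, 1
    n = len(ss)
    while True:
        if ss[i + k - 1] == ss[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


class TestEntropyOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sampen_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(96, 2, 300)
        r = 0.25 * x.std()
        assert sample_entropy(x, m=1) == pytest.approx(sampen_bf(x, 1, r), abs=1e-10)
        assert sample_entropy(x, m=2, r=r) == pytest.approx(sampen_bf(x, 2, r), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_apen_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(96, 2, 300)
        r = 0.25 * x.std()
        assert approx_entropy(x, m=1) == pytest.approx(apen_bf(x, 1, r), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 4])
    def test_permen_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(0, 1, 300)
        assert perm_entropy(x) == pytest.approx(permen_bf(x, 3, 1), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_lz76_matches_kaspar_schuster(self, seed):
        rng = np.random.default_rng(seed)
        bits = rng.integers(0, 2, int(rng.integers(10, 300)))
        assert lz76_complexity(bits) == lz76_ks(bits)

    def test_dfa_separates_white_and_integrated_noise(self):
        rng = np.random.default_rng(5)
        white = rng.normal(size=4000)
        brown = np.cumsum(white)
        assert 0.35 < dfa_alpha(white) < 0.65
        assert dfa_alpha(brown) > 1.2

    def test_ctm_counts_fraction_inside_radius(self):
        # second differences of [0,0,1,0,0,...] are large -> excluded
        x = np.zeros(100)
        x[50] = 10.0
        assert ctm(x, rho=1.0) < 1.0
        assert ctm(np.linspace(0, 1, 100), rho=1.0) == 1.0


class TestSampleFeatures:
    def test_constant_segment_forced_values(self):
        v = sample_features(np.full(30, 95.0), overnight_mean=95.0)
        d = dict(zip(SAMPLE_FEATURES, v))
        assert d["min"] == d["mean"] == 95.0
        for k in ("std", "range", "min_minus_overnight_mean", "sampen", "permen",
                  "d1_max", "d1_mean", "d1_gt3_frac", "desat_frac",
                  "p_lt95", "p_lt90", "p_lt80"):
            assert d[k] == 0.0, k

    def test_desat_fraction_requires_ten_seconds(self):
        seg = np.full(30, 96.0)
        seg[5:17] = 91.0  # 12 s below 96-3
        v = dict(zip(SAMPLE_FEATURES, sample_features(seg, 96.0)))
        assert v["desat_frac"] == pytest.approx(12 / 30)
        seg2 = np.full(30, 96.0)
        seg2[5:13] = 91.0  # only 8 s: below threshold duration
        v2 = dict(zip(SAMPLE_FEATURES, sample_features(seg2, 96.0)))
        assert v2["desat_frac"] == 0.0

    def test_single_step_derivative(self):
        seg = np.full(30, 97.0)
        seg[15:] = 93.0
        v = dict(zip(SAMPLE_FEATURES, sample_features(seg, 96.0)))
        assert v["d1_max"] == pytest.approx(4.0)
        assert v["d1_gt3_frac"] == pytest.approx(1 / 30)

    def test_nonfinite_rejected(self):
        seg = np.full(30, 97.0)
        seg[3] = np.nan
        with pytest.raises(FeatureError):
            sample_features(seg, 96.0)

    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(-5, 5), seed=st.integers(0, 50))
    def test_translation_consistency(self, shift, seed):
        seg = np.random.default_rng(seed).normal(95, 1.5, 30)
        base = sample_features(seg, 95.0)
        moved = sample_features(seg + shift, 95.0 + shift)
        d0 = dict(zip(SAMPLE_FEATURES, base))
        d1 = dict(zip(SAMPLE_FEATURES, moved))
        assert d1["min"] == pytest.approx(d0["min"] + shift)
        assert d1["mean"] == pytest.approx(d0["mean"] + shift)
        for k in ("std", "range", "min_minus_overnight_mean", "sampen", "permen",
                  "d1_max", "d1_mean", "d1_gt3_frac", "desat_frac"):
            assert d1[k] == pytest.approx(d0[k], abs=1e-9), k


class TestDesaturations:
    def test_flat_signal_no_events(self):
        assert detect_desaturations(np.full(600, 97.0)) == []

    def test_triangular_dip_depth_and_count(self):
        x = np.full(600, 97.0)
        x[100:115] = 97 - np.linspace(0, 5, 15)
        x[115:130] = 92 + np.linspace(0, 5, 15)
        events = detect_desaturations(x)
        assert len(events) == 1
        assert events[0].depth == pytest.approx(5.0, abs=0.5)

    def test_shallow_dip_ignored(self):
        x = np.full(600, 97.0)
        x[100:140] = 94.5  # 2.5 % drop, below the 3 % criterion
        assert detect_desaturations(x, drop_pct=3) == []

    def test_count_is_additive_over_disjoint_halves(self):
        rng = np.random.default_rng(8)
        x = np.full(1200, 97.0)
        for start in (100, 400, 800, 1000):
            x[start:start + 20] = 92.0
        full = len(detect_desaturations(x))
        halves = len(detect_desaturations(x[:600])) + len(detect_desaturations(x[600:]))
        assert full == halves == 4


def _night(signal):
    n_ep = len(signal) // 30
    return Recording(spo2=np.asarray(signal, dtype=float), fs=1.0,
                     hypnogram=["N2"] * n_ep, events=[],
                     demographics=(60.0, 28.0, 1, 0), ahi_label=0.0,
                     subject_id="G")


class TestGlobalFeatures:
    def test_constant_night_forced_values(self):
        g = global_features(_night(np.full(3600, 97.0)))
        assert g["std"] == 0 and g["spo2_range"] == 0 and g["zc"] == 0
        assert g["odi3"] == 0 and g["ct90"] == 0 and g["prsa_c"] == 0
        assert g["apen"] == 0 and g["sampen"] == 0

    def test_odi_counts_injected_desats(self):
        x = np.full(3600, 97.0)
        for k in range(8):
            s = 200 + 400 * k
            x[s:s + 20] = 92.0
        g = global_features(_night(x))
        assert g["odi3"] == pytest.approx(8.0)

    def test_psd_band_bounded_by_total(self):
        rng = np.random.default_rng(4)
        x = 96 + rng.normal(0, 1, 7200)
        g = global_features(_night(x))
        assert 0 <= g["psd_band"] <= g["psd_total"] * (1 + 1e-9)
        assert 0 <= g["psd_ratio"] <= 1

    def test_registry_complete_and_finite(self, clean_subject):
        from sasbls.preprocess import preprocess_recording

        _, clean = preprocess_recording(clean_subject)
        g = global_features(clean)
        assert list(g.index) == GLOBAL_FEATURES
        assert np.all(np.isfinite(g.to_numpy()))
        assert 0 <= g["pod"] <= 1 and 0 <= g["ct90"] <= 1

    def test_too_short_rejected(self):
        with pytest.raises(FeatureError):
            global_features(_night(np.full(100, 97.0)))
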