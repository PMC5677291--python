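"""HRV feature correctness: hand-derived values, oracles, identities."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stresskit.hrv import (HRV_FEATURES, approximate_entropy, ar_psd,
                           band_powers, burg_ar, hrv_features, nn_tachogram,
                           poincare, sample_entropy, time_domain)
from stresskit.signals import NNSeries


# -- independent brute-force entropy oracles (double loop, no vectorization)

def apen_bruteforce(x, m, r):
    x = np.asarray(x, float)
    n = len(x)

    def phi(mm):
        tpl = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in tpl:
            c = sum(1 for b in tpl if np.max(np.abs(a - b)) <= r)
            total += np.log(c / len(tpl))
        return total / len(tpl)

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r):
    x = np.asarray(x, float)
    n = len(x)
    tm = [x[i:i + m] for i in range(n - m)]
    tm1 = [x[i:i + m + 1] for i in range(n - m)]
    a_cnt = b_cnt = 0
    for i in range(len(tm)):
        for j in range(i + 1, len(tm)):
            if np.max(np.abs(tm[i] - tm[j])) <= r:
                b_cnt += 1
            if np.max(np.abs(tm1[i] - tm1[j])) <= r:
                a_cnt += 1
    if a_cnt == 0 or b_cnt == 0:
        return np.nan
    return -np.log(a_cnt / b_cnt)


class TestTimeDomain:
    def test_constant_nn(self):
        f = time_domain(np.array([1000.0, 1000.0, 1000.0]))
        assert f["HRavg"] == pytest.approx(60.0)
        assert f["SDNN"] == 0.0 and f["RMSSD"] == 0.0
        assert f["pNN20"] == 0.0 and f["pNN50"] == 0.0

    def test_hand_counted_pnn(self):
        # diffs [60, -5, 65]: two exceed 20 ms and two exceed 50 ms, out
        # of 4 NN intervals under the intervals-denominator convention
        f = time_domain(np.array([800.0, 860.0, 855.0, 920.0]))
        assert f["pNN50"] == pytest.approx(0.5)
        assert f["pNN20"] == pytest.approx(0.5)

    def test_pairs_denominator_variant(self):
        f = time_domain(np.array([800.0, 860.0, 855.0, 920.0]),
                        pnn_denominator="pairs")
        assert f["pNN50"] == pytest.approx(2 / 3)

    def test_rmssd_formula(self):
        f = time_domain(np.array([800.0, 860.0, 855.0, 920.0]))
        expected = np.sqrt((60.0 ** 2 + 5.0 ** 2 + 65.0 ** 2) / 3.0)
        assert f["RMSSD"] == pytest.approx(expected)

    @given(hnp.arrays(float, st.integers(4, 40),
                      elements=st.floats(400.0, 1500.0)))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_pnn20_dominates_pnn50(self, nn):
        f = time_domain(nn)
        assert f["pNN20"] >= f["pNN50"]


class TestTachogramAndSpectrum:
    def _nns(self, nn_ms):
        peaks = np.concatenate([[0.0], np.cumsum(nn_ms) / 1000.0])
        return NNSeries(peaks)

    def test_constant_tachogram(self):
        t, v = nn_tachogram(self._nns([1000.0] * 10))
        np.testing.assert_allclose(v, 1000.0)

    def test_linear_tachogram(self):
        # construct beat times so the anchored NN value is exactly
        # linear in time: nn(t) = 800 + 5 t; cubic splines reproduce
        # polynomials of degree <= 3, so the tachogram must be linear
        times = [0.0]
        for _ in range(12):
            times.append((times[-1] + 0.8) / (1.0 - 0.005))
        t, v = nn_tachogram(NNSeries(np.array(times)))
        np.testing.assert_allclose(v, 800.0 + 5.0 * t, atol=1e-8)

    def test_respiratory_modulation_lands_in_hf(self):
        rng = np.random.default_rng(0)
        t = 0.0
        nn = []
        for _ in range(300):
            v = 1000.0 + 80.0 * np.sin(2 * np.pi * 0.25 * t)
            nn.append(v + rng.normal(0, 2))
            t += v / 1000.0
        tach = nn_tachogram(self._nns(nn))
        f, p = ar_psd(tach, order=16)
        peak_f = f[np.argmax(p)]
        assert 0.15 <= peak_f <= 0.4

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4096)
        f, p = ar_psd((np.arange(4096) / 4.0, x), order=2)
        band = (f >= 0.04) & (f <= 0.4)
        assert p[band].max() / p[band].min() < 3.0

    def test_sinusoid_peak_location(self):
        t = np.arange(1024) / 4.0
        f, p = ar_psd((t, np.sin(2 * np.pi * 0.25 * t)), order=16)
        assert abs(f[np.argmax(p)] - 0.25) < 0.02

    def test_zero_variance_gives_negligible_psd(self):
        f, p = ar_psd((np.arange(64) / 4.0, np.full(64, 900.0)), order=8)
        assert np.all(p >= 0) and p.max() < 1e-12

    def test_burg_total_power_tracks_variance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2048)
        f, p = ar_psd((np.arange(x.size) / 4.0, x), order=12)
        total = np.trapezoid(p, f)
        assert abs(total - x.var()) / x.var() < 0.2

    def test_burg_recovers_ar2_coefficients(self):
        rng = np.random.default_rng(4)
        n = 20000
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for i in range(2, n):
            x[i] = 0.5 * x[i - 1] - 0.3 * x[i - 2] + e[i]
        a, _ = burg_ar(x[1000:], 2)
        np.testing.assert_allclose(a, [1.0, -0.5, 0.3], atol=0.02)


class TestBandPowers:
    def test_flat_psd_analytic_integral(self):
        f = np.linspace(0.0, 0.5, 2001)
        out = band_powers((f, np.ones_like(f)))
        assert out["LFnormal"] == pytest.approx(0.11 / 0.36, abs=1e-3)
        assert out["HFnormal"] == pytest.approx(0.25 / 0.36, abs=1e-3)

    def test_all_power_in_hf(self):
        f = np.linspace(0.0, 0.5, 2001)
        p = np.where((f > 0.2) & (f < 0.3), 1.0, 0.0)
        out = band_powers((f, p))
        assert out["LFnormal"] == pytest.approx(0.0, abs=1e-9)
        assert out["HFnormal"] == pytest.approx(1.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_normalization_identity(self, seed):
        rng = np.random.default_rng(seed)
        f = np.linspace(0.0, 0.5, 501)
        p = rng.uniform(0.1, 2.0, f.size)
        out = band_powers((f, p))
        assert out["LFnormal"] + out["HFnormal"] == pytest.approx(1.0)

    def test_dc_shift_invariance(self):
        """Adding a constant to the tachogram leaves band powers alone."""
        rng = np.random.default_rng(5)
        t = np.arange(256) / 4.0
        v = 900.0 + 30.0 * rng.standard_normal(t.size)
        a = band_powers(ar_psd((t, v), order=8))
        b = band_powers(ar_psd((t, v + 500.0), order=8))
        assert a["LFnormal"] == pytest.approx(b["LFnormal"], abs=1e-9)


class TestEntropies:
    def test_constant_series_perfectly_regular(self):
        x = np.full(30, 5.0)
        assert approximate_entropy(x) == 0.0
        assert sample_entropy(x) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            n = int(rng.integers(8, 51))
            x = rng.standard_normal(n)
            r = 0.2 * np.std(x, ddof=1)
            assert approximate_entropy(x, 2, r) == pytest.approx(
                apen_bruteforce(x, 2, r), abs=1e-12)
            sb = sampen_bruteforce(x, 2, r)
            sv = sample_entropy(x, 2, r)
            if np.isnan(sb):
                assert np.isnan(sv)
            else:
                assert sv == pytest.approx(sb, abs=1e-12)

    def test_random_exceeds_periodic_sampen(self):
        rng = np.random.default_rng(11)
        noise = rng.uniform(0, 1, 200)
        sine = np.sin(2 * np.pi * np.arange(200) / 25.0)
        s_noise = sample_entropy(noise, 2, 0.2 * np.std(noise, ddof=1))
        s_sine = sample_entropy(sine, 2, 0.2 * np.std(sine, ddof=1))
        assert s_noise > s_sine


class TestPoincare:
    def test_constant_series(self):
        out = poincare(np.full(10, 800.0))
        assert out["SD1"] == 0.0 and out["SD2"] == 0.0
        assert np.isnan(out["SD1_SD2"])

    def test_sd1_is_sdsd_over_sqrt2(self):
        rng = np.random.default_rng(12)
        nn = 900.0 + 40.0 * rng.standard_normal(200)
        out = poincare(nn)
        sdsd = np.std(np.diff(nn), ddof=1)
        assert out["SD1"] ** 2 == pytest.approx(sdsd ** 2 / 2.0, rel=1e-9)

    def test_variance_partition_population_convention(self):
        rng = np.random.default_rng(13)
        nn = 900.0 + 40.0 * rng.standard_normal(500)
        x1, x2 = nn[:-1], nn[1:]
        sd1 = np.std((x2 - x1) / np.sqrt(2))
        sd2 = np.std((x2 + x1) / np.sqrt(2))
        var_pairs = np.std(x1) ** 2 + np.std(x2) ** 2
        assert sd1 ** 2 + sd2 ** 2 == pytest.approx(var_pairs, rel=1e-9)


class TestFeatureAssembly:
    def test_full_vector_on_healthy_epoch(self):
        rng = np.random.default_rng(14)
        nn = 850.0 + 35.0 * rng.standard_normal(40)
        peaks = np.concatenate([[0.0], np.cumsum(nn) / 1000.0])
        out = hrv_features(NNSeries(peaks))
        assert set(out) == set(HRV_FEATURES)
        finite = {k: v for k, v in out.items() if not np.isnan(v)}
        assert len(finite) >= 13  # entropy can be undefined on occasion

    def test_missing_marker_on_degenerate_input(self):
        out = hrv_features(None)
        assert all(np.isnan(v) for v in out.values())
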