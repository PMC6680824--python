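import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smburst as sb
from smburst.bursts import BurstSearchParams, BurstSelectionParams


def brute_force_search(times_s, m, F, bg_khz):
    """Exhaustive enumeration of all qualifying m-windows (independent oracle)."""
    t = np.asarray(times_s, float)
    n = len(t)
    member = np.zeros(n, bool)
    for i in range(n - m + 1):
        dt = t[i + m - 1] - t[i]
        rate_hz = np.inf if dt == 0 else m / dt
        if rate_hz >= F * bg_khz * 1e3:
            member[i : i + m] = True
    runs = []
    start = None
    for j in range(n):
        if member[j] and start is None:
            start = j
        elif not member[j] and start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))
    return runs


def random_stream(rng, n_max=500):
    """Background Poisson with occasional dense clusters, <= n_max photons."""
    t_bg = np.cumsum(rng.exponential(1 / 2300.0, size=rng.integers(50, 300)))
    parts = [t_bg]
    for _ in range(rng.integers(0, 6)):
        t0 = rng.uniform(0, t_bg[-1])
        parts.append(t0 + np.cumsum(rng.exponential(1 / 50e3, size=rng.integers(5, 60))))
    t = np.sort(np.concatenate(parts))
    return t[:n_max]


class TestBgEstimator:
    def test_pure_poisson_within_5_percent(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.exponential(1 / 2300.0, size=int(2300 * 30)))
        est = sb.estimate_bg_rate(t)
        assert abs(est - 2.3) / 2.3 < 0.05

    def test_uniform_falls_back_to_total_rate(self):
        t = np.linspace(0.0, 10.0, 1001)
        with pytest.warns(UserWarning, match="falling back"):
            est = sb.estimate_bg_rate(t)
        assert est == pytest.approx(len(t) / 10.0 / 1e3)

    def test_bursty_mixture_estimator_beats_total_rate(self):
        rng = np.random.default_rng(1)
        bg = np.cumsum(rng.exponential(1 / 2300.0, size=int(2300 * 20)))
        bursts = [
            t0 + np.cumsum(rng.exponential(1 / 100e3, size=80))
            for t0 in rng.uniform(0, bg[-1], size=40)
        ]
        t = np.sort(np.concatenate([bg] + bursts))
        est = sb.estimate_bg_rate(t)
        total = len(t) / (t[-1] - t[0]) / 1e3
        assert abs(est - 2.3) < abs(total - 2.3)
        assert abs(est - 2.3) / 2.3 < 0.10

    def test_too_few_photons_rejected(self):
        with pytest.raises(ValueError):
            sb.estimate_bg_rate(np.linspace(0, 1, 50))


class TestSlidingWindowSearch:
    def test_matches_brute_force_on_handcrafted_stream(self):
        t = np.array([0.0, 1e-5, 2e-5, 3e-5, 1.0, 1.000005, 1.00001, 1.000015,
                      1.00002, 2.0, 3.0, 4.0])
        params = BurstSearchParams(m=3, F=6.0)
        found = sb.sliding_window_search(t, params, bg_rate_khz=1.0)
        expected = brute_force_search(t, 3, 6.0, 1.0)
        assert [(b.first, b.last) for b in found] == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        t = random_stream(rng)
        m = int(rng.integers(2, 12))
        F = float(rng.uniform(2, 25))
        found = sb.sliding_window_search(t, BurstSearchParams(m=m, F=F), 2.3)
        assert [(b.first, b.last) for b in found] == brute_force_search(t, m, F, 2.3)

    def test_globally_super_threshold_single_burst(self):
        # all window rates exactly 2*F*bg: one burst holding every photon
        m, F, bg = 5, 6.0, 1.0
        gap = 1.0 / (2 * F * bg * 1e3) * m / (m - 1) * (m - 1) / m  # = m/(2F·bg·1e3)/m
        t = np.arange(200) * (m / (2 * F * bg * 1e3) / m)
        found = sb.sliding_window_search(t, BurstSearchParams(m=m, F=F), bg)
        assert len(found) == 1
        assert (found[0].first, found[0].last) == (0, 199)

    def test_pure_background_rarely_yields_bursts(self):
        # false-positive rate: ~23000 windows/10 s, per-window tail probability
        # P(Gamma(9) <= 10/F) gives ~1.4 expected hits at F=6 but only ~0.01
        # at F=11, so a pure background stream almost never bursts at F=11
        n_with_bursts = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = np.cumsum(rng.exponential(1 / 2300.0, size=int(2300 * 10)))
            found = sb.sliding_window_search(t, BurstSearchParams(m=10, F=11.0), 2.3)
            n_with_bursts += bool(found)
        assert n_with_bursts == 0

    def test_zero_width_window_qualifies(self):
        t = np.array([0.0, 1.0, 1.0, 1.0, 2.0])
        found = sb.sliding_window_search(t, BurstSearchParams(m=3, F=1e6), 2.3)
        assert len(found) == 1
        assert (found[0].first, found[0].last) == (1, 3)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            sb.sliding_window_search(np.array([1.0, 0.5]), BurstSearchParams(2, 6), 2.3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_f_never_adds_photons(self, seed):
        rng = np.random.default_rng(seed)
        t = random_stream(rng)

        def photon_set(F):
            found = sb.sliding_window_search(t, BurstSearchParams(m=5, F=F), 2.3)
            return set().union(*[range(b.first, b.last + 1) for b in found]) if found else set()

        low, high = photon_set(6.0), photon_set(11.0)
        assert high <= low


class TestSelection:
    def _bursts(self):
        rng = np.random.default_rng(2)
        t = random_stream(rng)
        return sb.sliding_window_search(t, BurstSearchParams(m=10, F=6.0), 2.3)

    def test_sz_equal_m_identity(self):
        bursts = self._bursts()
        sel = sb.select_bursts(bursts, BurstSelectionParams(min_size=10, min_width_ms=0.0))
        assert sel == bursts

    def test_zero_width_threshold_identity(self):
        bursts = self._bursts()
        sel = sb.select_bursts(bursts, BurstSelectionParams(min_size=10, min_width_ms=0.0))
        assert len(sel) == len(bursts)

    def test_oversized_threshold_empties(self):
        bursts = self._bursts()
        top = max(b.size for b in bursts)
        sel = sb.select_bursts(bursts, BurstSelectionParams(min_size=top + 1))
        assert sel == []

    def test_raising_thresholds_never_adds_bursts(self):
        bursts = self._bursts()
        n_prev = len(bursts)
        for sz in (10, 20, 40, 80):
            n = len(sb.select_bursts(bursts, BurstSelectionParams(min_size=sz)))
            assert n <= n_prev
            n_prev = n


class TestMetrics:
    def test_two_photon_burst_width(self):
        t = np.array([0.0, 1e-3])
        found = sb.sliding_window_search(t, BurstSearchParams(m=2, F=1.0), 2.0)
        assert len(found) == 1
        assert found[0].width_s == pytest.approx(1e-3)

    def test_mean_and_se_match_direct_recomputation(self):
        rng = np.random.default_rng(3)
        t = random_stream(rng)
        bursts = sb.sliding_window_search(t, BurstSearchParams(m=3, F=4.0), 2.3)
        assert len(bursts) >= 2
        metrics = sb.burst_metrics(bursts)
        widths = np.array([b.times_s[-1] - b.times_s[0] for b in bursts])
        assert metrics["mean_width_s"] == pytest.approx(widths.mean())
        assert metrics["mean_width_se_s"] == pytest.approx(
            widths.std(ddof=1) / np.sqrt(len(widths))
        )

    def test_empty_set_sentinel(self):
        metrics = sb.burst_metrics([])
        assert metrics["n_bursts"] == 0
        assert np.isnan(metrics["mean_width_s"])
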