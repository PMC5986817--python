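"""Signal detection: baseline, robust sigma, hysteresis extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tunnelcall as tc
from tunnelcall.errors import DegenerateNoiseError, InputError
from tunnelcall.signal_detect import (NoiseEstimate, detect_signals,
                                      estimate_baseline, estimate_sigma)


def brute_moving_average(x, window):
    half_lo = window // 2
    half_hi = window - half_lo
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        lo, hi = max(0, i - half_lo), min(x.size, i + half_hi)
        out[i] = x[lo:hi].mean()
    return out


def brute_detect(c, sigma, rise=6.0, fall=1.0, min_samples=5):
    """Independent sample-by-sample replay of the rise/fall automaton."""
    segs, i, n = [], 0, c.size
    while i < n:
        if c[i] > rise * sigma:
            j = i
            while j > 0 and c[j - 1] > fall * sigma:
                j -= 1
            k = i + 1
            while k < n and c[k] >= fall * sigma:
                k += 1
            if segs and j <= segs[-1][1]:
                segs[-1] = (segs[-1][0], max(segs[-1][1], k))
            else:
                segs.append((j, k))
            i = k
        else:
            i += 1
    return [(a, b) for a, b in segs if b - a >= min_samples]


class TestBaseline:
    def test_constant_trace(self):
        x = np.full(5000, 17.0)
        assert np.allclose(estimate_baseline(x, 2000), 17.0)

    def test_window_validation(self):
        with pytest.raises(InputError):
            estimate_baseline(np.zeros(10), 0)

    def test_gaussian_noise_within_sem_bound(self):
        rng = np.random.default_rng(0)
        s = 4.0
        x = rng.normal(0.0, s, 20_000)
        b = estimate_baseline(x, 2000)
        # interior estimates average 2000 points; allow 5 standard errors
        interior = b[1000:-1000]
        assert np.abs(interior).max() <= 5 * s / np.sqrt(2000)

    @pytest.mark.parametrize("window", [4, 20, 200])
    def test_matches_brute_force(self, window):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 999)
        assert np.allclose(estimate_baseline(x, window),
                           brute_moving_average(x, window))

    def test_step_transition_spans_one_window(self):
        x = np.concatenate([np.zeros(6000), np.full(6000, 100.0)])
        w = 2000
        b = estimate_baseline(x, w)
        assert np.allclose(b[: 6000 - w], 0.0)
        assert np.allclose(b[6000 + w:], 100.0)
        ramp = b[6000 - w: 6000 + w]
        assert np.all(np.diff(ramp) >= -1e-9)


class TestSigma:
    def test_pure_gaussian_noise_band(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 4.0, 100_000)  # 10 s at 10 kHz
        noise = estimate_sigma(x, np.zeros_like(x), sample_rate_hz=10_000)
        assert noise.sigmas.size == 10
        assert np.all(noise.sigmas > 3.2) and np.all(noise.sigmas < 4.8)

    def test_mode_robust_to_rare_spikes(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 4.0, 10_000)
        clean = estimate_sigma(x, np.zeros_like(x), sample_rate_hz=10_000)
        spiky = x.copy()
        # contaminate < 2% of the 500 windows with tall spikes
        for w in range(0, 9, 1):
            spiky[w * 1000] += 300.0
        est = estimate_sigma(spiky, np.zeros_like(x), sample_rate_hz=10_000)
        assert abs(est.sigmas[0] - clean.sigmas[0]) <= 0.1 * clean.sigmas[0]

    def test_constant_trace_degenerates_downstream(self):
        x = np.full(10_000, 5.0)
        noise = estimate_sigma(x, np.full_like(x, 5.0), sample_rate_hz=10_000)
        assert np.all(noise.sigmas == 0.0)
        with pytest.raises(DegenerateNoiseError):
            detect_signals(x, np.full_like(x, 5.0), noise,
                           sample_rate_hz=10_000)

    def test_short_first_block_is_error(self):
        with pytest.raises(InputError):
            estimate_sigma(np.zeros(10), np.zeros(10), sample_rate_hz=10_000)


class TestDetect:
    def test_noise_free_event_boundaries_exact(self):
        x = np.zeros(2000)
        x[1000:1010] = 102.0
        noise = NoiseEstimate(np.array([2.0]), 10_000)
        segs = detect_signals(x, np.zeros_like(x), noise, sample_rate_hz=10_000)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (1000, 1010)
        assert segs[0].sigma_ps == 2.0

    def test_pure_noise_yields_no_segments(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 4.0, 100_000)
        base = estimate_baseline(x, 2000)
        noise = estimate_sigma(x, base, sample_rate_hz=10_000)
        segs = detect_signals(x, base, noise, sample_rate_hz=10_000)
        assert len(segs) == 0

    def test_recall_on_simulated_events(self, let7a_run):
        trace, segs = let7a_run["trace"], let7a_run["segments"]
        hits = 0
        spurious = 0
        events = trace.events
        starts = np.array([e.start for e in events])
        ends = np.array([e.end for e in events])
        matched = set()
        for s in segs:
            overlap = np.flatnonzero((s.start < ends) & (starts < s.end))
            if overlap.size:
                matched.update(overlap.tolist())
            else:
                spurious += 1
        assert len(matched) >= 0.95 * len(events)
        assert spurious <= 2

    def test_raising_threshold_never_increases_count(self, let7a_run):
        trace = let7a_run["trace"]
        base, noise = let7a_run["baseline"], let7a_run["noise"]
        n6 = len(detect_signals(trace, base, noise, rise_sigma=6.0))
        n7 = len(detect_signals(trace, base, noise, rise_sigma=7.0))
        assert n7 <= n6

    def test_segments_disjoint_and_sorted(self, let7a_run):
        segs = let7a_run["segments"]
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start

    @given(st.lists(st.floats(-5, 150, allow_nan=False), min_size=20,
                    max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_automaton(self, values):
        x = np.asarray(values)
        noise = NoiseEstimate(np.array([4.0]), 10_000)
        segs = detect_signals(x, np.zeros_like(x), noise,
                              sample_rate_hz=10_000)
        assert [(s.start, s.end) for s in segs] == brute_detect(x, 4.0)
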