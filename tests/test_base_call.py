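"""Base calling: smoothing, histogram mixture fit, interval calls,
fragment formation."""

import numpy as np
import pytest

import tunnelcall as tc
from tunnelcall.base_call import (BASELINE_LABEL, call_intervals,
                                  calls_to_fragment, fit_conductance_model,
                                  smooth_segment)
from tunnelcall.errors import FittingError
from tunnelcall.signal_detect import SignalSegment


def brute_median_filter(x, half=2):
    return np.array([np.median(x[max(0, i - half): i + half + 1])
                     for i in range(len(x))])


def seg_from(samples):
    x = np.asarray(samples, float)
    return SignalSegment(0, x.size, 0.0, 4.0, x)


class TestSmoothing:
    def test_single_sample_spike_removed(self):
        x = np.full(20, 77.0)
        x[10] = 300.0
        out = smooth_segment(seg_from(x))
        assert np.allclose(out.samples, 77.0)

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(0)
        x = rng.normal(70, 10, 57)
        out = smooth_segment(seg_from(x))
        assert np.allclose(out.samples, brute_median_filter(x))

    def test_alternating_bursts_suppressed(self):
        x = np.tile([45.0, 45.0, 102.0, 102.0], 6)
        out = smooth_segment(seg_from(x)).samples
        # no plateau of >= 3 samples attains either extreme level
        for level in (45.0, 102.0):
            runs = np.flatnonzero(np.isclose(out, level))
            longest = 0
            cur = 0
            prev = None
            for r in runs:
                cur = cur + 1 if prev is not None and r == prev + 1 else 1
                longest = max(longest, cur)
                prev = r
            assert longest < 5

    def test_smooth_ramp_nearly_unchanged(self):
        x = np.linspace(40, 110, 50)
        out = smooth_segment(seg_from(x)).samples
        assert np.allclose(out[2:-2], x[2:-2])


class TestFit:
    def test_recovers_default_peaks_within_5pct(self, let7a_run):
        means = let7a_run["fit"].base_means
        for got, true in zip(means, (45.0, 77.0, 102.0)):
            assert abs(got - true) <= 0.05 * true

    def test_two_delta_peaks_single_base(self):
        rng = np.random.default_rng(1)
        samples = np.concatenate([
            rng.normal(5.0, 1.0, 3000),    # baseline-like
            rng.normal(60.0, 1.0, 3000),
        ])
        fit = fit_conductance_model([seg_from(samples)], n_bases=1,
                                    labels_by_rank=("G",), smooth=False)
        assert abs(fit.means[0] - 5.0) < 1.0
        assert abs(fit.means[1] - 60.0) < 1.0

    def test_component_areas_track_known_weights(self):
        rng = np.random.default_rng(2)
        n = 30_000
        parts = [rng.normal(45, 5, int(0.2 * n)),
                 rng.normal(77, 5, int(0.3 * n)),
                 rng.normal(102, 5, int(0.5 * n))]
        fit = fit_conductance_model([seg_from(np.concatenate(parts))],
                                    smooth=False)
        areas = fit.areas[1:]  # skip baseline component
        fractions = areas / areas.sum()
        for got, true in zip(fractions, (0.2, 0.3, 0.5)):
            assert abs(got - true) <= 0.1 * true + 0.02

    def test_insufficient_data_raises(self):
        with pytest.raises(FittingError):
            fit_conductance_model([seg_from(np.full(50, 60.0))])

    def test_least_squares_agrees_with_em(self, let7a_run):
        """Histogram least squares vs expectation-maximization on samples."""
        from sklearn.mixture import GaussianMixture
        pooled = np.concatenate([
            smooth_segment(s).samples for s in let7a_run["segments"]
        ])
        gm = GaussianMixture(4, random_state=0,
                             means_init=[[5], [45], [77], [102]])
        gm.fit(pooled.reshape(-1, 1))
        em_means = np.sort(gm.means_.ravel())[1:]
        ls_means = let7a_run["fit"].base_means
        assert np.all(np.abs(em_means - ls_means) / ls_means < 0.02)


class TestCallIntervals:
    def test_pure_guanine_interval(self, default_cmodel):
        calls = call_intervals(seg_from([102.0] * 5), default_cmodel)
        assert len(calls) == 1
        assert calls[0].label == "G"
        assert calls[0].posteriors["G"] > 0.99

    def test_equidistant_tie_breaks_low_and_flags(self, default_cmodel):
        calls = call_intervals(seg_from([61.0] * 5), default_cmodel)
        c = calls[0]
        assert abs(c.posteriors["T"] - c.posteriors["A"]) < 1e-6
        assert c.label == "T"
        assert c.low_confidence

    def test_posteriors_normalized(self, default_cmodel):
        calls = call_intervals(seg_from([45.0] * 12 + [102.0] * 13),
                               default_cmodel)
        for c in calls:
            assert sum(c.posteriors.values()) == pytest.approx(1.0, abs=1e-9)

    def test_interval_accuracy_against_truth(self, let7a_run, default_cmodel):
        """Non-baseline interval labels match the underlying base >= 90%."""
        trace = let7a_run["trace"]
        fit = let7a_run["fit"]
        good = total = 0
        for seg in let7a_run["segments"][:300]:
            sm = smooth_segment(seg)
            for c in call_intervals(sm, fit.model):
                if c.label == BASELINE_LABEL:
                    continue
                mid = seg.start + int((c.start_ms + c.duration_ms / 2) * 10)
                idx = trace.base_index[min(mid, len(trace) - 1)]
                if idx < 1:
                    continue
                total += 1
                good += tc.LET7A[idx - 1] == c.label
        assert total > 500
        assert good / total >= 0.90


class TestAlphabetExtension:
    def test_fourth_base_component_leaves_calls_unchanged(self, default_cmodel):
        """A cytosine component with negligible weight does not perturb
        T/A/G calls on three-letter data."""
        import tunnelcall as tc
        extended = tc.ConductanceModel(
            means={"T": 45.0, "A": 77.0, "G": 102.0, "C": 130.0},
            sds={"T": 8.0, "A": 8.0, "G": 8.0, "C": 8.0})
        rng = np.random.default_rng(5)
        for level in (45.0, 77.0, 102.0):
            x = rng.normal(level, 4.0, 25)
            base = call_intervals(seg_from(x), default_cmodel)
            ext = call_intervals(seg_from(x), extended)
            assert [c.label for c in base] == [c.label for c in ext]


class TestCallsToFragment:
    def _mk_calls(self, spec, cmodel):
        """spec: list of (label, duration_ms)."""
        out = []
        t = 0.0
        for label, dur in spec:
            out.append(tc.IntervalCall(
                start_ms=t, duration_ms=dur, label=label,
                posteriors={"T": 0.0, "A": 0.0, "G": 0.0,
                            BASELINE_LABEL: 0.0} | {label: 1.0},
                mean_conductance_ps=cmodel.means.get(label, 0.0),
            ))
            t += dur
        return out

    def test_run_splitting_arithmetic(self, default_cmodel):
        # a 1.0-ms G run at nominal dwell 2/3 ms stays one letter ...
        calls = self._mk_calls([("G", 0.5), ("G", 0.5), ("A", 0.5)],
                               default_cmodel)
        frag = calls_to_fragment(calls, default_cmodel)
        assert frag.sequence == "GA"
        # ... but a 1.34-ms run splits into two
        calls = self._mk_calls([("G", 0.67), ("G", 0.67), ("A", 0.5)],
                               default_cmodel)
        frag = calls_to_fragment(calls, default_cmodel)
        assert frag.sequence == "GGA"

    def test_single_run_single_letter(self, default_cmodel):
        calls = self._mk_calls([("T", 0.5)], default_cmodel)
        frag = calls_to_fragment(calls, default_cmodel)
        assert frag.sequence == "T"
        assert frag.norm_conductances[0] == pytest.approx(45 / 102)

    def test_all_baseline_returns_none(self, default_cmodel):
        calls = self._mk_calls([(BASELINE_LABEL, 0.5)] * 4, default_cmodel)
        assert calls_to_fragment(calls, default_cmodel) is None

    def test_letter_times_strictly_increasing(self, let7a_run):
        for f in let7a_run["fragments"]:
            assert all(b > a for a, b in zip(f.times_ms, f.times_ms[1:]))

    def test_most_fragments_are_contiguous_reads(self, let7a_run):
        """At default noise, most events decode to a contiguous (possibly
        reversed/folded) read of the true sequence."""
        ok = 0
        frags = let7a_run["fragments"]
        for f in frags:
            s = tc.unfold_palindrome(f.sequence)
            ok += (s in tc.LET7A) or (s in tc.LET7A[::-1])
        assert ok / len(frags) >= 0.80
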