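"""Trace simulator: translocation paths, rendering, mixtures."""

import numpy as np
import pytest

import tunnelcall as tc
from tunnelcall.errors import InputError
from tunnelcall.trace_sim import (ConductanceModel, TranslocationModel,
                                  simulate_mixture, simulate_path,
                                  render_trace, simulate_trace)


class TestModels:
    def test_conductance_model_orders_means(self):
        with pytest.raises(InputError):
            ConductanceModel(means={"T": 90.0, "A": 77.0, "G": 102.0})

    def test_means_must_exceed_baseline(self):
        with pytest.raises(InputError):
            ConductanceModel(baseline_mean=50.0)

    def test_translocation_model_validation(self):
        with pytest.raises(InputError):
            TranslocationModel(min_dwell_ms=1.0, mean_dwell_ms=0.5)
        with pytest.raises(InputError):
            TranslocationModel(reversal_prob=1.0)

    def test_normalized_levels(self, default_cmodel):
        norm = default_cmodel.normalized()
        assert norm["G"] == 1.0
        assert norm["A"] == pytest.approx(77 / 102)
        assert norm["T"] == pytest.approx(45 / 102)


class TestSimulatePath:
    def test_no_reversal_is_monotone(self):
        model = TranslocationModel(reversal_prob=0.0, entry_3prime_prob=0.0,
                                   read_length_p=1e-9, max_read_length=3)
        # at vanishing p the truncated geometric is uniform on 1..3; the
        # chosen seed draws the full length so the walk must be 1,2,3
        path = simulate_path("TGA", model, seed=4)
        assert path.indices == [1, 2, 3]
        assert path.entry_end == "5p"

    def test_rejects_bad_sequence(self, default_tmodel):
        with pytest.raises(InputError):
            simulate_path("", default_tmodel, seed=0)
        with pytest.raises(InputError):
            simulate_path("TGAC", default_tmodel, seed=0)

    def test_adjacent_stepping_invariant(self, default_tmodel):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = simulate_path(tc.LET7A, default_tmodel, rng)
            steps = np.diff(p.indices)
            assert np.all(np.abs(steps) == 1)
            assert min(p.dwells_ms) >= default_tmodel.min_dwell_ms
            assert p.read_length <= default_tmodel.max_read_length

    def test_first_continuation_move_flips_with_rate_q(self):
        """The direction of the second move flips with probability q.

        Conditioning must not depend on the flip itself: a path takes a
        second move whenever its target length is >= 3 and the position
        after move one is interior — both decided before the flip draw —
        so among such paths the observed direction change at move two is
        exactly a Bernoulli(q) sample. (Marginal reversal fractions are
        censored by the stopping rule: a reversed move revisits a base
        and cannot complete the drawn read length, so closed forms that
        ignore stopping do not hold.)
        """
        q = 0.3
        model = TranslocationModel(reversal_prob=q)
        rng = np.random.default_rng(7)
        flips = trials = 0
        for _ in range(10_000):
            p = simulate_path(tc.LET7A, model, rng)
            idx = p.indices
            if len(idx) < 3:
                continue
            if idx[1] in (1, len(tc.LET7A)):
                continue  # a boundary would censor one flip outcome
            trials += 1
            flips += (idx[2] - idx[1]) != (idx[1] - idx[0])
        assert trials > 2000
        sigma = np.sqrt(trials * q * (1 - q))
        assert abs(flips - q * trials) < 3 * sigma

    def test_mean_dwell_matches_parameter(self, default_tmodel):
        rng = np.random.default_rng(3)
        dwells = []
        for _ in range(2000):
            dwells.extend(simulate_path(tc.LET7A, default_tmodel, rng).dwells_ms)
        dwells = np.asarray(dwells)
        se = dwells.std() / np.sqrt(dwells.size)
        assert abs(dwells.mean() - default_tmodel.mean_dwell_ms) < 3 * se

    def test_read_length_law_decays_and_caps(self, default_tmodel):
        rng = np.random.default_rng(5)
        lengths = [simulate_path(tc.LET7A, default_tmodel, rng).read_length
                   for _ in range(8000)]
        counts = np.bincount(lengths, minlength=14)
        assert max(lengths) <= 12
        assert all(a >= b for a, b in zip(counts[1:12], counts[2:13]))


class TestRenderTrace:
    def test_zero_noise_single_base_is_rectangular(self):
        cmodel = ConductanceModel(sds={"T": 1e-9, "A": 1e-9, "G": 1e-9},
                                  baseline_sd=0.0)
        model = TranslocationModel(reversal_prob=0.0, read_length_p=1.0 - 1e-12)
        path = simulate_path("T", model, seed=0)
        trace = render_trace([path], {"seq": "T"}, cmodel, seed=0,
                             mean_gap_ms=5.0)
        ev = trace.events[0]
        seg = trace.samples[ev.start:ev.end]
        assert np.allclose(seg, 45.0, atol=1e-6)
        out = np.concatenate([trace.samples[:ev.start], trace.samples[ev.end:]])
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_event_samples_show_three_modes(self, default_cmodel, default_tmodel):
        trace = simulate_trace(tc.LET7A, 1000, seed=11, sequence_id="s")
        mask = trace.base_index >= 1
        samples = trace.samples[mask]
        hist, edges = np.histogram(samples, bins=np.arange(0, 140, 2.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        for mu in (45, 77, 102):
            window = (centers > mu - 6) & (centers < mu + 6)
            flank = (centers > mu - 18) & (centers < mu - 12)
            assert hist[window].max() > hist[flank].max()

    def test_no_paths_gives_pure_baseline(self, default_cmodel):
        trace = render_trace([], {}, default_cmodel, seed=0, mean_gap_ms=2000.0)
        assert trace.events == []
        base = tc.estimate_baseline(trace)
        noise = tc.estimate_sigma(trace, base)
        assert tc.detect_signals(trace, base, noise) == []

    def test_annotation_conservation(self, default_tmodel):
        trace = simulate_trace(tc.LET7A, 57, seed=13)
        assert len(trace.events) == 57

    def test_reproducibility(self):
        a = simulate_trace(tc.LET7A, 40, seed=21)
        b = simulate_trace(tc.LET7A, 40, seed=21)
        assert np.array_equal(a.samples, b.samples)
        assert [e.start for e in a.events] == [e.start for e in b.events]


class TestSimulateMixture:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InputError):
            simulate_mixture({"a": "TG"}, {"a": 0.9}, 5, seed=0)

    def test_single_variant_all_events_labeled(self):
        t = simulate_mixture({"let-7a": tc.LET7A}, {"let-7a": 1.0}, 30, seed=2)
        assert all(e.sequence_id == "let-7a" for e in t.events)

    def test_event_counts_within_binomial_band(self):
        n = 4000
        t = simulate_mixture({"let-7a": tc.LET7A, "let-7f": tc.LET7F},
                             {"let-7a": 0.75, "let-7f": 0.25}, n, seed=3)
        n_a = sum(e.sequence_id == "let-7a" for e in t.events)
        sigma = np.sqrt(n * 0.75 * 0.25)
        assert abs(n_a - 0.75 * n) < 3 * sigma

    def test_determinism(self):
        kw = dict(variants={"let-7a": tc.LET7A, "let-7c": tc.LET7C},
                  fractions={"let-7a": 0.5, "let-7c": 0.5}, n_events=25)
        t1 = simulate_mixture(seed=9, **kw)
        t2 = simulate_mixture(seed=9, **kw)
        assert np.array_equal(t1.samples, t2.samples)
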