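"""Shared fixtures: simulated runs are expensive, so one moderate let-7a
run is produced once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import tunnelcall as tc
from tunnelcall.base_call import Fragment


@pytest.fixture(scope="session")
def let7a_run():
    """Simulated let-7a trace (600 events) with detection, fit, calls."""
    trace = tc.simulate_trace(tc.LET7A, 600, seed=101, sequence_id="let-7a")
    segments, baseline, noise = tc.detect_two_pass(trace)
    fit = tc.fit_conductance_model(segments)
    fragments = tc.call_segments(segments, fit.model, trace_id="let-7a")
    return {
        "trace": trace,
        "segments": segments,
        "baseline": baseline,
        "noise": noise,
        "fit": fit,
        "fragments": fragments,
    }


@pytest.fixture(scope="session")
def default_cmodel():
    return tc.ConductanceModel()


@pytest.fixture(scope="session")
def default_tmodel():
    return tc.TranslocationModel()


def make_fragment(seq: str, seg_id: int = 0, conds=None, quals=None) -> Fragment:
    """Minimal fragment with synthetic per-letter metadata."""
    n = len(seq)
    return Fragment(
        seq,
        times_ms=tuple(0.667 * (i + 0.5) for i in range(n)),
        norm_conductances=tuple(conds if conds is not None else [0.5] * n),
        qualities=tuple(quals if quals is not None else [1.0] * n),
        segment_id=seg_id,
    )


@pytest.fixture
def mk_fragment():
    return make_fragment
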