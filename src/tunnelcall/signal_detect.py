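"""Signal detection in conductance-time traces.

The baseline (conductance with no molecule in the gap) is a centered
moving average of 2000 samples; the per-second noise sigma is the mode of
the 500 standard deviations of disjoint 20-sample windows within the
second; a signal opens when the baseline-corrected conductance exceeds
6 sigma and closes when it falls below 1 sigma (hysteresis). Because
events themselves inflate the raw moving average, detection is run twice:
the second pass recomputes the baseline with detected segments replaced by
linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateNoiseError, InputError
from .trace_sim import Trace


@dataclass(frozen=True)
class SignalSegment:
    """A detected above-baseline event, half-open in sample indices."""

    start: int
    end: int
    baseline_ps: float  # mean local baseline over the segment
    sigma_ps: float     # sigma of the opening second
    samples: np.ndarray = field(repr=False)  # baseline-corrected, pS

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("segment must span at least one sample")

    def __len__(self) -> int:
        return self.end - self.start

    def duration_ms(self, sample_rate_hz: float) -> float:
        return len(self) / sample_rate_hz * 1000.0


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-second sigma values plus the window sd sets behind them."""

    sigmas: np.ndarray            # one per 1-s block, pS
    block_size: int               # samples per block
    window_sds: tuple[np.ndarray, ...] = field(default=(), repr=False)

    def sigma_at(self, sample_index: int) -> float:
        i = min(sample_index // self.block_size, self.sigmas.size - 1)
        return float(self.sigmas[i])


def estimate_baseline(trace: Trace | np.ndarray, window: int = 2000) -> np.ndarray:
    """Centered moving average with symmetric edge truncation."""
    if window < 1:
        raise InputError("window must be >= 1")
    x = trace.samples if isinstance(trace, Trace) else np.asarray(trace, float)
    n = x.size
    if n < 1:
        raise InputError("trace must have at least one sample")
    half_lo = window // 2
    half_hi = window - half_lo  # window of size w covers [i-half_lo, i+half_hi)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _mode_of_sds(sds: np.ndarray) -> float:
    """Mode as the midpoint of the most populated histogram bin.

    Bin width follows the Freedman-Diaconis rule over the sd set; ties are
    broken toward the smaller sigma (conservative detection).
    """
    sds = np.asarray(sds, float)
    lo, hi = float(sds.min()), float(sds.max())
    if hi == lo:
        return lo
    q75, q25 = np.percentile(sds, [75, 25])
    width = 2.0 * (q75 - q25) * sds.size ** (-1.0 / 3.0)
    if width <= 0:
        width = (hi - lo) / max(1, int(np.sqrt(sds.size)))
    nbins = max(1, int(np.ceil((hi - lo) / width)))
    counts, edges = np.histogram(sds, bins=nbins, range=(lo, hi))
    k = int(np.argmax(counts))  # first maximum = smallest sigma bin
    return float(0.5 * (edges[k] + edges[k + 1]))


def estimate_sigma(
    trace: Trace | np.ndarray,
    baseline: np.ndarray,
    *,
    sample_rate_hz: float | None = None,
    window: int = 20,
) -> NoiseEstimate:
    """Per-second robust sigma of the baseline-corrected trace.

    Each 1-second block (10 000 samples at 10 kHz) is divided into
    disjoint ``window``-sample pieces (500 of them); the block's sigma is
    the mode of their sample standard deviations. A trailing partial block
    uses as many whole windows as fit; a block with fewer than ``window``
    samples inherits the previous block's sigma.
    """
    if isinstance(trace, Trace):
        x = trace.samples
        sr = trace.sample_rate_hz
    else:
        x = np.asarray(trace, float)
        if sample_rate_hz is None:
            raise InputError("sample_rate_hz required for bare arrays")
        sr = sample_rate_hz
    corrected = x - baseline
    block = int(round(sr))  # samples per second
    n = corrected.size
    n_blocks = max(1, (n + block - 1) // block)
    sigmas = np.empty(n_blocks)
    all_sds: list[np.ndarray] = []
    for b in range(n_blocks):
        chunk = corrected[b * block: (b + 1) * block]
        n_win = chunk.size // window
        if n_win == 0:
            if b == 0:
                raise InputError(
                    f"block of {chunk.size} samples is shorter than one "
                    f"{window}-sample window and no previous block exists"
                )
            sigmas[b] = sigmas[b - 1]
            all_sds.append(np.empty(0))
            continue
        w = chunk[: n_win * window].reshape(n_win, window)
        sds = w.std(axis=1, ddof=1)
        all_sds.append(sds)
        sigmas[b] = _mode_of_sds(sds)
    return NoiseEstimate(sigmas, block, tuple(all_sds))


def detect_signals(
    trace: Trace | np.ndarray,
    baseline: np.ndarray,
    noise: NoiseEstimate,
    *,
    sample_rate_hz: float | None = None,
    rise_sigma: float = 6.0,
    fall_sigma: float = 1.0,
    min_duration_ms: float = 0.5,
) -> list[SignalSegment]:
    """Extract signal segments with the 6-sigma-rise / 1-sigma-fall rule.

    A candidate opens at the first sample whose corrected value exceeds
    ``rise_sigma*sigma``; its start is pulled back to just after the most
    recent sample <= ``fall_sigma*sigma`` and it runs forward until the
    corrected value drops below ``fall_sigma*sigma``. The sigma of the
    second in which the rise occurs applies to the whole segment.
    Overlapping candidates merge; candidates shorter than the minimum
    retention time (0.5 ms) are discarded.
    """
    if isinstance(trace, Trace):
        x = trace.samples
        sr = trace.sample_rate_hz
    else:
        x = np.asarray(trace, float)
        if sample_rate_hz is None:
            raise InputError("sample_rate_hz required for bare arrays")
        sr = sample_rate_hz
    if np.any(noise.sigmas <= 0):
        raise DegenerateNoiseError(
            "noise sigma is non-positive in at least one second; the trace "
            "is too quiet/constant for threshold detection"
        )
    c = x - baseline
    n = c.size
    min_samples = max(1, int(round(min_duration_ms * sr / 1000.0)))

    raw: list[tuple[int, int, float]] = []
    i = 0
    while i < n:
        sigma = noise.sigma_at(i)
        if c[i] > rise_sigma * sigma:
            # backward to just after the last sample <= fall threshold
            j = i
            while j > 0 and c[j - 1] > fall_sigma * sigma:
                j -= 1
            # forward until the corrected value drops below fall threshold
            k = i + 1
            while k < n and c[k] >= fall_sigma * sigma:
                k += 1
            raw.append((j, k, sigma))
            i = k
        else:
            i += 1

    merged: list[tuple[int, int, float]] = []
    for s0, e0, sg in raw:
        if merged and s0 <= merged[-1][1]:
            ps, pe, psg = merged[-1]
            merged[-1] = (ps, max(pe, e0), psg)
        else:
            merged.append((s0, e0, sg))

    out = []
    for s0, e0, sg in merged:
        if e0 - s0 < min_samples:
            continue
        out.append(
            SignalSegment(
                start=s0,
                end=e0,
                baseline_ps=float(np.mean(baseline[s0:e0])),
                sigma_ps=sg,
                samples=c[s0:e0].copy(),
            )
        )
    return out


def detect_two_pass(
    trace: Trace,
    *,
    baseline_window: int = 2000,
    rise_sigma: float = 6.0,
    fall_sigma: float = 1.0,
    min_duration_ms: float = 0.5,
) -> tuple[list[SignalSegment], np.ndarray, NoiseEstimate]:
    """Full detection: raw-baseline pass, then masked-baseline pass.

    Pass 1 detects on the plain moving average; pass 2 replaces detected
    segments by linear interpolation of the surrounding trace, recomputes
    the moving average and sigma on that molecule-free series, and
    re-detects. Returns ``(segments, baseline, noise)`` of the final pass.
    """
    b1 = estimate_baseline(trace, baseline_window)
    n1 = estimate_sigma(trace, b1)
    segs = detect_signals(trace, b1, n1, rise_sigma=rise_sigma,
                          fall_sigma=fall_sigma, min_duration_ms=min_duration_ms)
    masked = trace.samples.copy()
    for s in segs:
        left = masked[s.start - 1] if s.start > 0 else b1[s.start]
        right = masked[s.end] if s.end < masked.size else b1[s.end - 1]
        masked[s.start:s.end] = np.linspace(left, right, len(s) + 2)[1:-1]
    b2 = estimate_baseline(masked, baseline_window)
    # sigma from the original trace against the cleaned baseline: the mode
    # is robust to the (sparse, widely spread) event windows, whereas the
    # interpolated series would contribute spurious zero-variance windows
    n2 = estimate_sigma(trace, b2)
    segs2 = detect_signals(trace, b2, n2, rise_sigma=rise_sigma,
                           fall_sigma=fall_sigma, min_duration_ms=min_duration_ms)
    return segs2, b2, n2


__all__ = [
    "SignalSegment",
    "NoiseEstimate",
    "estimate_baseline",
    "estimate_sigma",
    "detect_signals",
    "detect_two_pass",
]
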