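"""Probabilistic base calling from conductance probability densities.

Detected segments are smoothed with a 0.5-ms median filter (the minimum
retention time of a base in the gap), the pooled conductance histogram is
fitted with a Gaussian mixture (baseline + one peak per base, lowest peak
= baseline, highest = guanine), and each 0.5-ms interval of a segment is
assigned the most probable label by integrating the per-label log density
over the interval. Runs of identical labels are split into letters using
the nominal dwell (1/1.5 ms per base), yielding fragments with per-letter
times, normalized conductances (relative to the fitted G peak) and
posterior qualities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import FittingError, InputError
from .signal_detect import SignalSegment
from .trace_sim import ConductanceModel

BASELINE_LABEL = "baseline"


def smooth_segment(
    segment: SignalSegment | np.ndarray,
    *,
    min_retention_ms: float = 0.5,
    sample_rate_hz: float = 10_000.0,
):
    """Median-filter a segment to suppress sub-retention excursions.

    The window is the minimum retention time in samples (5 at 10 kHz),
    forced odd; edges use truncated windows. Returns a new
    :class:`SignalSegment` (or array, matching the input type).
    """
    x = segment.samples if isinstance(segment, SignalSegment) else np.asarray(segment, float)
    w = max(1, int(round(min_retention_ms * sample_rate_hz / 1000.0)))
    if w % 2 == 0:
        w += 1
    half = w // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(x[max(0, i - half): min(n, i + half + 1)])
    if isinstance(segment, SignalSegment):
        return SignalSegment(segment.start, segment.end, segment.baseline_ps,
                             segment.sigma_ps, out)
    return out


# --------------------------------------------------------------------------
# conductance-model fitting


@dataclass(frozen=True)
class ConductanceFit:
    """Result of the histogram mixture fit."""

    model: ConductanceModel
    means: np.ndarray        # all components ascending (baseline first)
    sds: np.ndarray
    amplitudes: np.ndarray
    areas: np.ndarray        # amplitude * sd * sqrt(2*pi), same order
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    @property
    def base_means(self) -> np.ndarray:
        return self.means[1:]


def _gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for a, mu, s in zip(params[0::3], params[1::3], params[2::3]):
        y = y + a * np.exp(-0.5 * ((x - mu) / s) ** 2)
    return y


def fit_conductance_model(
    segments: list[SignalSegment],
    *,
    n_bases: int = 3,
    labels_by_rank: tuple[str, ...] = ("T", "A", "G"),
    bin_width_ps: float = 1.0,
    min_samples: int = 1000,
    smooth: bool = True,
    sample_rate_hz: float = 10_000.0,
) -> ConductanceFit:
    """Fit the pooled conductance histogram with baseline + base Gaussians.

    Histogram bins are ``bin_width_ps`` wide over [0, 1.3 x max sample];
    the ``n_bases + 1`` components are initialized at the most prominent
    local maxima (a near-zero baseline seed is added when the baseline
    peak is hidden because segments exclude baseline samples) and fitted
    by nonlinear least squares on the counts. Fitted means, ascending, are
    assigned baseline / T / A / G (mapping configurable via
    ``labels_by_rank``).
    """
    if len(labels_by_rank) != n_bases:
        raise InputError("labels_by_rank must have n_bases entries")
    pooled = []
    for seg in segments:
        s = smooth_segment(seg, sample_rate_hz=sample_rate_hz) if smooth else seg
        pooled.append(s.samples if isinstance(s, SignalSegment) else s)
    if not pooled:
        raise FittingError("no segments to fit")
    x = np.concatenate(pooled)
    if x.size < min_samples:
        raise FittingError(
            f"only {x.size} pooled samples; need >= {min_samples} for a "
            "stable histogram fit"
        )
    hi = 1.3 * float(x.max())
    edges = np.arange(0.0, hi + bin_width_ps, bin_width_ps)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # initialization: most prominent local maxima of the lightly smoothed counts
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 2.5) ** 2)
    smoothed = np.convolve(counts, kernel / kernel.sum(), mode="same")
    peaks, props = find_peaks(smoothed, prominence=max(1.0, smoothed.max() * 0.01))
    order = np.argsort(props["prominences"])[::-1]
    n_comp = n_bases + 1
    cand = sorted(centers[peaks[order[:n_comp]]])
    if len(cand) == n_comp - 1 and (not cand or cand[0] > 3 * bin_width_ps):
        # segments carry almost no baseline-level samples; seed baseline at 0
        cand = [0.0] + cand
    if len(cand) < n_comp:
        raise FittingError(
            f"insufficient peak separation: found {len(cand)} candidate "
            f"peaks, need {n_comp}"
        )

    p0, lo_b, hi_b = [], [], []
    for idx, mu in enumerate(cand):
        j = int(np.clip(np.searchsorted(centers, mu), 0, counts.size - 1))
        p0 += [max(float(smoothed[j]), 1.0), float(mu), 5.0]
        # each component's mean stays near its initializing peak (half-way
        # to the neighbors); otherwise a component without histogram mass
        # (the baseline, when segments carry none) drifts onto a base peak
        # and scrambles the label assignment
        lo_mu = 0.0 if idx == 0 else 0.5 * (cand[idx - 1] + mu)
        hi_mu = hi if idx == len(cand) - 1 else 0.5 * (cand[idx + 1] + mu)
        lo_b += [0.0, lo_mu, 0.5 * bin_width_ps]
        hi_b += [np.inf, max(hi_mu, lo_mu + bin_width_ps), hi]
    try:
        popt, _ = curve_fit(_gaussian_sum, centers, counts.astype(float),
                            p0=p0, bounds=(lo_b, hi_b), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FittingError(f"mixture fit did not converge: {exc}") from exc

    amps, mus, sds = popt[0::3], popt[1::3], popt[2::3]
    k = np.argsort(mus)
    amps, mus, sds = amps[k], mus[k], sds[k]
    means = {lab: float(m) for lab, m in zip(labels_by_rank, mus[1:])}
    bsds = {lab: float(s) for lab, s in zip(labels_by_rank, sds[1:])}
    model = ConductanceModel(means=means, sds=bsds,
                             baseline_mean=float(mus[0]),
                             baseline_sd=float(max(sds[0], 1e-9)))
    areas = amps * sds * math.sqrt(2 * math.pi)
    return ConductanceFit(model, mus, sds, amps, areas, edges, counts)


# --------------------------------------------------------------------------
# interval calling


@dataclass(frozen=True)
class IntervalCall:
    """Most probable label for one 0.5-ms interval of a segment."""

    start_ms: float
    duration_ms: float
    label: str                      # base letter or ``baseline``
    posteriors: dict[str, float]    # normalized, sums to 1
    mean_conductance_ps: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        tot = sum(self.posteriors.values())
        if abs(tot - 1.0) > 1e-9:
            raise InputError("posteriors must sum to 1")


def call_intervals(
    segment: SignalSegment,
    cmodel: ConductanceModel,
    *,
    interval_ms: float = 0.5,
    sample_rate_hz: float = 10_000.0,
    include_baseline: bool = True,
    low_confidence_gap: float = 0.1,
    grid_phase: int = 0,
) -> list[IntervalCall]:
    """Assign each 0.5-ms interval its most probable molecular species.

    ``grid_phase`` shifts the interval grid by that many samples (the
    grid origin relative to the segment start is arbitrary); a leading
    chunk of at least half an interval is called as a partial interval.

    The per-label score integrates the label's Gaussian probability
    density over the interval (sum of densities across samples, equal
    priors); posteriors are the normalized scores. Integrating densities
    rather than multiplying them keeps an interval that straddles a base
    transition (half its samples at one level, half at another) assigned
    to one of the two real levels instead of a spurious intermediate
    label. A final partial interval is kept when it is at least half the
    interval width. Ties break toward the lower-conductance label and are
    flagged low-confidence, as is any call whose top-two posterior gap is
    below ``low_confidence_gap``.
    """
    x = segment.samples
    n_per = max(1, int(round(interval_ms * sample_rate_hz / 1000.0)))
    labels = list(cmodel.alphabet)
    mus = [cmodel.means[b] for b in labels]
    sds = [cmodel.sds[b] for b in labels]
    if include_baseline:
        labels.append(BASELINE_LABEL)
        mus.append(cmodel.baseline_mean)
        sds.append(max(cmodel.baseline_sd, 1e-9))
    mus_a = np.array(mus)
    sds_a = np.array(sds)
    order_by_mu = np.argsort(mus_a)  # for tie-breaking toward lower conductance

    calls: list[IntervalCall] = []
    i = max(0, int(grid_phase))
    if 0 < i < math.ceil(n_per / 2):
        i = 0  # a too-short leading chunk is absorbed into the first interval
    elif i > 0:
        chunk = x[:i]
        z = (chunk[:, None] - mus_a[None, :]) / sds_a[None, :]
        dens = np.exp(-0.5 * z ** 2) / sds_a[None, :]
        scores = dens.sum(axis=0)
        tot = scores.sum()
        post = scores / tot if tot > 0 else np.full_like(scores, 1.0 / scores.size)
        best = int(np.argmax(post))
        ranked = np.sort(post)[::-1]
        calls.append(IntervalCall(
            start_ms=0.0,
            duration_ms=chunk.size / sample_rate_hz * 1000.0,
            label=labels[best],
            posteriors={lab: float(p) for lab, p in zip(labels, post)},
            mean_conductance_ps=float(chunk.mean()),
            low_confidence=bool(ranked.size > 1
                                and ranked[0] - ranked[1] < low_confidence_gap),
        ))
    while i < x.size:
        chunk = x[i: i + n_per]
        if chunk.size < n_per and chunk.size < math.ceil(n_per / 2):
            break  # drop a too-short trailing interval
        # integrate N(x; mu, sd) over the interval: sum of densities
        z = (chunk[:, None] - mus_a[None, :]) / sds_a[None, :]
        dens = np.exp(-0.5 * z ** 2) / sds_a[None, :]
        scores = dens.sum(axis=0)
        tot = scores.sum()
        post = scores / tot if tot > 0 else np.full_like(scores,
                                                         1.0 / scores.size)
        best = int(np.argmax(post))
        # deterministic tie-break: lower-conductance label wins near-exact ties
        tied = [j for j in order_by_mu if post[best] - post[j] < 1e-9]
        low = False
        if tied and tied[0] != best:
            best = tied[0]
            low = True
        ranked = np.sort(post)[::-1]
        if ranked.size > 1 and (ranked[0] - ranked[1]) < low_confidence_gap:
            low = True
        calls.append(
            IntervalCall(
                start_ms=i / sample_rate_hz * 1000.0,
                duration_ms=chunk.size / sample_rate_hz * 1000.0,
                label=labels[best],
                posteriors={lab: float(p) for lab, p in zip(labels, post)},
                mean_conductance_ps=float(chunk.mean()),
                low_confidence=low,
            )
        )
        i += n_per
    return calls


# --------------------------------------------------------------------------
# fragments


@dataclass(frozen=True)
class Fragment:
    """A called base sequence from one translocation event.

    ``norm_conductances`` are relative to the fitted guanine mean;
    ``times_ms`` are per-letter times from segment start; ``qualities``
    are mean per-letter posteriors (used as consensus weights).
    """

    sequence: str
    times_ms: tuple[float, ...]
    norm_conductances: tuple[float, ...]
    qualities: tuple[float, ...]
    segment_id: int | None = None
    trace_id: str | None = None

    def __post_init__(self) -> None:
        m = len(self.sequence)
        if m < 1:
            raise InputError("fragment must have at least one letter")
        if not (len(self.times_ms) == len(self.norm_conductances)
                == len(self.qualities) == m):
            raise InputError("per-letter arrays must match sequence length")
        if any(b <= a for a, b in zip(self.times_ms, self.times_ms[1:])):
            raise InputError("letter times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def reversed(self) -> "Fragment":
        """Letter-order reversal (a 3'-entry read; never complemented)."""
        return Fragment(self.sequence[::-1],
                        tuple(-t for t in reversed(self.times_ms)),
                        tuple(reversed(self.norm_conductances)),
                        tuple(reversed(self.qualities)),
                        self.segment_id, self.trace_id)


def _refine_boundaries(
    runs: list[tuple[str, list[IntervalCall]]],
    samples: np.ndarray,
    cmodel: ConductanceModel,
    sample_rate_hz: float,
    interval_ms: float,
) -> list[float]:
    """Sample-resolution run boundaries via a local change-point fit.

    Interval calling quantizes run durations to the 0.5-ms grid, which is
    too coarse to separate one slow base from two quick repeated bases.
    For each internal run boundary the cut is re-placed at the sample
    within +-1 interval that minimizes the two-level squared error, so
    durations track the underlying dwells. Returns boundary times in ms
    (length ``len(runs) + 1``).
    """
    level = dict(cmodel.means)
    level[BASELINE_LABEL] = cmodel.baseline_mean
    sr_ms = sample_rate_hz / 1000.0
    w = max(1, int(round(interval_ms * sr_ms)))
    cuts = [0.0]
    edge = 0
    for (lab1, members1), (lab2, _m2) in zip(runs, runs[1:]):
        edge += sum(len_intervals for len_intervals in
                    (int(round(c.duration_ms * sr_ms)) for c in members1))
        lo = max(0, edge - w)
        hi = min(samples.size, edge + w)
        mu1, mu2 = level[lab1], level[lab2]
        seg = samples[lo:hi]
        best_c, best_cost = edge, np.inf
        for c in range(lo, hi + 1):
            j = c - lo
            cost = float(((seg[:j] - mu1) ** 2).sum()
                         + ((seg[j:] - mu2) ** 2).sum())
            if cost < best_cost:
                best_cost, best_c = cost, c
        cuts.append(max(best_c / sr_ms, cuts[-1]))
    cuts.append(max(samples.size / sr_ms, cuts[-1]))
    return cuts


def calls_to_fragment(
    calls: list[IntervalCall],
    cmodel: ConductanceModel,
    *,
    expected_dwell_ms: float = 1.0 / 1.5,
    samples: np.ndarray | None = None,
    sample_rate_hz: float = 10_000.0,
    interval_ms: float = 0.5,
    min_run_ms: float = 0.25,
    segment_id: int | None = None,
    trace_id: str | None = None,
) -> Fragment | None:
    """Collapse interval calls into a fragment.

    Maximal runs of consecutive identical non-baseline labels become
    ``k = max(1, round(duration / expected_dwell))`` letters (ties at .5
    round down, so a 1.0-ms run at the default dwell stays one letter) —
    a base that lingered across several intervals is one letter, while a
    long run over a repeated base (e.g. the GG of let-7a) splits into
    two. When the segment's ``samples`` are given, run boundaries are
    refined to sample resolution first and runs that collapse below
    ``min_run_ms`` (boundary-interval artifacts) are dropped. Returns
    ``None`` when every call is baseline (caller skips the segment).
    """
    runs: list[tuple[str, list[IntervalCall]]] = []
    for c in calls:
        if runs and runs[-1][0] == c.label:
            runs[-1][1].append(c)
        else:
            runs.append((c.label, [c]))
    if not runs:
        return None
    if samples is not None:
        bounds = _refine_boundaries(runs, np.asarray(samples, float), cmodel,
                                    sample_rate_hz, interval_ms)
    else:
        bounds = [runs[0][1][0].start_ms]
        for _, members in runs:
            bounds.append(bounds[-1] + sum(c.duration_ms for c in members))
    g_mean = cmodel.reference_mean
    letters: list[str] = []
    times: list[float] = []
    conds: list[float] = []
    quals: list[float] = []
    for (label, members), start, end in zip(runs, bounds, bounds[1:]):
        if label == BASELINE_LABEL:
            continue
        dur = end - start
        if samples is not None and dur < min_run_ms:
            continue
        # round-half-down: ceil(x - 1/2)
        k = max(1, int(math.ceil(dur / expected_dwell_ms - 0.5)))
        if samples is not None:
            # median over the run interior: boundary samples mix adjacent
            # levels and would bias the lowest/highest letters toward the
            # middle of the conductance range
            sr_ms = sample_rate_hz / 1000.0
            i0 = int(round(start * sr_ms)) + 1
            i1 = max(i0 + 1, int(round(end * sr_ms)) - 1)
            chunk = np.asarray(samples[i0:i1], float)
            mean_c = (float(np.median(chunk)) if chunk.size else
                      float(np.mean([c.mean_conductance_ps for c in members])))
        else:
            mean_c = float(np.mean([c.mean_conductance_ps for c in members]))
        mean_q = float(np.mean([c.posteriors[label] for c in members]))
        for j in range(k):
            letters.append(label)
            times.append(start + (j + 0.5) * dur / k)
            conds.append(mean_c / g_mean)
            quals.append(mean_q)
    if not letters:
        return None
    return Fragment("".join(letters), tuple(times), tuple(conds), tuple(quals),
                    segment_id=segment_id, trace_id=trace_id)


def call_segments(
    segments: list[SignalSegment],
    cmodel: ConductanceModel,
    *,
    interval_ms: float = 0.5,
    expected_dwell_ms: float = 1.0 / 1.5,
    sample_rate_hz: float = 10_000.0,
    trace_id: str | None = None,
) -> list[Fragment]:
    """Smooth, interval-call and fragment every segment (skipping those
    that call entirely baseline)."""
    n_per = max(1, int(round(interval_ms * sample_rate_hz / 1000.0)))
    out = []
    for i, seg in enumerate(segments):
        sm = smooth_segment(seg, sample_rate_hz=sample_rate_hz)
        # the grid origin is arbitrary relative to base transitions, so
        # pick the phase whose intervals align best with the conductance
        # plateaus: straddling intervals mimic the intermediate base (the
        # adenine level sits near the G/T midpoint) and are low-confidence
        best_calls, best_q = None, -1.0
        for phase in range(n_per):
            cand = call_intervals(sm, cmodel, interval_ms=interval_ms,
                                  sample_rate_hz=sample_rate_hz,
                                  grid_phase=phase)
            if not cand:
                continue
            q = float(np.mean([c.posteriors[c.label] for c in cand]))
            if q > best_q + 1e-12:
                best_calls, best_q = cand, q
        calls = best_calls or []
        frag = calls_to_fragment(calls, cmodel,
                                 expected_dwell_ms=expected_dwell_ms,
                                 samples=sm.samples,
                                 sample_rate_hz=sample_rate_hz,
                                 interval_ms=interval_ms,
                                 segment_id=i, trace_id=trace_id)
        if frag is not None:
            out.append(frag)
    return out


__all__ = [
    "BASELINE_LABEL",
    "ConductanceFit",
    "IntervalCall",
    "Fragment",
    "smooth_segment",
    "fit_conductance_model",
    "call_intervals",
    "calls_to_fragment",
    "call_segments",
]
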