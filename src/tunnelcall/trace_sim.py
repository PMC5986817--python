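"""Synthetic conductance-trace simulator with ground-truth annotations.

Emulates single-molecule tunneling-current measurements of short DNA in a
fixed nanogap: a molecule diffuses through the gap by Brownian motion, each
base dwelling in the sensing zone produces a conductance plateau at a
base-specific level (Gaussian around ~45/77/102 pS for T/A/G at 0.1 V),
and the molecule may enter from either end and reverse direction mid-read.
Traces are sampled uniformly (default 10 kHz) on a zero-mean noisy
baseline; every simulated event carries its ground truth so downstream
stages can be validated quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

DEFAULT_SAMPLE_RATE_HZ = 10_000.0
DEFAULT_BIAS_V = 0.1


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class ConductanceModel:
    """Per-base Gaussian conductance peaks plus a baseline peak.

    ``means``/``sds`` are in pS; means must be strictly increasing over the
    alphabet (T < A < G by default) and all above the baseline mean. The
    baseline sits at 0 pS after baseline correction.
    """

    means: dict[str, float] = field(
        default_factory=lambda: {"T": 45.0, "A": 77.0, "G": 102.0}
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {"T": 8.0, "A": 8.0, "G": 8.0}
    )
    baseline_mean: float = 0.0
    baseline_sd: float = 4.0

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sds):
            raise InputError("means and sds must cover the same alphabet")
        mu = list(self.means.values())
        if any(b <= a for a, b in zip(mu, mu[1:])):
            raise InputError("base means must be strictly increasing over the alphabet")
        if any(m <= self.baseline_mean for m in mu):
            raise InputError("all base means must exceed the baseline mean")
        if any(s <= 0 for s in self.sds.values()) or self.baseline_sd < 0:
            raise InputError("standard deviations must be positive")

    @property
    def alphabet(self) -> tuple[str, ...]:
        return tuple(self.means)

    @property
    def reference_mean(self) -> float:
        """Mean of the highest peak (G) — the normalization reference."""
        return max(self.means.values())

    def normalized(self) -> dict[str, float]:
        g = self.reference_mean
        return {b: m / g for b, m in self.means.items()}


@dataclass(frozen=True)
class TranslocationModel:
    """Stochastic model of one molecule's passage through the nanogap.

    Dwell per base is exponential above a hard floor (``min_dwell_ms``,
    the minimum retention time); the mean dwell 1/1.5 ms reproduces the
    ~1.5 bases/ms translocation velocity. Read length (number of distinct
    bases sensed) is geometric truncated at ``max_read_length``; the
    molecule enters 3' or 5' first with probability ``entry_3prime_prob``
    and flips reading direction with per-step probability
    ``reversal_prob``.
    """

    mean_dwell_ms: float = 1.0 / 1.5
    min_dwell_ms: float = 0.5
    reversal_prob: float = 0.05
    entry_3prime_prob: float = 0.5
    read_length_p: float = 0.3
    max_read_length: int = 12
    mean_gap_ms: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.min_dwell_ms <= self.mean_dwell_ms):
            raise InputError("need 0 < min dwell <= mean dwell")
        if not (0 <= self.reversal_prob < 1):
            raise InputError("reversal probability must be in [0, 1)")
        if not (0 <= self.entry_3prime_prob <= 1):
            raise InputError("entry probability must be in [0, 1]")
        if not (0 < self.read_length_p <= 1):
            raise InputError("read-length parameter must be in (0, 1]")
        if self.max_read_length < 1:
            raise InputError("max read length must be >= 1")
        if self.mean_gap_ms <= 0:
            raise InputError("mean gap must be positive")

    def draw_read_length(self, rng: np.random.Generator) -> int:
        """Geometric(p) truncated at ``max_read_length`` (resampling tail)."""
        if self.read_length_p >= 1.0:
            return 1
        # inverse-CDF of the truncated geometric
        p, m = self.read_length_p, self.max_read_length
        u = rng.random()
        cdf_max = 1.0 - (1.0 - p) ** m
        k = int(math.ceil(math.log1p(-u * cdf_max) / math.log1p(-p)))
        return min(max(k, 1), m)

    def draw_dwell(self, rng: np.random.Generator) -> float:
        return self.min_dwell_ms + rng.exponential(
            self.mean_dwell_ms - self.min_dwell_ms
        )


@dataclass(frozen=True)
class TranslocationPath:
    """Ordered (1-based base index, dwell ms) steps of one event."""

    steps: tuple[tuple[int, float], ...]
    sequence_id: str
    entry_end: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.steps]
        if any(abs(b - a) != 1 for a, b in zip(idx, idx[1:])):
            raise InputError("path must step between adjacent bases only")

    @property
    def indices(self) -> list[int]:
        return [i for i, _ in self.steps]

    @property
    def dwells_ms(self) -> list[float]:
        return [d for _, d in self.steps]

    @property
    def read_length(self) -> int:
        """Number of distinct bases dwelled on."""
        return len(set(self.indices))

    @property
    def n_reversals(self) -> int:
        idx = self.indices
        dirs = [b - a for a, b in zip(idx, idx[1:])]
        return sum(1 for a, b in zip(dirs, dirs[1:]) if a != b)

    def letters(self, sequence: str) -> str:
        return "".join(sequence[i - 1] for i in self.indices)


@dataclass(frozen=True)
class EventTruth:
    start: int
    end: int  # half-open sample interval
    sequence_id: str
    entry_end: str
    path: TranslocationPath


@dataclass
class Trace:
    """Uniformly sampled conductance series with optional ground truth."""

    samples: np.ndarray  # pS
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    bias_v: float = DEFAULT_BIAS_V
    events: list[EventTruth] | None = None
    base_index: np.ndarray | None = None  # per-sample 1-based index, -1 baseline

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InputError("trace needs at least one sample")
        if self.sample_rate_hz <= 0:
            raise InputError("sample rate must be positive")
        if self.events is not None:
            ivals = sorted((e.start, e.end) for e in self.events)
            n = self.samples.size
            for (s0, e0), nxt in zip(ivals, ivals[1:] + [(n, n)]):
                if not (0 <= s0 < e0 <= n) or e0 > nxt[0]:
                    raise InputError("ground-truth intervals must be disjoint, in bounds")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


# --------------------------------------------------------------------------
# simulation


def _validate_sequence(sequence: str, alphabet: tuple[str, ...] | None) -> None:
    if not sequence:
        raise InputError("sequence must be non-empty")
    if alphabet is not None and not set(sequence) <= set(alphabet):
        bad = sorted(set(sequence) - set(alphabet))
        raise InputError(f"sequence symbols {bad} outside alphabet {alphabet}")


def simulate_path(
    sequence: str,
    model: TranslocationModel,
    seed: int | np.random.Generator,
    *,
    sequence_id: str = "seq",
    alphabet: tuple[str, ...] | None = ("T", "A", "G"),
) -> TranslocationPath:
    """Simulate one translocation event over ``sequence``.

    A read length L is drawn from the truncated geometric; a contiguous
    window of that length is chosen uniformly on the sequence and the walk
    starts at the window end corresponding to the entry end (5' entry reads
    forward). At each step the direction flips with ``reversal_prob``; the
    walk stops once L distinct bases have been dwelled on or it steps off
    either end of the sequence.
    """
    _validate_sequence(sequence, alphabet)
    rng = _as_rng(seed)
    n = len(sequence)
    target = min(model.draw_read_length(rng), n)
    window_start = int(rng.integers(0, n - target + 1))  # 0-based
    entry_3p = rng.random() < model.entry_3prime_prob
    if entry_3p:
        pos, direction, entry = window_start + target, -1, "3p"
    else:
        pos, direction, entry = window_start + 1, +1, "5p"  # 1-based
    steps: list[tuple[int, float]] = [(pos, model.draw_dwell(rng))]
    visited = {pos}
    while len(visited) < target:
        if rng.random() < model.reversal_prob:
            direction = -direction
        nxt = pos + direction
        if not (1 <= nxt <= n):
            break  # exited the molecule
        pos = nxt
        visited.add(pos)
        steps.append((pos, model.draw_dwell(rng)))
    return TranslocationPath(tuple(steps), sequence_id, entry)


def render_trace(
    paths: list[TranslocationPath],
    sequences: dict[str, str],
    cmodel: ConductanceModel,
    seed: int | np.random.Generator,
    *,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    mean_gap_ms: float = 25.0,
    bias_v: float = DEFAULT_BIAS_V,
    drift_amplitude_ps: float = 0.0,
    drift_period_s: float = 5.0,
) -> Trace:
    """Render translocation paths into a noisy conductance trace.

    Each path becomes one above-baseline event (per-step Gaussian samples
    at the dwelled base's level); events are separated by exponential gaps
    of pure baseline. An optional slow sinusoidal drift exercises the
    moving-average baseline estimator.
    """
    if sample_rate_hz <= 0:
        raise InputError("sample rate must be positive")
    rng = _as_rng(seed)
    sr_ms = sample_rate_hz / 1000.0  # samples per ms

    chunks: list[np.ndarray] = []
    bidx: list[np.ndarray] = []
    events: list[EventTruth] = []
    cursor = 0

    def gap(mean_ms: float) -> None:
        nonlocal cursor
        m = max(1, int(round(rng.exponential(mean_ms) * sr_ms)))
        chunks.append(rng.normal(cmodel.baseline_mean, cmodel.baseline_sd, m))
        bidx.append(np.full(m, -1, dtype=np.int64))
        cursor += m

    gap(mean_gap_ms)
    for path in paths:
        seq = sequences[path.sequence_id]
        _validate_sequence(seq, cmodel.alphabet)
        start = cursor
        for idx, dwell in path.steps:
            base = seq[idx - 1]
            m = max(1, int(round(dwell * sr_ms)))
            chunks.append(rng.normal(cmodel.means[base], cmodel.sds[base], m))
            bidx.append(np.full(m, idx, dtype=np.int64))
            cursor += m
        events.append(EventTruth(start, cursor, path.sequence_id, path.entry_end, path))
        gap(mean_gap_ms)

    samples = np.concatenate(chunks)
    if drift_amplitude_ps:
        t = np.arange(samples.size) / sample_rate_hz
        samples = samples + drift_amplitude_ps * np.sin(
            2 * np.pi * t / drift_period_s
        )
    return Trace(
        samples,
        sample_rate_hz=sample_rate_hz,
        bias_v=bias_v,
        events=events,
        base_index=np.concatenate(bidx),
    )


def simulate_trace(
    sequence: str,
    n_events: int,
    seed: int,
    *,
    tmodel: TranslocationModel | None = None,
    cmodel: ConductanceModel | None = None,
    sequence_id: str = "seq",
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    **render_kwargs,
) -> Trace:
    """Convenience: simulate ``n_events`` paths of one sequence and render."""
    tmodel = tmodel or TranslocationModel()
    cmodel = cmodel or ConductanceModel()
    rng = np.random.default_rng(seed)
    paths = [
        simulate_path(sequence, tmodel, rng, sequence_id=sequence_id,
                      alphabet=cmodel.alphabet)
        for _ in range(n_events)
    ]
    render_kwargs.setdefault("mean_gap_ms", tmodel.mean_gap_ms)
    return render_trace(paths, {sequence_id: sequence}, cmodel, rng,
                        sample_rate_hz=sample_rate_hz, **render_kwargs)


def simulate_mixture(
    variants: dict[str, str],
    fractions: dict[str, float],
    n_events: int,
    seed: int,
    *,
    tmodel: TranslocationModel | None = None,
    cmodel: ConductanceModel | None = None,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    **render_kwargs,
) -> Trace:
    """Simulate a mixed solution: each event's variant is drawn by molar
    fraction; ground truth records the per-event variant label."""
    if n_events < 1:
        raise InputError("n_events must be >= 1")
    if set(fractions) - set(variants):
        raise InputError("fractions name unknown variants")
    vals = np.array([fractions[k] for k in fractions], dtype=float)
    if np.any(vals <= 0):
        raise InputError("fractions must be positive")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise InputError(f"fractions must sum to 1 (got {vals.sum()!r})")
    tmodel = tmodel or TranslocationModel()
    cmodel = cmodel or ConductanceModel()
    rng = np.random.default_rng(seed)
    names = list(fractions)
    labels = rng.choice(len(names), size=n_events, p=vals / vals.sum())
    paths = [
        simulate_path(variants[names[k]], tmodel, rng,
                      sequence_id=names[k], alphabet=cmodel.alphabet)
        for k in labels
    ]
    render_kwargs.setdefault("mean_gap_ms", tmodel.mean_gap_ms)
    return render_trace(paths, variants, cmodel, rng,
                        sample_rate_hz=sample_rate_hz, **render_kwargs)


def simulate_called_fragments(
    variants: dict[str, str],
    fractions: dict[str, float],
    n_events: int,
    seed: int,
    *,
    tmodel: TranslocationModel | None = None,
    cmodel: ConductanceModel | None = None,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
):
    """Fast fragment-level generator bypassing trace rendering.

    For each simulated path, the per-base observed conductance is the mean
    of the Gaussian samples the base would have produced over its dwell,
    and the letter is the maximum-density label under the conductance
    model — i.e. the idealized limit of detection + interval calling where
    segment boundaries are exact. Used for estimator-level studies
    (quantitation bias, consensus-vs-coverage) where rendering full traces
    would only add identical letters more slowly.

    Returns ``(fragments, truth_labels)`` where ``truth_labels[i]`` is the
    source variant name of fragment ``i``.
    """
    from .base_call import Fragment  # local import to avoid a cycle

    tmodel = tmodel or TranslocationModel()
    cmodel = cmodel or ConductanceModel()
    rng = np.random.default_rng(seed)
    names = list(fractions)
    vals = np.array([fractions[k] for k in names], dtype=float)
    if abs(vals.sum() - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1")
    labels = rng.choice(len(names), size=n_events, p=vals / vals.sum())
    sr_ms = sample_rate_hz / 1000.0
    letter_means = np.array([cmodel.means[b] for b in cmodel.alphabet])
    letter_sds = np.array([cmodel.sds[b] for b in cmodel.alphabet])
    g_mean = cmodel.reference_mean
    fragments, truth = [], []
    for ev, k in enumerate(labels):
        name = names[k]
        path = simulate_path(variants[name], tmodel, rng, sequence_id=name,
                             alphabet=cmodel.alphabet)
        seq = variants[name]
        t = 0.0
        letters, times, conds, quals = [], [], [], []
        for idx, dwell in path.steps:
            base = seq[idx - 1]
            m = max(1, int(round(dwell * sr_ms)))
            obs = rng.normal(cmodel.means[base], cmodel.sds[base] / math.sqrt(m))
            # most probable label given the per-letter mean of m samples
            z = -0.5 * ((obs - letter_means) / (letter_sds / math.sqrt(m))) ** 2 \
                - np.log(letter_sds)
            j = int(np.argmax(z))
            w = np.exp(z - z.max())
            letters.append(cmodel.alphabet[j])
            times.append(t + dwell / 2.0)
            conds.append(obs / g_mean)
            quals.append(float(w[j] / w.sum()))
            t += dwell
        fragments.append(
            Fragment("".join(letters), tuple(times), tuple(conds), tuple(quals),
                     segment_id=ev, trace_id=name)
        )
        truth.append(name)
    return fragments, truth


__all__ = [
    "ConductanceModel",
    "TranslocationModel",
    "TranslocationPath",
    "EventTruth",
    "Trace",
    "simulate_path",
    "render_trace",
    "simulate_trace",
    "simulate_mixture",
    "simulate_called_fragments",
    "DEFAULT_SAMPLE_RATE_HZ",
    "DEFAULT_BIAS_V",
]
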