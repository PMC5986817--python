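"""Transition-point (reading-direction) analysis of called fragments.

A molecule steps only between adjacent bases, so a fragment is a walk on
the reference that moves +-1 position per letter; direction reversals
("folds") re-read bases and duplicate letters. This module aligns
fragments to such walks by dynamic programming, detects fold points,
linearizes folded reads without a reference (mirror-span search), and
estimates the translocation velocity from base-position-versus-time
slopes over monotone stretches.

Reads are orientation-agnostic at the letter level: tunneling senses base
identity, not strand chemistry, so a reversed read is the reversed letter
string and is never complemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_call import Fragment
from .errors import InsufficientDataError

#: slope-uncertainty floor (bases/ms) guarding inverse-variance pooling
#: against degenerate zero-residual stretches created by 0.5-ms time
#: quantization of letter times
VELOCITY_SE_FLOOR = 0.05


@dataclass(frozen=True)
class TransitionProfile:
    """Best +-1 walk of a fragment on a reference."""

    positions: tuple[int, ...]       # 1-based reference positions per letter
    times_ms: tuple[float, ...]
    fold_points: tuple[int, ...]     # letter indices where direction reverses
    directions: tuple[int, ...]      # per monotone stretch, +1/-1
    matches: int
    identity: float
    velocity: float | None           # bases/ms over monotone stretches >= 4
    velocity_se: float | None

    @property
    def read_length(self) -> int:
        """Number of distinct reference positions visited."""
        return len(set(self.positions))


def _walk_dp(letters: str, reference: str, flip_penalty: float,
             match: float = 1.0, mismatch: float = -1.0):
    """Max-score +-1 walk; returns (score, positions 0-based)."""
    m, n = len(letters), len(reference)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    frag = np.frombuffer(letters.encode(), dtype=np.uint8)
    # score[i, p, d]: best walk over letters[:i+1] ending at p with last step d
    # d=0 -> arrived via +1, d=1 -> arrived via -1 (i=0: both equal, no step)
    NEG = -1e18
    score = np.full((m, n, 2), NEG)
    back = np.zeros((m, n, 2), dtype=np.int8)  # previous d
    s0 = np.where(frag[0] == ref, match, mismatch).astype(float)
    score[0, :, 0] = s0
    score[0, :, 1] = s0
    for i in range(1, m):
        emit = np.where(frag[i] == ref, match, mismatch).astype(float)
        for d, step in ((0, +1), (1, -1)):
            # arriving at p via step means previous position p - step
            prev_same = np.full(n, NEG)
            prev_flip = np.full(n, NEG)
            if step == +1:
                prev_same[1:] = score[i - 1, :-1, 0]
                prev_flip[1:] = score[i - 1, :-1, 1]
            else:
                prev_same[:-1] = score[i - 1, 1:, 1]
                prev_flip[:-1] = score[i - 1, 1:, 0]
            prev_flip = prev_flip - flip_penalty
            take_flip = prev_flip > prev_same
            best_prev = np.where(take_flip, prev_flip, prev_same)
            score[i, :, d] = best_prev + emit
            back[i, :, d] = np.where(take_flip, 1 - d, d)
    flat = score[m - 1].ravel()
    j = int(np.argmax(flat))
    p, d = divmod(j, 2)
    best = float(flat[j])
    pos = [0] * m
    pos[m - 1] = p
    for i in range(m - 1, 0, -1):
        prev_d = int(back[i, p, d])
        p = p - (1 if d == 0 else -1)
        d = prev_d
        pos[i - 1] = p
    return best, pos


def find_transition_points(
    fragment: Fragment | str,
    reference: str,
    *,
    min_identity: float = 0.6,
    flip_penalty: float = 0.25,
    min_stretch: int = 4,
    time_quantization_ms: float = 0.5,
) -> TransitionProfile | None:
    """Align a fragment to the best +-1 walk on ``reference``.

    Letter matches score +1, mismatches -1; a small ``flip_penalty``
    per direction change canonicalizes ties toward monotone walks without
    suppressing genuine folds. Returns ``None`` (unalignable) when the
    best walk matches fewer than ``min_identity`` of the letters; such
    fragments are excluded from velocity statistics.
    """
    if isinstance(fragment, Fragment):
        letters, times = fragment.sequence, fragment.times_ms
    else:
        letters, times = fragment, tuple(float(i) for i in range(len(fragment)))
    if not letters:
        return None
    _, pos0 = _walk_dp(letters, reference, flip_penalty)
    matches = sum(1 for c, p in zip(letters, pos0) if reference[p] == c)
    identity = matches / len(letters)
    if identity < min_identity:
        return None
    positions = tuple(p + 1 for p in pos0)

    steps = [b - a for a, b in zip(positions, positions[1:])]
    folds = tuple(i + 1 for i, (a, b) in enumerate(zip(steps, steps[1:])) if a != b)
    directions = tuple(steps[i] for i in (0, *folds)) if steps else ()

    # velocity: weighted LS slope of position vs time over monotone stretches
    stretch_slopes, stretch_vars = [], []
    start = 0
    for cut in list(folds) + [len(letters) - 1]:
        sl = slice(start, cut + 1)
        t = np.asarray(times[sl], float)
        y = np.asarray(positions[sl], float)
        if t.size >= min_stretch:
            A = np.vstack([t, np.ones_like(t)]).T
            coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            slope = abs(float(coef[0]))
            sxx = float(((t - t.mean()) ** 2).sum())
            dof = t.size - 2
            s2 = float(res[0]) / dof if (dof > 0 and res.size) else 0.0
            # letter times are quantized to the calling interval; an
            # apparently perfect fit is still uncertain at that scale
            s2_quant = slope ** 2 * time_quantization_ms ** 2 / 12.0
            var = (s2 + s2_quant) / sxx if sxx > 0 else np.inf
            stretch_slopes.append(slope)
            stretch_vars.append(var)
        start = cut
    if stretch_slopes:
        w = 1.0 / (np.asarray(stretch_vars) + VELOCITY_SE_FLOOR ** 2)
        velocity = float(np.sum(w * stretch_slopes) / w.sum())
        velocity_se = float(np.sqrt(1.0 / w.sum()))
    else:
        velocity = velocity_se = None
    return TransitionProfile(positions, tuple(times), folds, directions,
                             matches, identity, velocity, velocity_se)


# --------------------------------------------------------------------------
# reference-free unfolding


def _mirror_span(s: str, center: int, max_mismatch: int,
                 mismatch_min_span: int) -> tuple[int, int]:
    """Longest j with s[center+1..center+j] mirroring s[center-1..center-j].

    Mismatches are only usable when the resulting span reaches
    ``mismatch_min_span``; shorter spans must mirror exactly (this keeps
    short accidental near-palindromes in correct reads from being folded
    away). Returns ``(span, limit)`` where ``limit`` is the largest span
    geometrically possible at this center — a span that saturates its
    limit means the mirror runs into a fragment end.
    """
    limit = min(center, len(s) - 1 - center)
    mm = 0
    span_exact = 0
    span_mm = 0
    for j in range(1, limit + 1):
        if s[center + j] != s[center - j]:
            mm += 1
            if mm > max_mismatch:
                break
        if mm == 0:
            span_exact = j
        span_mm = j
    if span_mm >= mismatch_min_span and mm <= max_mismatch:
        return span_mm, limit
    return span_exact, limit


def _even_mirror_span(s: str, edge: int) -> tuple[int, int]:
    """Exact even mirror about the boundary before index ``edge``:
    ``s[edge+j] == s[edge-1-j]`` for j = 0..span-1.

    An even mirror is the signature of a fold whose turning letters were
    merged by run splitting (a reversal over a repeated base reads
    ...b|b... back as a single run), which erases the odd-mirror pattern.
    """
    limit = min(edge, len(s) - edge)
    span = 0
    for j in range(limit):
        if s[edge + j] != s[edge - 1 - j]:
            break
        span = j + 1
    return span, limit


def unfold_palindrome(
    fragment: Fragment | str,
    *,
    min_span: int = 3,
    max_mismatch: int = 0,
    mismatch_min_span: int = 5,
    terminal_min_span: int = 3,
) -> Fragment | str:
    """Linearize folded readouts by removing mirrored duplicate spans.

    A fold at letter f re-reads the preceding bases, so the letters after
    f mirror those before it: about a letter (odd mirror) or, when the
    turning letters were merged by run splitting, about a boundary (even
    mirror). The longest mirrored span (>= ``min_span``; mismatches
    allowed only for odd spans >= ``mismatch_min_span``) is deduplicated
    — the prefix up to the fold is kept, the mirror and everything after
    it dropped, since post-mirror letters re-read earlier bases in the
    reversed direction — and the search repeats until no fold remains,
    which makes the operation idempotent. A mirror that saturates a
    fragment end (a reversal right at the end of the read, leaving a
    short duplicated stub) is accepted from ``terminal_min_span``
    letters (default also 3: short genuine palindromes such as GTTG and
    GTATG occur in the family). Fragments without a mirrored span are
    returned unchanged.
    """
    def find_fold(s: str):
        """Best right-side fold: (first mirrored index, span) or None.

        The terminal floor applies only to mirrors that run into the
        RIGHT end of the string (a reversal at the end of the read). Both
        floors default to 3: the 4-letter even palindrome GTTG and the
        5-letter odd palindrome GTATG occur genuinely in the let-7
        family, so span-2 terminal mirrors cannot be trusted.
        """
        n = len(s)
        best = None
        for f in range(1, n - 1):
            m, _ = _mirror_span(s, f, max_mismatch, mismatch_min_span)
            floor = terminal_min_span if f + m == n - 1 else min_span
            if m >= floor and (best is None or m > best[1]):
                best = (f + 1, m)
        for e in range(1, n):
            m, _ = _even_mirror_span(s, e)
            floor = max(min_span, 3)
            if m >= floor and (best is None or m > best[1]):
                best = (e, m)
        return best

    is_frag = isinstance(fragment, Fragment)
    orig = fragment.sequence if is_frag else fragment
    keep = list(range(len(orig)))
    s = orig
    while True:
        fold = find_fold(s)
        if fold is not None:
            keep = keep[: fold[0]]
            s = s[: fold[0]]
            continue
        # prefix stubs: a reversal right after the read began shows up as
        # a left-saturating mirror, i.e. a right-side fold of the
        # reversed string
        fold = find_fold(s[::-1])
        if fold is not None:
            keep = keep[len(s) - fold[0]:]
            s = s[len(s) - fold[0]:]
            continue
        break
    if not is_frag:
        return s
    if len(s) == len(orig):
        return fragment
    return Fragment(s,
                    tuple(fragment.times_ms[i] for i in keep),
                    tuple(fragment.norm_conductances[i] for i in keep),
                    tuple(fragment.qualities[i] for i in keep),
                    fragment.segment_id, fragment.trace_id)


# --------------------------------------------------------------------------
# velocity pooling


def estimate_velocity(
    profiles: list[TransitionProfile],
    *,
    n_boot: int = 1000,
    seed: int = 0,
    min_profiles: int = 5,
) -> tuple[float, tuple[float, float]]:
    """Pooled translocation velocity (bases/ms) with bootstrap 95% CI.

    Inverse-variance-weighted mean of per-profile slopes (with the
    quantization floor on each standard error); the confidence interval is
    the 2.5/97.5 percentile over ``n_boot`` seeded resamples of profiles.
    """
    vs = np.array([p.velocity for p in profiles if p.velocity is not None])
    ses = np.array([p.velocity_se for p in profiles if p.velocity is not None])
    if vs.size < min_profiles:
        raise InsufficientDataError(
            f"need >= {min_profiles} alignable profiles with a velocity, "
            f"got {vs.size}"
        )
    w = 1.0 / (ses ** 2 + VELOCITY_SE_FLOOR ** 2)
    pooled = float(np.sum(w * vs) / w.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vs.size, size=(n_boot, vs.size))
    bw = w[idx]
    boot = (bw * vs[idx]).sum(axis=1) / bw.sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return pooled, (float(lo), float(hi))


__all__ = [
    "TransitionProfile",
    "find_transition_points",
    "unfold_palindrome",
    "estimate_velocity",
    "VELOCITY_SE_FLOOR",
]
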