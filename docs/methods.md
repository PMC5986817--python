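# Methods

## The measurement being modeled

A nanogap electrode pair reads single DNA bases by tunneling current:
while a base resides in the gap the conductance sits at a base-specific
level, and a molecule diffusing through the gap produces a spike-like
event whose internal levels encode a short stretch of sequence. The
package implements the computational side of that experiment — event
detection, base calling, reading-direction analysis, assembly and
two-variant quantitation — plus a simulator that stands in for raw
recordings, which are not available.

All defaults describe DNA analogues of the let-7 microRNA family:
22-base molecules over the alphabet {T, A, G} (the family contains no
cytosine), identical except for one base at position 19 (let-7c), 9
(let-7e) or 12 (let-7f) relative to let-7a.

## Simulator

**Conductance model.** Per-base Gaussian levels with means 45 / 77 /
102 pS (T / A / G) and a baseline at 0 pS after correction. The per-base
standard deviation defaults to 8 pS and the baseline to 4 pS; these two
are plumbing defaults chosen so that the 6σ detection threshold
(~24 pS) sits well below the lowest base level while single-interval
calls still make occasional errors, and both are configurable.

**Translocation model.** Dwell per base is exponential above a hard
0.5-ms floor with mean 1/1.5 ms, reproducing the minimum retention time
and the ~1.5 bases/ms mean velocity; the memoryless dwell is the
standard single-molecule assumption. Read length (number of distinct
bases sensed) is geometric with p = 0.3, truncated at 12 — the observed
exponential decay with a 12-base maximum; p is chosen so that most
fragments are short and roughly a quarter reach the 5-base assembly
threshold, matching the qualitative statement that most fragments are
too short to assemble. Entry from the 3′ or 5′ end is equiprobable, and
the reading direction flips with per-step probability 0.05 (reversals
are reported qualitatively in the source experiments without a rate;
the value produces folded reads regularly without dominating).
Inter-event gaps are exponential with mean 25 ms; the physical
experiment is sparser (~1000 signals per chip), but gap statistics only
set the trace length per event, and 25 ms keeps simulations compact
while leaving the baseline estimator plenty of molecule-free samples.

**What the simulator does not emulate.** Gap-distance drift and the
break-junction formation cycle; 1/f and instrument noise shapes
(baseline noise is white Gaussian, optionally with a slow sinusoidal
drift); sequence-dependent dwell times; inter-molecule interactions.
Consequently, passing tests demonstrate that the *algorithms* recover
the modeled statistical structure, not that the instrument physics is
captured.

## Detection

Baseline: centered moving average of 2000 samples with truncated edge
windows. σ per second: each 10 000-sample block is divided into 500
20-sample windows; the block's σ is the mode of their sample standard
deviations (histogram mode, Freedman–Diaconis bin width, ties toward
the smaller σ). The mode makes the estimate robust to the small
fraction of windows containing events. Hysteresis: a segment opens at
the first sample above 6σ, extends back to just after the last sample
≤1σ and forward until the signal drops below 1σ; segments shorter than
the 0.5-ms minimum retention are discarded. Because events inflate the
raw moving average, detection runs twice: the second pass recomputes
the baseline with detected segments replaced by linear interpolation.
The σ of the second in which the 6σ crossing occurs applies to the
whole segment.

## Base calling

The pooled histogram (1-pS bins) of median-filtered segment samples is
fitted by nonlinear least squares with one Gaussian per base plus a
baseline component; components are initialized at the most prominent
histogram maxima and each mean is bounded halfway toward its
neighbors, which prevents a mass-less component (the baseline, when
segments carry no baseline samples) from drifting onto a base peak.
Ascending fitted means map to baseline, T, A, G.

Interval calling integrates each label's probability density over the
0.5-ms interval (sum of densities across samples, equal priors) and
takes the argmax. Integration rather than a log-likelihood product is
essential: an interval straddling a base transition contains samples at
two levels, and a product would assign it to the *intermediate* level —
particularly damaging here because the adenine mean (77 pS) lies almost
exactly at the G/T midpoint (73.5 pS). For the same reason the interval
grid's phase (arbitrary relative to the segment start) is chosen per
segment to maximize mean calling confidence, aligning intervals with
conductance plateaus.

Runs of identical labels become `max(1, round(duration / (1/1.5 ms)))`
letters, ties at .5 rounding down; run boundaries are first refined to
sample resolution by a local two-level change-point fit, because the
0.5-ms grid cannot distinguish one slow base from two quick repeated
bases. Per-letter normalized conductance is the median over the run
interior divided by the fitted G mean (the median avoids the bias that
transition-contaminated boundary samples would add toward the middle of
the conductance range); per-letter quality is the run's mean posterior.

## Transition points, unfolding, velocity

Fragments are aligned to the best walk on a reference that steps ±1
position per letter (dynamic programming; match +1, mismatch −1, and a
0.25 penalty per direction change that canonicalizes ties toward
monotone walks). Walks matching fewer than 60% of letters are
unalignable. Velocity is fitted per monotone stretch of ≥4 letters by
least squares; stretch variances include a term for the 0.5-ms
quantization of letter times (otherwise stretches whose runs all
quantized to the same duration appear noise-free at a biased slope and
dominate the inverse-variance pooling); profiles pool by inverse
variance with a 0.05 bases/ms floor, and the confidence interval is a
seeded bootstrap over profiles.

Reference-free unfolding removes mirrored spans: a reversal at letter f
makes subsequent letters mirror the preceding ones, either about a
letter (odd mirror) or about a boundary when the turning letters merged
during run splitting (even mirror). Odd spans ≥3 (≥2 when the mirror
runs into a fragment end), even spans ≥3; everything from the mirror
onward is dropped, since post-mirror letters re-read earlier bases in
the reversed direction. The terminal relaxation is safe for this family
because none of the four references contains the 5-letter odd palindrome
a genuine read would need to mimic a terminal fold; even mirrors need
span 3 everywhere because the 4-letter even palindrome GTTG *does* occur
genuinely. A prefix stub (reversal just after reading began) is the same
pattern on the reversed string and is handled symmetrically.

## Assembly

Fragments of ≥5 letters are unfolded, deduplicated into weighted
bundles, and merged greedily into a growing layout: containments and
longest overlaps first, consensus re-voted after every merge so isolated
miscalls stay minority votes. Placements are ungapped when exact;
interior placements also accept a gap-tolerant semi-global alignment
(match +1, mismatch −1, gap −2), because the caller's dominant error
mode is run-length (a repeated base split once too often or merged) and
ungapped matching cannot place such reads. Alignments that skip a
consensus column cast a deletion vote; columns whose deletion votes
outweigh their letter votes drop out. Extensions past either layout end
must dovetail exactly, anchor at least as many letters as they overhang,
and rest on the multiply-supported core — otherwise one miscalled
fragment seeds a junk arm that recruits leftovers. Genuinely tied
placements (the GTAG/AGGT repeats of this family) are resolved by
rolling each option out greedily and keeping the outcome that places the
most fragments, within a bounded budget.

For the let-7 assay the molecule length is known (22 bases), and the
pipeline uses it: the final consensus is the 22-base sequence maximizing
the total placement score of all fragments, found by a deterministic
search (grow supported letters / select the best window / sweep single
substitutions, indels and terminal-block reversals) from multi-start
initials, after which the layout is rebuilt on the selected sequence.
This matters because two failure modes of reference-free consensus are
otherwise unresolvable at realistic coverage: correlated miscalls
(G↔T straddle intervals reading as A) can outvote the thin coverage at
the molecule ends, and fold stubs echo repeat content into spurious
terminal arms whose coverage matches genuine end coverage. Without a
target length (`target_length=None`) the assembler still returns the
trimmed greedy layout, which is exact on clean reads.

The 18 five-letter windows of let-7a admit two layout-equivalent
superstrings (the repeats commute), so window-tiling tests assert the
layout properties rather than one literal string; longer fragments pin
the repeat order, which is why simulated assemblies are exact.

A plurality-consensus error calculator (`consensus_error_rate`) is
provided as a Monte-Carlo diagnostic of how per-position consensus
error falls with coverage at a given per-letter accuracy; no claim is
made about any particular instrument's coverage–error relation.

## Quantitation

Two variants differing at one base share a scaffold; a fragment is
counted when it is ≥5 letters, places at exactly one scaffold offset in
either orientation (mismatch allowed only at the marker), and spans the
marker. Ambiguous placements (possible on the repetitive GTAGTAG
region) are rejected rather than fractionally counted; marker letters
matching neither variant are tallied separately and excluded. The ratio
is normalized so the smaller side is 1.0; the interval is a seeded
bootstrap over accepted fragments. Mixture heat maps lay accepted
fragments out at their known scaffold placements and report both marker
letters' weights and conductance levels.

## Problem sizes and numerical choices

Defaults: 10 kHz sampling, 0.1 V bias, thresholds 6σ/1σ, windows
2000/20-sample, interval 0.5 ms, minimum fragment 5, minimum overlap 4,
trim fraction 0.05. Simulation sizes used by the tests and the
acceptance script: 1200 events for peak/velocity recovery, 2000 events
per reference for whole-sequence assembly, 10 000 events for the
read-length statistic, 200 replicates of 400 events per fraction for
quantitation bias — sizes at which the estimators' sampling error is
well inside the tolerances they are checked against.

Read lengths are reported as the number of distinct bases visited by
the best walk, over fragments whose walk identity is ≥0.95; ambiguous
decodings drift to spuriously long walks and are not read-length
evidence. About 0.1–0.2% of detected signals are two coincident
molecules merged by the hysteresis rule, which read as one longer
event; this can add one base beyond the 12-base cap (the cap holds
exactly for the underlying translocation paths).

## Known limitations

- Exact whole-sequence recovery relies on the known marker length;
  fully de-novo consensus of these short, repeat-laden, three-letter
  molecules is not reliable at the coverages simulated here.
- The caller's per-letter error is level-structured (A sits midway
  between G and T), so errors are correlated with sequence context;
  accuracy figures measured on this simulator do not transfer to other
  level layouts.
- Velocity estimates inherit the 0.5-ms letter-time quantization; the
  pooled estimate is accurate to a few percent but per-fragment slopes
  are coarse.
- Quantitation assumes exactly two variants and a single-base marker;
  the k-variant generalization is untested.
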