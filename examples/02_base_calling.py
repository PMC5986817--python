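"""Fit the conductance histogram and call base sequences per event.

The pooled histogram of detected-signal conductances shows three peaks —
thymine near 45 pS, adenine near 77 pS, guanine near 102 pS — plus the
baseline. Each 0.5-ms interval of a segment is assigned its most probable
base by integrating the fitted probability densities, and runs of labels
are split into letters at the nominal dwell of 1/1.5 ms per base.
"""

import numpy as np

import tunnelcall as tc

trace = tc.simulate_trace(tc.LET7A, 600, seed=2, sequence_id="let-7a")
segments, _, _ = tc.detect_two_pass(trace)

fit = tc.fit_conductance_model(segments)
print("fitted peak means (pS):", np.round(fit.means, 1),
      "-> baseline, T, A, G")

fragments = tc.call_segments(segments, fit.model)
print(f"{len(fragments)} fragments called; first ten:")
for f in fragments[:10]:
    print(f"  {f.sequence:14s} mean quality "
          f"{np.mean(f.qualities):.2f}")
# Fragments are short (read lengths decay geometrically, at most 12
# bases) and may be read in either direction or fold mid-read.
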