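"""Reference sequences for the let-7 microRNA family (DNA analogues).

The four 22-base DNAs differ from let-7a at a single position each
(1-based): let-7c at 19 (A->G), let-7e at 9 (T->G), let-7f at 12 (G->A).
None of them contains cytosine, which is why the default base alphabet of
the pipeline is {T, A, G}.
"""

from __future__ import annotations

LET7A = "TGAGGTAGTAGGTTGTATAGTT"
LET7C = "TGAGGTAGTAGGTTGTATGGTT"
LET7E = "TGAGGTAGGAGGTTGTATAGTT"
LET7F = "TGAGGTAGTAGATTGTATAGTT"

LET7: dict[str, str] = {
    "let-7a": LET7A,
    "let-7c": LET7C,
    "let-7e": LET7E,
    "let-7f": LET7F,
}

#: 1-based position at which each variant differs from let-7a.
VARIANT_POSITIONS: dict[str, int] = {
    "let-7c": 19,
    "let-7e": 9,
    "let-7f": 12,
}


def _check() -> None:
    for name, pos in VARIANT_POSITIONS.items():
        diffs = [i + 1 for i, (a, b) in enumerate(zip(LET7A, LET7[name])) if a != b]
        assert diffs == [pos], (name, diffs)


_check()
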