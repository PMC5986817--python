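"""On-disk formats: text traces, FASTA sequences, fragments with sidecar
TSVs, heat-map TSVs.

Traces are two-column text (``time_s<TAB>conductance_pS``) under a
``#``-prefixed metadata header, or raw little-endian float64 with a JSON
sidecar. Fragments are FASTA plus a TSV sidecar carrying per-letter
times, normalized conductances and posteriors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .base_call import Fragment
from .errors import FormatError, InputError
from .trace_sim import Trace

_TIME_UNIFORMITY_TOL_S = 1e-9


# --------------------------------------------------------------------------
# traces


def write_trace(trace: Trace, path: str | Path, *, seed: int | None = None) -> None:
    path = Path(path)
    header = [
        "# tunnelcall trace v1",
        f"# sample_rate_hz: {trace.sample_rate_hz!r}",
        f"# bias_v: {trace.bias_v!r}",
    ]
    if seed is not None:
        header.append(f"# seed: {seed}")
    t = trace.times_s
    body = "\n".join(f"{ti:.9f}\t{x:.6f}" for ti, x in zip(t, trace.samples))
    path.write_text("\n".join(header) + "\n" + body + "\n")


def write_trace_binary(trace: Trace, path: str | Path) -> None:
    """Raw little-endian float64 samples + JSON sidecar (``<path>.json``)."""
    path = Path(path)
    trace.samples.astype("<f8").tofile(path)
    sidecar = {"sample_rate_hz": trace.sample_rate_hz, "bias_v": trace.bias_v,
               "n_samples": int(trace.samples.size), "dtype": "<f8"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(path, dtype=meta.get("dtype", "<f8"))
        return Trace(samples, sample_rate_hz=meta["sample_rate_hz"],
                     bias_v=meta.get("bias_v", 0.1))
    meta: dict[str, float] = {}
    times, vals = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        pass
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"malformed trace line: {line!r}")
            times.append(float(parts[0]))
            vals.append(float(parts[1]))
    if "sample_rate_hz" not in meta:
        raise FormatError("trace header missing required field 'sample_rate_hz'")
    sr = meta["sample_rate_hz"]
    t = np.asarray(times)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / sr) > _TIME_UNIFORMITY_TOL_S):
            raise FormatError("trace time column is not uniform at the "
                              "declared sample rate")
    return Trace(np.asarray(vals), sample_rate_hz=sr,
                 bias_v=meta.get("bias_v", 0.1))


# --------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# fragments


def write_fragments(
    fragments: list[Fragment],
    fasta_path: str | Path,
    sidecar_path: str | Path,
    *,
    alphabet: tuple[str, ...] = ("T", "A", "G"),
) -> None:
    """FASTA (letters) + TSV sidecar (per-letter metadata), ids shared."""
    rows = []
    records = []
    for i, f in enumerate(fragments):
        if not set(f.sequence) <= set(alphabet):
            raise InputError(
                f"fragment {i} has letters outside alphabet {alphabet}"
            )
        fid = f"frag_{i:06d}"
        records.append(SeqRecord(Seq(f.sequence), id=fid, description=""))
        for j in range(len(f)):
            rows.append((fid, j, f.sequence[j], f.times_ms[j],
                         f.norm_conductances[j], f.qualities[j]))
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(rows, columns=["id", "letter_index", "letter", "time_ms",
                                "norm_conductance", "posterior"]
                 ).to_csv(sidecar_path, sep="\t", index=False)


def read_fragments(fasta_path: str | Path, sidecar_path: str | Path
                   ) -> list[Fragment]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(sidecar_path, sep="\t")
    if set(table["id"]) != set(seqs):
        raise FormatError("FASTA and sidecar fragment ids do not match")
    out = []
    for fid in seqs:
        sub = table[table["id"] == fid].sort_values("letter_index")
        if "".join(sub["letter"]) != seqs[fid]:
            raise FormatError(f"sidecar letters disagree with FASTA for {fid}")
        out.append(Fragment(seqs[fid],
                            tuple(sub["time_ms"]),
                            tuple(sub["norm_conductance"]),
                            tuple(sub["posterior"])))
    return out


# --------------------------------------------------------------------------
# tables


def write_heatmap(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_truth_tsv(trace: Trace, path: str | Path) -> None:
    """Ground-truth events of a simulated trace as TSV."""
    if trace.events is None:
        raise InputError("trace has no ground-truth annotations")
    rows = [(i, e.start, e.end, e.sequence_id, e.entry_end)
            for i, e in enumerate(trace.events)]
    pd.DataFrame(rows, columns=["event_id", "start_index", "end_index",
                                "variant", "entry_end"]
                 ).to_csv(path, sep="\t", index=False)


__all__ = [
    "read_trace", "write_trace", "write_trace_binary",
    "read_fasta", "write_fasta",
    "read_fragments", "write_fragments",
    "write_heatmap", "write_truth_tsv",
]
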