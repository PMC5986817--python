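"""End-to-end pipeline: simulate/load traces -> detect -> call ->
analyze -> assemble -> quantify, with per-stage counts and a
machine-readable summary."""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np

from . import io as tcio
from .assemble import greedy_assemble, heatmap_table
from .base_call import call_segments, fit_conductance_model
from .config import PipelineConfig
from .errors import InsufficientDataError, TunnelcallError
from .fragment_analysis import (estimate_velocity, find_transition_points,
                                unfold_palindrome)
from .quantify import MarkerSpec, count_markers
from .signal_detect import detect_two_pass
from .trace_sim import Trace, simulate_mixture

log = logging.getLogger("tunnelcall")


def process_trace(trace: Trace, config: PipelineConfig, *,
                  trace_id: str | None = None):
    """Detect, fit and call one trace. Returns (fragments, fit, segments)."""
    segments, _, _ = detect_two_pass(
        trace,
        baseline_window=config.baseline_window,
        rise_sigma=config.rise_sigma,
        fall_sigma=config.fall_sigma,
        min_duration_ms=config.min_retention_ms,
    )
    log.info("detect: %d segments", len(segments))
    if not segments:
        raise InsufficientDataError("no signal segments detected")
    fit = fit_conductance_model(
        segments,
        n_bases=config.n_bases,
        labels_by_rank=tuple(config.labels_by_rank),
        sample_rate_hz=config.sample_rate_hz,
    )
    log.info("fit: base means %s pS",
             np.round(fit.base_means, 2).tolist())
    fragments = call_segments(
        segments, fit.model,
        interval_ms=config.interval_ms,
        expected_dwell_ms=config.expected_dwell_ms,
        sample_rate_hz=config.sample_rate_hz,
        trace_id=trace_id,
    )
    log.info("call: %d fragments from %d segments", len(fragments),
             len(segments))
    return fragments, fit, segments


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    *,
    trace_paths: list[str | Path] | None = None,
    simulate: dict | None = None,
    reference: str | None = None,
    marker: MarkerSpec | None = None,
) -> dict:
    """Execute the full pipeline and write the report files.

    Either ``trace_paths`` (existing trace files) or ``simulate`` (a dict
    with keys ``variants`` (name -> sequence), ``fractions`` and
    ``n_events``) must be given. Writes consensus FASTA, heat-map TSV,
    read-length histogram TSV, quantitation JSON (when ``marker`` is
    given) and a summary JSON; returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_seed": config.seed, "stages": {}}

    if simulate is not None:
        trace = simulate_mixture(
            simulate["variants"], simulate["fractions"], simulate["n_events"],
            config.seed,
            tmodel=config.translocation_model(),
            cmodel=config.conductance_model(),
            sample_rate_hz=config.sample_rate_hz,
        )
        traces = [("simulated", trace)]
        tcio.write_truth_tsv(trace, out / "truth_events.tsv")
    elif trace_paths:
        traces = [(Path(p).stem, tcio.read_trace(p)) for p in trace_paths]
    else:
        raise InsufficientDataError("no traces given: nothing to detect")

    fragments = []
    for name, trace in traces:
        frags, fit, segments = process_trace(trace, config, trace_id=name)
        fragments.extend(frags)
        summary["stages"].setdefault("detect", {})[name] = len(segments)
        summary.setdefault("fitted_means_ps", {})[name] = [
            round(float(m), 3) for m in fit.base_means
        ]
    summary["stages"]["fragments"] = len(fragments)

    # read-length histogram (letters after unfolding)
    unfolded = [unfold_palindrome(f) for f in fragments]
    lengths = Counter(len(f) for f in unfolded)
    with (out / "read_length_histogram.tsv").open("w") as fh:
        fh.write("length\tcount\n")
        for L in sorted(lengths):
            fh.write(f"{L}\t{lengths[L]}\n")
    summary["max_read_length"] = max(lengths) if lengths else 0

    # velocity (needs a reference)
    if reference is not None:
        profiles = [p for f in fragments
                    if (p := find_transition_points(f, reference)) is not None]
        summary["stages"]["alignable_fragments"] = len(profiles)
        try:
            v, ci = estimate_velocity(profiles, seed=config.seed)
            summary["velocity_bases_per_ms"] = round(v, 4)
            summary["velocity_ci95"] = [round(ci[0], 4), round(ci[1], 4)]
        except InsufficientDataError as exc:
            summary["velocity_bases_per_ms"] = None
            log.warning("velocity: %s", exc)

    # assembly
    try:
        profile = greedy_assemble(
            fragments,
            min_fragment_len=config.min_fragment_len,
            min_overlap=config.min_overlap,
            max_mismatch=config.max_mismatch,
            trim_end_frac=config.trim_end_frac,
            target_length=config.target_length,
        )
        summary["consensus"] = profile.sequence
        summary["consensus_length"] = len(profile.sequence)
        summary["min_coverage"] = int(profile.coverage.min())
        summary["stages"]["assembly"] = profile.diagnostics
        tcio.write_fasta({"consensus": profile.sequence}, out / "consensus.fasta")
        tcio.write_heatmap(heatmap_table(profile), out / "heatmap.tsv")
    except TunnelcallError as exc:
        summary["consensus"] = None
        log.warning("assembly: %s", exc)

    # quantitation
    if marker is not None:
        try:
            q = count_markers(fragments, marker,
                              min_len=config.min_fragment_len,
                              seed=config.seed)
            quant = {
                "counts": q.counts,
                "ratio": list(q.ratio),
                "ci95_fraction": list(q.ci95),
                "n_used": q.n_used,
                "rejections": q.rejections,
            }
            (out / "quantitation.json").write_text(json.dumps(quant, indent=2))
            summary["quantitation"] = quant
        except InsufficientDataError as exc:
            summary["quantitation"] = None
            log.warning("quantitation: %s", exc)

    tcio.write_fragments(fragments, out / "fragments.fasta",
                         out / "fragments.tsv")
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return summary


__all__ = ["process_trace", "run_pipeline"]
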