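"""High-level orchestration of the two analysis phases.

Phase I takes a raw trace to the representative averaged complex: low-pass
filter, beat detection, windowing, template selection, correlation
classification, ensemble averaging.  Phase II measures the averaged
waveform: onset, trapezium-area offset, FPD/cFPD/AUC.  Both functions are
thin compositions of the module operations — the CLI and the tests call the
same code paths — and record every parameter in the waveform provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fpd_metrics, preprocess, template_matching
from .io_mea import AveragedWaveform, Recording
from .template_matching import CorrelationReport, ExtractionResult, Template

__all__ = ["Phase1Result", "run_phase1", "run_phase2"]


@dataclass
class Phase1Result:
    waveform: AveragedWaveform
    report: CorrelationReport
    extraction: ExtractionResult
    template: Template
    beating_rate_bpm: float
    filtered: np.ndarray


def run_phase1(
    recording: Recording,
    electrode: str,
    cf: float = 0.98,
    template: str | int = "default",
    window_ms: float | str = "auto",
    max_lag_ms: float = 2.0,
    filter_order: int = 5,
    filter_cutoff: float = 200.0,
    threshold: float | str = "auto",
    refractory_ms: float = 200.0,
    normalization: str = "pearson",
    combiner: str = "mean",
    source: dict | None = None,
) -> Phase1Result:
    """Raw recording -> representative averaged field-potential complex."""
    trace = recording.trace(electrode)
    filtered = preprocess.lowpass_filter(
        trace, recording.sample_rate, order=filter_order, cutoff=filter_cutoff
    )
    peaks = preprocess.detect_peaks(
        filtered, recording.sample_rate, threshold=threshold, refractory_ms=refractory_ms
    )
    stats = preprocess.beat_statistics(peaks, recording.sample_rate)
    extraction = template_matching.extract_complexes(
        filtered, peaks, recording.sample_rate, window_ms=window_ms
    )
    tmpl = template_matching.select_template(
        extraction, mode=template, trace_length=len(trace), electrode=electrode
    )
    max_lag = int(round(max_lag_ms / 1000.0 * recording.sample_rate))
    report = template_matching.classify_complexes(
        extraction, tmpl, cf=cf, max_lag=max_lag, normalization=normalization
    )
    src = dict(source or {})
    src.update(
        {
            "electrode": electrode,
            "template_mode": tmpl.mode,
            "template_index": tmpl.index,
            "beating_rate_bpm": stats["beating_rate"],
            "min_interval_ms": stats["min_interval"],
            "filter_order": filter_order,
            "filter_cutoff_hz": filter_cutoff,
            "refractory_ms": refractory_ms,
            "max_lag_ms": max_lag_ms,
            "normalization": normalization,
            "n_dropped_edge": extraction.n_dropped,
        }
    )
    waveform = template_matching.ensemble_average(
        report, extraction, recording.sample_rate, combiner=combiner, source=src
    )
    return Phase1Result(
        waveform=waveform,
        report=report,
        extraction=extraction,
        template=tmpl,
        beating_rate_bpm=stats["beating_rate"],
        filtered=filtered,
    )


def run_phase2(
    waveform: AveragedWaveform,
    beating_rate: float | None = None,
    onset: float | str = "auto",
    offset: float | str = "auto",
    frame_ms: float = 10.0,
    k: float = 3.0,
) -> fpd_metrics.FPDMeasurement:
    """Averaged waveform -> FPD measurement (auto or manual landmarks)."""
    return fpd_metrics.analyze_waveform(
        waveform, beating_rate=beating_rate, onset=onset, offset=offset,
        frame_ms=frame_ms, k=k,
    )
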