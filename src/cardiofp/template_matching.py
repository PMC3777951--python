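"""Template-based classification and ensemble averaging of field-potential complexes.

Each detected beat is windowed into an :class:`FPComplex` (window centred on
the depolarisation peak; window length defaults to the smallest beat-to-beat
interval so adjacent complexes never leak into the correlation interval).
One complex — by default the one nearest the centre of the recording — serves
as the template; every complex is scored against it by a lag-searched
correlation coefficient, accepted when the coefficient reaches the
user-chosen correlation factor (CF), and the accepted complexes are
ensemble-averaged after lag alignment to yield the representative waveform.

Two coefficient normalisations are available.  The default is Pearson-type
(mean-removed, amplitude-normalised, so c is in [-1, 1] and CF thresholds
like 0.98 are portable across recordings); ``normalization="raw"`` gives the
plain 1/N product sum for fidelity with the classical formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    InsufficientDataError,
    LookupError_,
    ParameterError,
    UndefinedCorrelationError,
)
from .io_mea import AveragedWaveform
from .preprocess import PeakTrain

__all__ = [
    "FPComplex",
    "Template",
    "ComplexEntry",
    "CorrelationReport",
    "ExtractionResult",
    "extract_complexes",
    "select_template",
    "correlation_coefficient",
    "classify_complexes",
    "ensemble_average",
]


@dataclass
class FPComplex:
    """One windowed field-potential beat.

    ``start`` is the global sample index of the window's first sample;
    ``peak_local`` the depolarisation-peak position inside the window
    (within one sample of the centre).
    """

    samples: np.ndarray
    start: int
    peak_local: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n = len(self.samples)
        if not 0 <= self.peak_local < n:
            raise ValueError("peak_local outside window")
        if abs(self.peak_local - n / 2) > 1:
            raise ValueError("window must be centred on the peak (+/- 1 sample)")

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass
class Template:
    """The comparison standard: a complex plus how it was selected."""

    complex: FPComplex
    mode: str  # "default-centre" | "manual index"
    index: int  # position in the complex list it was drawn from
    electrode: str | None = None

    @property
    def samples(self) -> np.ndarray:
        return self.complex.samples


@dataclass
class ComplexEntry:
    """Per-complex correlation outcome."""

    coefficient: float
    best_lag: int
    accepted: bool
    undefined: bool = False  # zero-variance operand: rejected with a flag


@dataclass
class CorrelationReport:
    """Scores and accept/reject labels for every complex, in input order."""

    entries: list[ComplexEntry]
    cf: float
    max_lag: int

    @property
    def accepted_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.accepted]

    @property
    def n_accepted(self) -> int:
        return len(self.accepted_indices)

    @property
    def n_rejected(self) -> int:
        return len(self.entries) - self.n_accepted

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([e.coefficient for e in self.entries])

    @property
    def accepted_flags(self) -> np.ndarray:
        return np.array([e.accepted for e in self.entries], dtype=bool)


@dataclass
class ExtractionResult:
    """Complexes plus bookkeeping from the windowing step."""

    complexes: list[FPComplex]
    n_dropped: int  # beats whose window fell off the trace edge
    window_samples: int

    def __iter__(self):
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    def __getitem__(self, i):
        return self.complexes[i]


def extract_complexes(
    trace: np.ndarray,
    peaks: PeakTrain,
    sample_rate: float,
    window_ms: float | str = "auto",
) -> ExtractionResult:
    """Cut one centred window per detected beat.

    ``window_ms="auto"`` uses the smallest beat-to-beat interval, which keeps
    the correlation interval free of the neighbouring complex while covering
    as much of the beat as possible.  Beats whose full window does not fit
    inside the trace are dropped and counted.
    """
    trace = np.asarray(trace, dtype=float)
    if window_ms == "auto":
        if len(peaks) < 2:
            raise InsufficientDataError(
                "auto window needs >= 2 peaks to measure a beat-to-beat interval"
            )
        n = int(np.min(np.diff(peaks.indices)))
    else:
        n = int(round(float(window_ms) / 1000.0 * sample_rate))
    if n < 2:
        raise ParameterError(f"window of {n} samples is too small")
    if n > len(trace):
        raise ParameterError(
            f"window of {n} samples exceeds the trace length {len(trace)}"
        )
    half = n // 2
    complexes: list[FPComplex] = []
    dropped = 0
    for p in peaks.indices:
        start = int(p) - half
        if start < 0 or start + n > len(trace):
            dropped += 1
            continue
        complexes.append(
            FPComplex(samples=trace[start : start + n].copy(), start=start, peak_local=half)
        )
    return ExtractionResult(complexes=complexes, n_dropped=dropped, window_samples=n)


def select_template(
    complexes: list[FPComplex] | ExtractionResult,
    mode: str | int = "default",
    trace_length: int | None = None,
    electrode: str | None = None,
) -> Template:
    """Pick the template complex.

    ``mode="default"`` selects the complex whose start is nearest the middle
    of the recording (ties go to the earlier one) — the beat at the centre of
    the total recording duration.  An integer selects that complex directly
    (0-based).  ``trace_length`` is required for the default mode.
    """
    if isinstance(complexes, ExtractionResult):
        complexes = complexes.complexes
    if not complexes:
        raise InsufficientDataError("no complexes to select a template from")
    if mode == "default":
        if trace_length is None:
            raise ParameterError("default template selection needs trace_length")
        mid = trace_length / 2.0
        dists = [abs(c.start - mid) for c in complexes]
        idx = int(np.argmin(dists))  # argmin takes the first -> earlier on ties
        return Template(complex=complexes[idx], mode="default-centre", index=idx, electrode=electrode)
    idx = int(mode)
    if not 0 <= idx < len(complexes):
        raise LookupError_(
            f"template index {idx} out of range (have {len(complexes)} complexes)"
        )
    return Template(complex=complexes[idx], mode="manual index", index=idx, electrode=electrode)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(np.dot(a, a))
    nb = np.sqrt(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError("zero-variance operand")
    return float(np.dot(a, b) / (na * nb))


def correlation_coefficient(
    x1: FPComplex | np.ndarray,
    x2: FPComplex | np.ndarray,
    max_lag: int = 0,
    normalization: str = "pearson",
) -> tuple[float, int]:
    """Lag-searched similarity between two equal-length complexes.

    Returns ``(c, best_lag)`` where ``c`` is the maximum over lags
    ``|n| <= max_lag`` of the coefficient between ``x1`` and ``x2`` delayed
    by ``n`` samples, computed on the overlapping segment.  A positive
    ``best_lag`` means ``x2`` lags (is delayed relative to) ``x1``.
    Ties prefer the smaller ``|lag|``, then the negative lag.

    With ``normalization="pearson"`` both operands are mean-removed and
    amplitude-normalised, so ``c`` lies in [-1, 1].  ``"raw"`` gives the
    unnormalised-amplitude 1/N product sum.
    """
    a = x1.samples if isinstance(x1, FPComplex) else np.asarray(x1, dtype=float)
    b = x2.samples if isinstance(x2, FPComplex) else np.asarray(x2, dtype=float)
    if len(a) != len(b):
        raise ParameterError("complexes must have equal window length")
    n = len(a)
    if max_lag < 0 or max_lag > n // 4:
        raise ParameterError(f"max_lag must be in [0, N/4] = [0, {n // 4}]")
    if normalization not in ("pearson", "raw"):
        raise ParameterError(f"unknown normalization {normalization!r}")

    best_c = -np.inf
    best_lag = 0
    # lag order encodes the tie-break: 0, -1, +1, -2, +2, ...
    lags = [0]
    for m in range(1, max_lag + 1):
        lags.extend([-m, m])
    for lag in lags:
        # x2 delayed by `lag`: compare a[k] with b[k + lag]
        if lag >= 0:
            seg_a, seg_b = a[: n - lag], b[lag:]
        else:
            seg_a, seg_b = a[-lag:], b[: n + lag]
        if normalization == "pearson":
            c = _pearson(seg_a, seg_b)
        else:
            c = float(np.dot(seg_a, seg_b)) / n
        if c > best_c:
            best_c = c
            best_lag = lag
    return best_c, best_lag


def classify_complexes(
    complexes: list[FPComplex] | ExtractionResult,
    template: Template,
    cf: float = 0.98,
    max_lag: int = 0,
    normalization: str = "pearson",
) -> CorrelationReport:
    """Score every complex against the template; accept when ``c >= cf``.

    A complex with undefined correlation (zero variance) is rejected with a
    flag rather than aborting the run.
    """
    if isinstance(complexes, ExtractionResult):
        complexes = complexes.complexes
    if not 0.0 < cf <= 1.0:
        raise ParameterError(f"correlation factor must be in (0, 1], got {cf}")
    entries: list[ComplexEntry] = []
    for c in complexes:
        try:
            coef, lag = correlation_coefficient(template.complex, c, max_lag, normalization)
        except UndefinedCorrelationError:
            entries.append(ComplexEntry(coefficient=np.nan, best_lag=0, accepted=False, undefined=True))
            continue
        entries.append(ComplexEntry(coefficient=coef, best_lag=lag, accepted=coef >= cf))
    return CorrelationReport(entries=entries, cf=cf, max_lag=max_lag)


def ensemble_average(
    report: CorrelationReport,
    complexes: list[FPComplex] | ExtractionResult,
    sample_rate: float,
    combiner: str = "mean",
    source: dict | None = None,
) -> AveragedWaveform:
    """Pointwise mean of the accepted complexes after lag alignment.

    Each accepted complex is shifted by its best lag so the depolarisation
    peaks coincide; the output is the combiner applied over the common
    overlap of all shifted windows (full N when every lag is zero), and the
    trimming is recorded in the provenance.
    """
    if isinstance(complexes, ExtractionResult):
        complexes = complexes.complexes
    if combiner not in ("mean", "median"):
        raise ParameterError(f"unknown combiner {combiner!r}")
    idx = report.accepted_indices
    if not idx:
        raise InsufficientDataError(
            "no complexes accepted for averaging; consider lowering the "
            "correlation factor"
        )
    n = complexes[idx[0]].n
    lags = [report.entries[i].best_lag for i in idx]
    # aligned sample k of a complex delayed by lag is samples[k + lag];
    # the common valid k-range is the intersection over members
    lo = max(0, -min(lags))
    hi = n - max(0, max(lags))
    if hi - lo < 2:
        raise InsufficientDataError("lag shifts leave no common overlap to average")
    stack = np.stack(
        [complexes[i].samples[lo + lag : hi + lag] for i, lag in zip(idx, lags)]
    )
    avg = np.mean(stack, axis=0) if combiner == "mean" else np.median(stack, axis=0)
    peak = complexes[idx[0]].peak_local - lo
    src = dict(source or {})
    src.update(
        {
            "cf": report.cf,
            "max_lag": report.max_lag,
            "n_accepted": len(idx),
            "n_rejected": report.n_rejected,
            "window_samples": n,
            "overlap_samples": hi - lo,
            "trimmed_samples": n - (hi - lo),
            "combiner": combiner,
        }
    )
    return AveragedWaveform(
        samples=avg,
        sample_rate=sample_rate,
        n_ensembles=len(idx),
        peak_index=int(np.clip(peak, 0, hi - lo - 1)),
        source=src,
    )
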