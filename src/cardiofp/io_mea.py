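"""Reading MC_DataTool-style ASCII MEA exports and analysis-artifact I/O.

The ASCII dialect accepted here is the one MC_DataTool produces when a
multichannel ``.mcd`` recording is exported as text: one or more free-form
header lines, the last of which is a tab-separated row of column names
(column 1 is time, the remaining columns are electrode identifiers), followed
by tab-separated numeric rows.  Amplitudes are micro-volts.  The time column
may be in milliseconds or seconds; by default the unit is auto-detected from
the median step (steps below 1 are taken as milliseconds, consistent with
kilohertz-range sampling).

Analysis artifacts use plain-text formats: measurement tables are CSV, and
averaged waveforms are a CSV sample series plus a JSON metadata sidecar.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, LookupError_, ParseError

__all__ = [
    "Recording",
    "AveragedWaveform",
    "read_mcd_ascii",
    "write_measurements",
    "read_measurements",
    "write_waveform",
    "read_waveform",
    "MEASUREMENT_COLUMNS",
]

#: Column schema of a measurement table (one row per analysed waveform).
MEASUREMENT_COLUMNS = [
    "label",
    "onset_index",
    "offset_index",
    "onset_mode",
    "offset_mode",
    "FPD_ms",
    "cFPD_ms",
    "AUC_uV_ms",
    "beating_rate_bpm",
]


@dataclass
class Recording:
    """Multi-channel extracellular recording with a single sampling rate.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz; must be positive.
    electrodes : list of str
        Ordered, unique electrode identifiers (e.g. ``"A1"`` or ``"21"``).
    traces : dict
        Per-electrode amplitude series in µV; all the same length (≥ 2).
    """

    sample_rate: float
    electrodes: list[str]
    traces: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(set(self.electrodes)) != len(self.electrodes):
            raise ValueError("electrode identifiers must be unique")
        if set(self.electrodes) != set(self.traces):
            raise ValueError("electrodes and traces keys must agree")
        lengths = {len(v) for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must have identical length")
        if lengths and min(lengths) < 2:
            raise ValueError("traces must have length >= 2")
        self.traces = {k: np.asarray(v, dtype=float) for k, v in self.traces.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values())))

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sample_rate

    def trace(self, electrode: str) -> np.ndarray:
        if electrode not in self.traces:
            raise LookupError_(
                f"electrode {electrode!r} not in recording; "
                f"available: {sorted(self.electrodes)}"
            )
        return self.traces[electrode]

    def subset(self, electrodes: Sequence[str]) -> "Recording":
        """Recording restricted to the given electrodes, sample order untouched."""
        missing = [e for e in electrodes if e not in self.traces]
        if missing:
            raise LookupError_(
                f"electrode(s) {missing} not in recording; "
                f"available: {sorted(self.electrodes)}"
            )
        return Recording(
            sample_rate=self.sample_rate,
            electrodes=list(electrodes),
            traces={e: self.traces[e] for e in electrodes},
        )


@dataclass
class AveragedWaveform:
    """Ensemble average of accepted field-potential complexes.

    ``source`` is a free-form provenance mapping (input file, electrode,
    template id, correlation factor, beating rate, ...) carried through to
    disk so downstream analysis is traceable.
    """

    samples: np.ndarray
    sample_rate: float
    n_ensembles: int
    peak_index: int | None = None
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.n_ensembles < 1:
            raise ValueError("n_ensembles must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.sample_rate * 1000.0


def _split_header(lines: list[str]) -> tuple[int, list[str]]:
    """Locate the header block: return (index of first data line, column names).

    The last header line is the tab-separated column-name row; everything
    before it is free-form header text.  A file whose very first line parses
    as numbers has no header at all.
    """

    def is_numeric_row(line: str) -> bool:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            return False
        try:
            [float(p) for p in parts]
        except ValueError:
            return False
        return True

    first_data = None
    for i, line in enumerate(lines):
        if is_numeric_row(line):
            first_data = i
            break
    if first_data is None:
        raise ParseError("no numeric data rows found in file")
    if first_data == 0:
        raise FormatError(
            "missing header: line 1 is already numeric data; expected at "
            "least one header line ending with a tab-separated column-name row"
        )
    name_row = lines[first_data - 1].rstrip("\n").split("\t")
    names = [c.strip() for c in name_row if c.strip()]
    if len(names) < 2:
        raise FormatError(
            f"header line {first_data} does not name a time column and at "
            f"least one electrode: {lines[first_data - 1]!r}"
        )
    return first_data, names


def _clean_electrode_name(raw: str) -> str:
    """Strip unit suffixes like ``'El A1 [µV]'`` -> ``'A1'``."""
    name = raw.split("[")[0].strip()
    if name.lower().startswith("el ") or name.lower().startswith("el_"):
        name = name[3:].strip()
    return name


def read_mcd_ascii(
    path: str | Path,
    electrodes: Sequence[str] | None = None,
    *,
    time_unit: str = "auto",
    sample_rate: float | None = None,
) -> Recording:
    """Read an MC_DataTool-dialect ASCII export into a :class:`Recording`.

    Parameters
    ----------
    path : path
        ASCII file with header lines, a column-name row and tab-separated data.
    electrodes : sequence of str, optional
        Restrict the result to these electrodes (order preserved); all if None.
    time_unit : {"auto", "ms", "s"}
        Unit of the time column; ``"auto"`` treats median steps < 1 as ms.
    sample_rate : float, optional
        Override the rate inferred from the time column.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines(keepends=True)
    first_data, names = _split_header(lines)
    col_names = [names[0]] + [_clean_electrode_name(n) for n in names[1:]]

    body = "".join(lines[first_data:])
    try:
        df = pd.read_csv(
            io.StringIO(body),
            sep="\t",
            header=None,
            names=col_names,
            dtype=float,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(
            f"unparseable data in {path.name} (rows start at line "
            f"{first_data + 1}): {exc}"
        ) from exc
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise ParseError(
            f"non-numeric or missing cell at data row {bad + 1} "
            f"(file line {first_data + bad + 1})"
        )
    if len(df) < 2:
        raise ParseError(f"{path.name}: need at least 2 data rows, got {len(df)}")

    t = df[col_names[0]].to_numpy()
    steps = np.diff(t)
    med = float(np.median(steps))
    if med <= 0:
        raise ParseError("time column is not strictly increasing")
    if time_unit == "auto":
        time_unit = "ms" if med < 1.0 else "s"
    step_s = med / 1000.0 if time_unit == "ms" else med
    if sample_rate is None:
        jitter = np.max(np.abs(steps - med)) / med
        if jitter > 1e-6:
            warnings.warn(
                f"time column jitter {jitter:.2e} exceeds 1 ppm; "
                "using median step for the sample rate",
                stacklevel=2,
            )
        sample_rate = 1.0 / step_s

    available = col_names[1:]
    if electrodes is None:
        electrodes = available
    else:
        missing = [e for e in electrodes if e not in available]
        if missing:
            raise LookupError_(
                f"electrode(s) {missing} not in file header; "
                f"available: {available}"
            )
    traces = {e: df[e].to_numpy() for e in electrodes}
    return Recording(sample_rate=float(sample_rate), electrodes=list(electrodes), traces=traces)


# ---------------------------------------------------------------------------
# analysis artifacts


def write_measurements(measurements: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write a measurement table (one row per waveform) as CSV.

    Accepts a DataFrame or a sequence of mappings; missing schema columns are
    added empty so every file carries the full FPD/cFPD/AUC/BR schema.
    """
    df = pd.DataFrame(measurements)
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=float)
    df = df[MEASUREMENT_COLUMNS]
    df.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_waveform(waveform: AveragedWaveform, path: str | Path) -> None:
    """Write an averaged waveform as ``<path>`` (CSV) + ``<path>.json`` sidecar.

    The CSV holds ``time_ms, amplitude_uV``; the sidecar holds sample rate,
    ensemble count, peak index and provenance, so ``read_waveform`` restores
    the object field-for-field.
    """
    path = Path(path)
    t_ms = np.arange(len(waveform.samples)) / waveform.sample_rate * 1000.0
    pd.DataFrame({"time_ms": t_ms, "amplitude_uV": waveform.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )
    meta = {
        "sample_rate": waveform.sample_rate,
        "n_ensembles": waveform.n_ensembles,
        "peak_index": waveform.peak_index,
        "n_samples": len(waveform.samples),
        "source": waveform.source,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_waveform(path: str | Path) -> AveragedWaveform:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = pd.read_csv(path)["amplitude_uV"].to_numpy()
    if len(samples) != meta["n_samples"]:
        raise ParseError(
            f"{path.name}: sample count {len(samples)} disagrees with sidecar "
            f"({meta['n_samples']})"
        )
    return AveragedWaveform(
        samples=samples,
        sample_rate=meta["sample_rate"],
        n_ensembles=meta["n_ensembles"],
        peak_index=meta["peak_index"],
        source=meta.get("source", {}),
    )
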