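"""Seeded generator of MEA-like cardiomyocyte field-potential recordings.

Every other stage of the pipeline is tested against this generator, so each
beat is built from primitives with analytically known landmarks:

* depolarisation spike — a derivative-of-Gaussian (width ``spike_sigma_ms``,
  ~5 ms across both lobes), biphasic like the extracellular sodium spike,
  normalised so its extrema reach ``spike_amplitude``;
* repolarisation wave (the T-wave analogue) — a smooth half-cosine rise into
  the wave peak followed by a *linear* descent that reaches baseline exactly
  at ``onset + FPD``.  The linear-descent/flat-tail corner is precisely the
  point the trapezium-area offset detector defines, so the planted FPD is an
  exact oracle rather than an approximation.

A recording schedules beats at the configured rate (with optional Gaussian
timing jitter), makes each beat premature with probability
``premature_prob`` — a premature beat arrives after a shortened coupling
interval *and* has a reshaped morphology (wider spike, attenuated and
shortened repolarisation wave) so that correlation-based rejection can be
tested independently of timing — applies optional per-beat morphology drift,
and adds i.i.d. Gaussian noise.  All randomness flows from ``seed``.

The generator emulates the phenomenology of spontaneously beating human
stem-cell-derived cardiomyocyte aggregates on an MEA (beating rates around
110-135 bpm, FPD around 300-430 ms, spikes of a few hundred µV); it does not
model ionic currents, electrode spatial coupling, baseline wander or mains
interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ParameterError
from .io_mea import Recording

__all__ = ["SynthConfig", "GroundTruth", "make_complex", "make_recording", "write_mcd_ascii"]


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    Amplitudes are µV, durations seconds, FPD milliseconds.  The defaults
    describe a healthy spontaneously beating aggregate: 120 bpm, 350 ms FPD,
    500 µV spikes with a 75 µV repolarisation wave and 2% timing jitter.
    """

    sample_rate: float = 20000.0
    duration: float = 10.0
    beating_rate: float = 120.0
    rate_jitter: float = 0.02
    spike_amplitude: float = 500.0
    repol_amplitude: float = 75.0
    fpd_ms: float = 350.0
    noise_sd: float = 0.0
    premature_prob: float = 0.0
    premature_shape_scale: float = 0.5
    premature_coupling: float = 0.6
    drift_per_beat: float = 0.0
    seed: int = 0
    spike_sigma_ms: float = 1.25
    repol_rise_ms: float = 40.0
    repol_descent_ms: float = 80.0
    electrodes: tuple[str, ...] = ("A1",)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0 or self.beating_rate <= 0:
            raise ParameterError("sample_rate, duration and beating_rate must be positive")
        if min(self.spike_amplitude, self.repol_amplitude, self.noise_sd) < 0:
            raise ParameterError("amplitudes and noise_sd must be non-negative")
        for p in (self.premature_prob, self.premature_coupling):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities/fractions must be in [0, 1]")
        if self.fpd_ms >= 60000.0 / self.beating_rate:
            raise ParameterError(
                f"FPD {self.fpd_ms} ms must be shorter than the beat interval "
                f"{60000.0 / self.beating_rate:.1f} ms"
            )

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.beating_rate


@dataclass
class GroundTruth:
    """Per-beat annotations aligned 1:1 with the generated beats."""

    beat_times: np.ndarray  # sample index of the positive spike extremum
    beat_labels: list[str]  # "normal" | "premature" | "drifted"
    true_onset: np.ndarray  # sample indices
    true_offset: np.ndarray
    true_fpd_ms: np.ndarray

    def __len__(self) -> int:
        return len(self.beat_times)


# the onset is annotated where the leading lobe reaches 5% of the spike
# amplitude — the amplitude-fraction convention the onset detector also uses,
# which makes the landmark well-defined for lobes with Gaussian tails;
# for this shape that point sits 4.1 sigma before the trough centre
_ONSET_SIGMAS = 4.1

# positive pre-lobe: fraction of the main amplitude, centred 2 sigma early
_PRELOBE_FRAC = 0.45
_PRELOBE_SHIFT = 2.0


def _spike(t_ms: np.ndarray, centre_ms: float, amplitude: float, sigma_ms: float) -> np.ndarray:
    """Biphasic, negative-dominant sodium-spike analogue.

    A positive Gaussian pre-lobe (0.45 x amplitude, 2 sigma early) followed
    by the dominant negative Gaussian trough at ``centre_ms`` — the classic
    extracellular spike polarity, so negative-polarity peak tracking never
    confuses the (positive) repolarisation wave with a beat.
    """
    u = (t_ms - centre_ms) / sigma_ms
    return amplitude * (
        _PRELOBE_FRAC * np.exp(-0.5 * (u + _PRELOBE_SHIFT) ** 2) - np.exp(-0.5 * u * u)
    )


def make_complex(cfg: SynthConfig, lead_ms: float = 50.0, tail_ms: float = 100.0):
    """One noise-free beat with exact landmark annotations.

    Returns ``(samples, annotations)``; the window spans
    ``lead_ms + FPD + tail_ms`` so the full repolarisation wave and a flat
    tail are inside it.  Annotations carry the spike-extremum index
    (``peak``), the depolarisation ``onset``, the repolarisation ``offset``
    (exactly ``onset + FPD``) and the spike centre ``t0``.
    """
    fs = cfg.sample_rate
    n = int(round((lead_ms + cfg.fpd_ms + tail_ms) / 1000.0 * fs))
    if n < 10:
        raise ParameterError("window too short for a beat")
    t_ms = np.arange(n) / fs * 1000.0
    onset_ms = lead_ms
    centre_ms = onset_ms + _ONSET_SIGMAS * cfg.spike_sigma_ms
    x = _spike(t_ms, centre_ms, cfg.spike_amplitude, cfg.spike_sigma_ms)

    offset_ms = onset_ms + cfg.fpd_ms
    if cfg.repol_amplitude > 0:
        peak_ms = offset_ms - cfg.repol_descent_ms
        rise_start = peak_ms - cfg.repol_rise_ms
        if rise_start <= centre_ms + 3.0 * cfg.spike_sigma_ms:
            raise ParameterError(
                "FPD too short: repolarisation wave would overlap the spike"
            )
        rising = (t_ms >= rise_start) & (t_ms < peak_ms)
        x[rising] += cfg.repol_amplitude * np.sin(
            0.5 * np.pi * (t_ms[rising] - rise_start) / cfg.repol_rise_ms
        ) ** 2
        falling = (t_ms >= peak_ms) & (t_ms < offset_ms)
        x[falling] += cfg.repol_amplitude * (offset_ms - t_ms[falling]) / cfg.repol_descent_ms
        offset = int(round(offset_ms / 1000.0 * fs))
    else:
        # bare spike: the complex ends where the trailing lobe dies out
        offset = int(round((centre_ms + 3.0 * cfg.spike_sigma_ms) / 1000.0 * fs))

    ann = {
        "peak": int(np.argmin(x)),  # the dominant (negative) spike extremum
        "onset": int(round(onset_ms / 1000.0 * fs)),
        "offset": offset,
        "t0": int(round(centre_ms / 1000.0 * fs)),
        "fpd_ms": cfg.fpd_ms if cfg.repol_amplitude > 0 else (offset - int(round(onset_ms / 1000.0 * fs))) / fs * 1000.0,
    }
    return x, ann


def _morph_for_beat(cfg: SynthConfig, label: str, drift_steps: int) -> SynthConfig:
    """Morphology parameters for one beat given its label and drift position."""
    out = cfg
    if label == "premature":
        s = cfg.premature_shape_scale
        out = replace(
            out,
            spike_sigma_ms=cfg.spike_sigma_ms * (1.0 + s),
            repol_amplitude=cfg.repol_amplitude * (1.0 - s),
            fpd_ms=cfg.fpd_ms * (1.0 - 0.3 * s),
        )
    if cfg.drift_per_beat > 0 and drift_steps > 0:
        d = min(cfg.drift_per_beat * drift_steps, 0.5)
        out = replace(
            out,
            repol_amplitude=out.repol_amplitude * (1.0 - d),
            spike_sigma_ms=out.spike_sigma_ms * (1.0 + 0.5 * d),
        )
    return out


def make_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Full multi-beat recording plus ground truth.

    Beats are scheduled every ``RR * (1 + rate_jitter * N(0,1))`` ms; a beat
    drawn premature follows its predecessor after ``premature_coupling * RR``
    instead, with reshaped morphology.  Cumulative drift beyond 10%
    relabels a beat "drifted".  Gaussian noise of ``noise_sd`` µV is added
    to every electrode independently.
    """
    fs = cfg.sample_rate
    n = int(round(cfg.duration * fs))
    rng = np.random.default_rng(cfg.seed)

    rr = cfg.rr_ms
    lead_ms, tail_ms = 50.0, 100.0

    # schedule spike-extremum times in ms: first beat half an interval in,
    # last one half an interval before the end, so RR-long centred windows fit
    times: list[float] = []
    labels: list[str] = []
    t = rr / 2.0
    while t < cfg.duration * 1000.0 - rr / 2.0 + 1e-6:
        premature = rng.random() < cfg.premature_prob
        if premature and times:
            t = times[-1] + cfg.premature_coupling * rr
            labels.append("premature")
        else:
            labels.append("normal")
        times.append(t)
        t = times[-1] + rr * (1.0 + cfg.rate_jitter * float(rng.standard_normal()))

    clean = np.zeros(n)
    onsets, offsets, fpds = [], [], []
    for k, (bt, label) in enumerate(zip(times, labels)):
        bcfg = _morph_for_beat(cfg, label, k)
        if label == "normal" and cfg.drift_per_beat * k > 0.10:
            labels[k] = label = "drifted"
        beat, ann = make_complex(bcfg, lead_ms=lead_ms, tail_ms=tail_ms)
        start = int(round(bt / 1000.0 * fs)) - ann["peak"]
        lo, hi = max(0, start), min(n, start + len(beat))
        if hi <= lo:
            continue
        clean[lo:hi] += beat[lo - start : hi - start]
        onsets.append(start + ann["onset"])
        offsets.append(start + ann["offset"])
        fpds.append(ann["fpd_ms"])

    beat_times = np.array([int(round(bt / 1000.0 * fs)) for bt in times], dtype=int)
    truth = GroundTruth(
        beat_times=beat_times,
        beat_labels=labels,
        true_onset=np.array(onsets, dtype=int),
        true_offset=np.array(offsets, dtype=int),
        true_fpd_ms=np.array(fpds, dtype=float),
    )
    traces = {}
    for e in cfg.electrodes:
        noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
        traces[e] = clean + noise
    rec = Recording(sample_rate=fs, electrodes=list(cfg.electrodes), traces=traces)
    return rec, truth


def write_mcd_ascii(recording: Recording, path: str | Path) -> None:
    """Write a recording in the MC_DataTool ASCII dialect the reader accepts.

    Two free-form header lines, a tab-separated column-name row
    (``t [ms]`` then one ``El <id> [µV]`` per electrode), then tab-separated
    numeric rows; amplitudes are printed to 1e-3 µV.
    """
    path = Path(path)
    fs = recording.sample_rate
    names = "\t".join(["t [ms]"] + [f"El {e} [µV]" for e in recording.electrodes])
    cols = [recording.traces[e] for e in recording.electrodes]
    n = recording.n_samples
    t_ms = np.arange(n) * (1000.0 / fs)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("MC_DataTool ASCII conversion\n")
        fh.write(f"Sample rate = {fs:g} Hz; electrodes = {len(cols)}\n")
        fh.write(names + "\n")
        data = np.column_stack([t_ms] + cols)
        np.savetxt(fh, data, fmt=["%.5f"] + ["%.3f"] * len(cols), delimiter="\t")
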