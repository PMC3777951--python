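# Methods

`cardiofp` analyses extracellular field potentials (FPs) recorded from
spontaneously beating cardiomyocyte aggregates on micro-electrode arrays
(MEAs), the standard in-vitro substrate for drug cardiotoxicity screening.
The analysis has two phases: Phase I reduces a noisy multi-beat recording to
one representative FP complex by template-matched ensemble averaging;
Phase II measures the field-potential duration (FPD, the QT-interval
analogue) and related quantities on that representative complex.

## Phase I — template matching and ensemble averaging

**Filtering.** Traces are low-pass filtered with a 5th-order Butterworth at
200 Hz, applied forward-backward (`scipy.signal.sosfiltfilt`). Zero-phase
filtering is used because a causal pass would delay every landmark and bias
the FPD; the price is that the effective magnitude response is the square of
the single-pass prototype (−6 dB rather than −3 dB at the cut-off) and that
a millisecond-scale spike acquires a small symmetric precursor. Both
consequences are covered by tests.

**Beat detection.** A window-threshold scheme: the trace is median-centred,
the detection threshold defaults to 5 × the robust noise scale (median
absolute deviation × 1.4826), the tracked polarity is the sign with the
larger extrema, and `scipy.signal.find_peaks` enforces a refractory spacing
(default 200 ms, safely below the 300 ms beat interval of a 200 bpm rhythm)
so biphasic spikes are not double-counted. All three constants are
configurable; the defaults were chosen against the synthetic generator's
ground truth across 30–200 bpm.

**Windowing and template.** Each beat is cut into a window centred on its
depolarisation peak. The default window length is the smallest beat-to-beat
interval of the recording — long enough to cover the beat, short enough
that the neighbouring complex cannot leak into the correlation interval.
The template is by default the complex nearest the centre of the total
recording duration, or any complex chosen by index (the programmatic
analogue of the operator picking a representative beat; note that if the
centre beat happens to be arrhythmogenic, the "representative" waveform
will represent the arrhythmia — choosing the template deliberately is the
operator's responsibility, and the synthetic benchmarks do exactly that).

**Correlation coefficient.** Every complex is scored against the template
by a lag-searched correlation; the acceptance rule is `c ≥ CF` for a
user-chosen correlation factor CF (0.96–0.98 is the useful range; 0.98 is
the default). The default coefficient is Pearson-type — mean-removed and
amplitude-normalised on the overlapping segment — because a CF threshold
near 1 presupposes a unit-bounded, scale-free similarity score; the plain
1/N product sum is available as `normalization="raw"` for fidelity with the
classical formulation but its scale depends on the signal amplitude. The
lag search covers ±2 ms by default: wide enough to absorb detection jitter,
far too narrow to lock onto an adjacent beat. Ties prefer the smaller
absolute lag, then the negative one, so results are deterministic.

**Ensemble average.** Accepted complexes are shifted by their best lags and
averaged pointwise (median optionally). Lag shifts shrink the output to the
common overlap of the shifted windows; the trimming is recorded in the
provenance. Averaging N beats suppresses i.i.d. noise by √N — the tests
check the N^(−1/2) law at N ∈ {4, 16, 64} — but alignment jitter acts as an
additional low-pass: a ±1 ms jitter attenuates a 200 Hz component visibly
more than a 50 Hz one (also under test), which is why the lag search exists.

## Phase II — landmarks and FPD

**Onset.** Scanning forward, the first frame (default 10 ms) whose maximum
deviation from the baseline level (median of the leading frame) exceeds
`k ×` the baseline excursion (default k = 3) localises the departure; the
onset is the first above-threshold sample in that frame, and must precede
the depolarisation peak. The threshold has a floor of 5% of the waveform's
peak deviation. The floor is the usual amplitude-fraction onset convention
and is load-bearing here: a heavily averaged waveform is nearly noiseless,
so the excursion term collapses and a bare threshold would fire on the
low-level precursor that zero-phase filtering smears ahead of the spike.
Five percent sits above that leakage (~2–3% for a 1–2 ms spike filtered at
200 Hz) and below any deflection of interest.

**Offset — trapezium area (TRA).** The repolarisation end-point maximises
the area of a rectangular trapezium with fixed vertices at the
repolarisation-wave peak (x_i, y_i) and the final sample x_r, and a moving
vertex (x_m, y_m):

    A(x_m) = ½ · |y_i − y_m| · (2·x_r − x_m − x_i)

Geometrically the maximiser is where the descending repolarisation limb
hands over to the flat tail. The implementation is a vectorised argmax and
must equal the exhaustive brute force on every waveform (a test enforces
this); ties take the earliest maximiser. The moving vertex nominally starts
at the valley after the activation spike; because the trapezium is
degenerate while the signal still rises toward the repolarisation peak, the
sweep effectively starts at the fixed vertex. With `fixed_vertex="valley"`
the anchor moves to the post-activation valley instead — the two published
variants of the construction — and the vertex choice is config-exposed.

**Measures.** FPD = (offset − onset) in ms. The rate-corrected
cFPD = FPD / √RR with the beat interval RR in seconds (Bazett), so
cFPD = FPD exactly at 60 bpm and grows with rate at fixed FPD. AUC is the
trapezoidal integral of |amplitude − baseline| between the landmarks, the
baseline being the median of the pre-onset samples; the absolute value is
used because MEA complexes may deflect either way. Every landmark carries
an auto/manual mode flag; manual landmarks are given in ms from the window
start.

## Validation metrics

Classification is scored as a screening test: a complex is a positive when
its coefficient reaches CF. PPV = TP/(TP+FP), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), in percent, two decimals. Multi-dataset
summaries are macro-averages — each dataset's metrics come from its own
counts, unrounded, then averaged with equal weight and rounded last; this
is the convention under which the published per-dataset counts reproduce
their printed means. A zero-denominator metric is undefined and rendered
"–"; undefined values are excluded from means.

## The synthetic generator

Each beat is built from primitives with analytically known landmarks:

* **spike** — a positive Gaussian pre-lobe (0.45 × amplitude, 2σ early)
  followed by the dominant negative Gaussian trough (σ = 1.25 ms): the
  classic biphasic, negative-dominant extracellular sodium spike. The
  negative polarity is what lets threshold detection ignore the (positive)
  repolarisation wave.
* **repolarisation wave** — a half-cosine rise (40 ms) into the wave peak,
  then a *linear* descent (80 ms) reaching baseline exactly at
  onset + FPD. For a linear descent anchored at the wave peak the
  trapezium area is strictly increasing up to the descent/tail corner and
  strictly decreasing after it, so the TRA offset of the clean shape is the
  planted landmark *exactly*, not approximately. The onset is annotated
  where the leading lobe reaches 5% of the spike amplitude — the same
  amplitude-fraction convention the detector uses, which makes the landmark
  well-defined for lobes with Gaussian tails.

Beats are scheduled every RR·(1 + jitter·N(0,1)) ms starting half an
interval into the recording; a beat is premature with probability
`premature_prob`, arriving after a shortened coupling interval (0.6·RR)
*and* reshaped (spike 50% wider, repolarisation wave halved and FPD
shortened 15% at the default shape scale). The reshaping matters because
the Pearson-type coefficient is scale-invariant: a pure amplitude rescale
would be invisible to the classifier, so premature beats must genuinely
change shape for CF-based rejection to be testable independently of timing.
Optional per-beat linear drift attenuates the repolarisation wave and
widens the spike; beats beyond 10% cumulative drift are labelled
"drifted". Gaussian noise is added per electrode; all randomness flows
from one seed and identical configurations are bit-identical.

Defaults describe a healthy aggregate (120 bpm, FPD 350 ms, 500 µV spike,
75 µV repolarisation wave, 2% rate jitter). The generator emulates beat
morphology, arrhythmic contamination and additive noise; it does not model
ionic currents, electrode spatial coupling, baseline wander, mains
interference, or amplitude non-stationarity — passing tests therefore
demonstrate algorithmic correctness on this phenomenology, not performance
on any particular laboratory's recordings.

### Benchmark geometry

A centred window of one beat interval leaves only RR/2 of signal after the
depolarisation peak, so an FPD is only measurable from such a window when
FPD < ~RR/2. Real aggregates violate this freely (e.g. FPD ≈ 400 ms at
113 bpm), which is why operators use asymmetric windows in practice; with
centred windows, the end-to-end FPD-recovery benchmarks run at slow rates
(40–60 bpm) so the window spans the full repolarisation wave, while
classification benchmarks run at the physiological 120 bpm. Benchmark
problem sizes: 30–36 s recordings at 20 kHz, ~24–63 beats, noise 2% of the
spike amplitude, ~15% premature beats.

## Numerical choices and degenerate inputs

* Sample-rate inference from the ASCII time column uses the median step and
  warns above 1 ppm jitter (text-format rounding).
* A zero-variance complex has undefined correlation: it is rejected with a
  flag, never aborting the run; an all-flat trace yields an empty peak
  train, not an error.
* Ensemble averaging with zero accepted complexes raises an error that
  advises lowering CF.
* All tie-breaks (template centre, lag, TRA maximiser) resolve to the
  earlier/smaller candidate, making every pipeline output deterministic;
  rerunning a CLI command produces byte-identical files.

## Known limitations

* The FPD of a complex whose repolarisation wave leaves the correlation
  window cannot be measured from the averaged waveform (see benchmark
  geometry above); the package reports what the window contains.
* TRA assumes a positive repolarisation wave followed by a quieter tail;
  waveforms whose tail contains another beat's spike need a shorter window
  or manual landmarks.
* Only Bazett rate correction is provided.
* The ASCII reader targets the tab-separated MC_DataTool export dialect;
  native binary formats are out of scope.
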