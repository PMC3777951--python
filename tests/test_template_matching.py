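"""Complex extraction, template selection, correlation scoring, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiofp import synth, template_matching as tm
from cardiofp.exceptions import (
    InsufficientDataError,
    LookupError_,
    ParameterError,
    UndefinedCorrelationError,
)
from cardiofp.preprocess import PeakTrain
from cardiofp.template_matching import (
    FPComplex,
    classify_complexes,
    correlation_coefficient,
    ensemble_average,
    extract_complexes,
    select_template,
)

FS = 20000.0


def make_peaks(indices, refractory=100):
    return PeakTrain(indices=np.array(indices), polarity=1, threshold=1.0, refractory=refractory)


def complex_from(samples, start=0):
    samples = np.asarray(samples, dtype=float)
    return FPComplex(samples=samples, start=start, peak_local=len(samples) // 2)


# ---------------------------------------------------------------------------
# extraction


def test_auto_window_is_smallest_beat_interval():
    trace = np.random.default_rng(0).normal(size=120000)
    peaks = make_peaks(np.arange(10) * 10000 + 15000)  # 500 ms apart
    res = extract_complexes(trace, peaks, FS, window_ms="auto")
    assert res.window_samples == 10000
    assert all(c.n == 10000 for c in res)
    assert all(c.peak_local == 5000 for c in res)
    assert len(res) <= 10


def test_edge_beat_dropped_and_counted():
    trace = np.zeros(100000)
    peaks = make_peaks([200, 30000, 60000])  # first peak 10 ms from start
    res = extract_complexes(trace, peaks, FS, window_ms=500.0)
    assert len(res) == 2
    assert res.n_dropped == 1


def test_explicit_window_sets_all_lengths():
    trace = np.zeros(100000)
    peaks = make_peaks([20000, 50000, 80000])
    res = extract_complexes(trace, peaks, FS, window_ms=100.0)
    assert all(c.n == 2000 for c in res)


def test_window_larger_than_trace_rejected():
    with pytest.raises(ParameterError):
        extract_complexes(np.zeros(1000), make_peaks([500]), FS, window_ms=500.0)


# ---------------------------------------------------------------------------
# template selection


def test_default_template_is_centre_beat():
    # 7 complexes uniformly spread: midpoint ties resolve to the earlier one,
    # landing on the 4th complex (0-based index 3)
    complexes = [complex_from(np.sin(np.arange(10)), start=i * 100) for i in range(7)]
    t = select_template(complexes, mode="default", trace_length=700)
    assert t.index == 3
    assert t.mode == "default-centre"


def test_manual_template_is_verbatim():
    complexes = [complex_from(np.sin(np.arange(10)) + i) for i in range(5)]
    t = select_template(complexes, mode=2)
    assert t.index == 2
    np.testing.assert_array_equal(t.samples, complexes[2].samples)


def test_template_selection_errors():
    with pytest.raises(InsufficientDataError):
        select_template([], mode="default", trace_length=100)
    complexes = [complex_from(np.sin(np.arange(10)))]
    with pytest.raises(LookupError_):
        select_template(complexes, mode=5)


# ---------------------------------------------------------------------------
# correlation coefficient


def test_self_correlation_is_one():
    c = complex_from(np.random.default_rng(0).normal(size=200))
    coef, lag = correlation_coefficient(c, c, max_lag=0)
    assert coef == pytest.approx(1.0)
    assert lag == 0


def test_negation_gives_minus_one():
    x = np.random.default_rng(1).normal(size=200)
    coef, _ = correlation_coefficient(complex_from(x), complex_from(-x), max_lag=0)
    assert coef == pytest.approx(-1.0)


def test_delayed_copy_found_at_its_lag():
    rng = np.random.default_rng(2)
    base = rng.normal(size=400)
    delayed = np.roll(base, 3)  # delayed[k] = base[k-3]
    coef, lag = correlation_coefficient(
        complex_from(base), complex_from(delayed), max_lag=5
    )
    assert coef == pytest.approx(1.0, abs=1e-6)
    assert lag == 3


def test_matches_brute_force_over_all_lags():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=100), rng.normal(size=100)
    max_lag = 10

    def pearson(u, v):
        u, v = u - u.mean(), v - v.mean()
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    best = max(
        (
            (pearson(a[: 100 - lag], b[lag:]) if lag >= 0 else pearson(a[-lag:], b[:100 + lag]), lag)
            for lag in range(-max_lag, max_lag + 1)
        ),
        key=lambda t: (t[0], -abs(t[1]), -t[1]),
    )
    coef, lag = correlation_coefficient(complex_from(a), complex_from(b), max_lag=max_lag)
    assert coef == pytest.approx(best[0])
    assert abs(lag) <= max_lag


def test_zero_variance_is_undefined():
    with pytest.raises(UndefinedCorrelationError):
        correlation_coefficient(
            complex_from(np.zeros(50)), complex_from(np.ones(50)), max_lag=0
        )


def test_max_lag_bounds_enforced():
    c = complex_from(np.arange(40.0))
    with pytest.raises(ParameterError):
        correlation_coefficient(c, c, max_lag=11)  # > N/4


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=0.1, max_value=50.0),
    offset=st.floats(min_value=-100.0, max_value=100.0),
    seed=st.integers(min_value=0, max_value=500),
)
def test_invariant_to_positive_rescale_and_offset(scale, offset, seed):
    x = np.random.default_rng(seed).normal(size=80)
    y = np.random.default_rng(seed + 1).normal(size=80)
    c0, _ = correlation_coefficient(complex_from(x), complex_from(y), max_lag=0)
    c1, _ = correlation_coefficient(
        complex_from(x), complex_from(scale * y + offset), max_lag=0
    )
    assert c1 == pytest.approx(c0, abs=1e-9)


def test_symmetric_at_lag_zero():
    rng = np.random.default_rng(7)
    a, b = rng.normal(size=60), rng.normal(size=60)
    c_ab, _ = correlation_coefficient(complex_from(a), complex_from(b), max_lag=0)
    c_ba, _ = correlation_coefficient(complex_from(b), complex_from(a), max_lag=0)
    assert c_ab == pytest.approx(c_ba)


def test_raw_normalization_is_mean_product_sum():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 0.0, 1.0, 3.0])
    coef, _ = correlation_coefficient(
        complex_from(a), complex_from(b), max_lag=0, normalization="raw"
    )
    assert coef == pytest.approx(np.dot(a, b) / 4.0)


# ---------------------------------------------------------------------------
# classification


def test_template_accepts_itself_at_any_cf():
    complexes = [complex_from(np.random.default_rng(i).normal(size=100)) for i in range(5)]
    t = select_template(complexes, mode=2)
    report = classify_complexes(complexes, t, cf=1.0)
    assert report.entries[2].accepted
    assert report.entries[2].coefficient == pytest.approx(1.0)


def test_cf_zero_disallowed():
    complexes = [complex_from(np.random.default_rng(0).normal(size=100))]
    t = select_template(complexes, mode=0)
    with pytest.raises(ParameterError):
        classify_complexes(complexes, t, cf=0.0)


def test_zero_variance_complex_rejected_with_flag():
    good = complex_from(np.random.default_rng(0).normal(size=100))
    flat = complex_from(np.zeros(100))
    t = select_template([good, flat], mode=0)
    report = classify_complexes([good, flat], t, cf=0.9)
    assert report.entries[1].undefined
    assert not report.entries[1].accepted
    assert report.entries[0].accepted


def test_premature_beats_rejected_at_strict_cf(arrhythmic_phase1):
    """At CF 0.98 every planted premature beat is rejected and nearly all
    normal beats are accepted (the correlation-screening core claim)."""
    res, labels = arrhythmic_phase1
    accepted = res.report.accepted_flags
    premature = np.array([l == "premature" for l in labels])
    normal = np.array([l == "normal" for l in labels])
    assert premature.sum() >= 5
    assert not accepted[premature].any()
    assert accepted[normal].mean() >= 0.95


def test_accepted_set_shrinks_as_cf_rises(arrhythmic_phase1):
    res, _ = arrhythmic_phase1
    coeffs = res.report.coefficients
    previous = None
    for cf in (0.88, 0.93, 0.98):
        accepted = set(np.flatnonzero(coeffs >= cf))
        if previous is not None:
            assert accepted <= previous
        previous = accepted


# ---------------------------------------------------------------------------
# ensemble averaging


def test_average_of_identical_complexes_is_the_complex():
    x = np.sin(np.arange(100) / 7.0)
    complexes = [complex_from(x.copy()) for _ in range(6)]
    t = select_template(complexes, mode=0)
    report = classify_complexes(complexes, t, cf=0.5)
    avg = ensemble_average(report, complexes, FS)
    np.testing.assert_allclose(avg.samples, x, atol=1e-12)
    assert avg.n_ensembles == 6


def test_symmetric_errors_cancel():
    s = np.sin(np.arange(200) / 9.0)
    e = np.cos(np.arange(200) / 4.0) * 0.05
    complexes = [complex_from(s + e), complex_from(s - e)]
    t = select_template(complexes, mode=0)
    report = classify_complexes(complexes, t, cf=0.5)
    avg = ensemble_average(report, complexes, FS)
    np.testing.assert_allclose(avg.samples, s, atol=1e-12)


def test_noise_suppression_follows_law_of_large_numbers():
    """Averaging 100 noisy copies leaves RMSE <= 1.5 sigma / sqrt(100)."""
    rng = np.random.default_rng(11)
    clean = np.sin(np.arange(500) / 20.0) * 50.0
    sigma = 5.0
    complexes = [complex_from(clean + rng.normal(0, sigma, 500)) for _ in range(100)]
    t = select_template(complexes, mode=0)
    report = classify_complexes(complexes, t, cf=0.5, max_lag=0)
    avg = ensemble_average(report, complexes, FS)
    rmse = np.sqrt(np.mean((avg.samples - clean) ** 2))
    assert rmse <= 1.5 * sigma / np.sqrt(100)


def test_rmse_scales_as_inverse_sqrt_n():
    rng = np.random.default_rng(13)
    clean = np.sin(np.arange(400) / 15.0) * 50.0
    sigma = 8.0

    def rmse_for(n):
        complexes = [complex_from(clean + rng.normal(0, sigma, 400)) for _ in range(n)]
        t = select_template(complexes, mode=0)
        report = classify_complexes(complexes, t, cf=0.5)
        avg = ensemble_average(report, complexes, FS)
        return np.sqrt(np.mean((avg.samples - clean) ** 2))

    for n in (4, 16, 64):
        expected = sigma / np.sqrt(n)
        assert rmse_for(n) <= 1.5 * expected


def test_alignment_jitter_acts_as_low_pass():
    """+/-1 ms alignment jitter attenuates 200 Hz strictly more than 50 Hz."""
    rng = np.random.default_rng(17)
    n = 2000
    t = np.arange(n) / FS

    def attenuation(freq):
        clean = np.sin(2 * np.pi * freq * t)
        shifted = []
        for _ in range(200):
            jit = int(round(rng.uniform(-1e-3, 1e-3) * FS))
            shifted.append(np.roll(clean, jit))
        avg = np.mean(shifted, axis=0)
        sl = slice(n // 4, 3 * n // 4)
        return np.max(np.abs(avg[sl])) / np.max(np.abs(clean[sl]))

    assert attenuation(200.0) < attenuation(50.0)


def test_no_accepted_complexes_is_an_error():
    complexes = [complex_from(np.random.default_rng(0).normal(size=50))]
    report = tm.CorrelationReport(
        entries=[tm.ComplexEntry(coefficient=0.1, best_lag=0, accepted=False)],
        cf=0.98,
        max_lag=0,
    )
    with pytest.raises(InsufficientDataError, match="lower"):
        ensemble_average(report, complexes, FS)


def test_lag_alignment_recovers_shifted_copies():
    """Copies delayed by known lags average back to the template shape."""
    rng = np.random.default_rng(19)
    base = np.convolve(rng.normal(size=400), np.ones(20) / 20, mode="same")
    delays = (0, 2, -3, 1)
    complexes = [complex_from(np.roll(base, d)) for d in delays]
    t = select_template(complexes, mode=0)
    report = classify_complexes(complexes, t, cf=0.9, max_lag=5)
    assert [e.best_lag for e in report.entries] == list(delays)
    avg = ensemble_average(report, complexes, FS)
    lo = max(0, -min(delays))
    ref = base[lo : lo + len(avg.samples)]
    # interior only: np.roll wraps the (smoothed) edges around
    core = slice(25, len(avg.samples) - 25)
    np.testing.assert_allclose(avg.samples[core], ref[core], atol=1e-9)
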