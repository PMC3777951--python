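"""Shared fixtures: small synthetic recordings and benchmark helpers."""

from __future__ import annotations

import numpy as np
import pytest

from cardiofp import pipeline, synth, validation
from cardiofp.synth import SynthConfig


@pytest.fixture(scope="session")
def quiet_recording():
    """Noise-free 10 s recording at 60 bpm: 10 beats, no premature activity."""
    cfg = SynthConfig(
        duration=10.0, beating_rate=60.0, rate_jitter=0.0, noise_sd=0.0, seed=0
    )
    rec, truth = synth.make_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def arrhythmic_recording():
    """Noisy 30 s recording at 120 bpm with ~17% premature beats (seeded)."""
    cfg = SynthConfig(
        duration=30.0,
        beating_rate=120.0,
        noise_sd=10.0,  # 2% of the 500 µV spike
        premature_prob=0.15,
        seed=42,
    )
    rec, truth = synth.make_recording(cfg)
    return cfg, rec, truth


def classify_against_truth(rec, truth, cf=0.98, template="normal-centre"):
    """Run Phase I and pair each complex with its ground-truth label.

    ``template="normal-centre"`` mimics the operator picking a representative
    normal beat: the normal-labelled complex nearest the recording midpoint.
    Returns ``(phase1_result, per_complex_truth_labels)``.
    """
    fs = rec.sample_rate
    res = pipeline.run_phase1(rec, rec.electrodes[0], cf=cf)
    det = [c.start + c.peak_local for c in res.extraction]
    labels = validation.align_to_truth(det, truth.beat_times, truth.beat_labels, fs)
    if template == "normal-centre":
        mid = rec.n_samples / 2
        normal = [i for i, l in enumerate(labels) if l == "normal"]
        idx = min(normal, key=lambda i: abs(res.extraction[i].start - mid))
        if idx != res.template.index:
            res = pipeline.run_phase1(rec, rec.electrodes[0], cf=cf, template=idx)
    return res, labels


@pytest.fixture(scope="session")
def arrhythmic_phase1(arrhythmic_recording):
    cfg, rec, truth = arrhythmic_recording
    res, labels = classify_against_truth(rec, truth)
    return res, labels
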