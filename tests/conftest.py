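"""Shared fixtures: one moderately sized synthetic anesthesia recording that
several test modules analyse, plus its derived pipeline products."""

from __future__ import annotations

import numpy as np
import pytest

import caldyn


@pytest.fixture(scope="session")
def anesthesia_dataset():
    """Default anesthesia scenario, 300 neurons, 1400 s at 10 Hz, seed 11."""
    cfg = caldyn.SimulationConfig(n_neurons=300, seed=11)
    traces, truth = caldyn.simulate(cfg)
    dff = caldyn.compute_dff(traces)
    return cfg, traces, truth, dff


@pytest.fixture(scope="session")
def segmentation_products(anesthesia_dataset):
    """PCA projection, windows, DTW distances and the k=5 segmentation."""
    cfg, traces, truth, dff = anesthesia_dataset
    basis = caldyn.fit_projection(dff)
    ws = caldyn.make_windows(caldyn.project(dff, basis), 100, dff.sampling_rate)
    dmat = caldyn.pairwise_dtw(ws)
    curve, _ = caldyn.within_class_curve(dmat, k_max=10)
    seg = caldyn.average_linkage(dmat, 5)
    return basis, ws, dmat, curve, seg


@pytest.fixture(scope="session")
def detected_events(anesthesia_dataset):
    _, _, _, dff = anesthesia_dataset
    return caldyn.detect_events(dff)
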