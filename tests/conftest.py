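"""Shared fixtures.

The heavier study datasets are generated once per session at reduced
duration (the generators are pure functions of their seeds, so shorter
recordings exercise exactly the same code paths as the 5/10-minute
defaults used by the acceptance script).
"""

from __future__ import annotations

import numpy as np
import pytest

from pulmovib import pipeline, sigproc, synth


@pytest.fixture(scope="session")
def six_state_small():
    """Six discrete states, 60 s each (seed 7)."""
    return synth.generate_six_state_dataset(seed=7, duration=60.0)


@pytest.fixture(scope="session")
def six_state_tables(six_state_small):
    """Per-state feature tables for the reduced six-state dataset."""
    tables = []
    for i, rec in enumerate(six_state_small):
        tab, _ = pipeline.extract_cycle_table(rec)
        tables.append(tab.assign(state=i + 1))
    return tables


@pytest.fixture(scope="session")
def continuous_small():
    """Five continuous-sweep runs, 90 s each (seed 3)."""
    return synth.generate_continuous_dataset(seed=3, duration=90.0)


@pytest.fixture(scope="session")
def continuous_tables(continuous_small):
    tables = []
    for i, rec in enumerate(continuous_small):
        tab, _ = pipeline.extract_cycle_table(rec)
        tables.append(tab.assign(run=i + 1))
    return tables


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_recording():
    """One fixed-setting recording with default noise (seed 11), 30 s."""
    cfg = synth.MCLConfig(resistance_setting=0.4, seed=11)
    return synth.generate_recording(cfg, 30.0)


@pytest.fixture(scope="session")
def single_segmented(single_recording):
    rec = single_recording
    p = sigproc.lowpass_pressure(rec.p_pa, rec.fs)
    edges = sigproc.detect_edges(rec.servo, rec.fs)
    segs = sigproc.per_cycle_pressure_params(p, edges, rec.fs)
    return rec, segs
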