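"""Shared fixtures: geometric models are expensive, so they are built
once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mieeg.headmodel import BemSolver, lead_field, make_concentric_sphere_model
from mieeg.io import DEFAULT_CHANNELS, epoch_trials
from mieeg.pipeline import build_head_model
from mieeg.simulate import SimulationConfig, generate_dataset

RADII = (0.08, 0.085, 0.092)


@pytest.fixture(scope="session")
def bundle():
    """Default pipeline fixture: level-2 BEM shells, level-3 dome cortex."""
    return build_head_model()


@pytest.fixture(scope="session")
def level3_solver():
    """Equal-conductivity level-3 sphere model (single-shell regime)."""
    model = make_concentric_sphere_model(RADII, (0.33, 0.33, 0.33), 3)
    return BemSolver(model)


@pytest.fixture(scope="session")
def level3_lead_field(level3_solver, bundle):
    """Level-3 BEM lead field over the dome source space."""
    return lead_field(level3_solver, bundle.source_space, bundle.electrodes,
                      list(DEFAULT_CHANNELS))


@pytest.fixture(scope="session")
def zero_noise_small(bundle):
    """Small zero-noise dataset: 4 trials per class, epoched."""
    cfg = SimulationConfig(snr_db=None, blink_rate=0.0)
    rec, truth = generate_dataset(cfg, n_per_class=4, seed=7,
                                  lead_field=bundle.lead_field,
                                  ves=bundle.ves)
    trials = epoch_trials(rec, cfg.imagery_window)
    return cfg, trials, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
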