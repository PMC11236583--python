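"""Shared fixtures: toy sensor models and one simulated cohort.

The ``cohort`` fixture simulates a reduced-scale study (8 virtual
subjects, 64 trials each, default generator amplitudes) once per session
and exposes the derived quantities every analysis stage consumes --
sensor spectra, omission ERFs and source-level ROI responses -- so the
expensive synthesis is shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deltrain import erf as erf_mod
from deltrain import pipeline as pl
from deltrain import simulate as sim
from deltrain import spectral, stats
from deltrain.spectral import SpectralGrid
from deltrain.stimuli import FAST, SLOW

COHORT_SUBJECTS = 8
COHORT_TRIALS = 96
COHORT_SEED = 42


@pytest.fixture(scope="session")
def model():
    """Default 102-sensor / 90-node toy forward model."""
    return sim.build_sensor_model(seed=0)


@pytest.fixture(scope="session")
def small_model():
    """Reduced 32-sensor / 40-node model for cheap unit tests."""
    return sim.build_sensor_model(n_sensors=32, n_nodes=40, seed=1)


@pytest.fixture(scope="session")
def cohort(model):
    """Reduced-scale synthetic cohort with all derived per-subject data."""
    cfg = sim.SimConfig(
        n_subjects=COHORT_SUBJECTS, n_trials=COHORT_TRIALS, seed=COHORT_SEED
    )
    grid = SpectralGrid()
    coh = {SLOW: [], FAST: []}
    pow_ = {SLOW: [], FAST: []}
    erfs = []
    roi_ent, roi_tgt = [], []
    truth0 = None
    for s, rng in enumerate(sim.subject_seeds(cfg.seed, cfg.n_subjects)):
        plan = sim.generate_plan_for(cfg, subject=s)
        rec, truth = sim.simulate_subject(cfg, plan, model, rng)
        if s == 0:
            truth0 = truth
        spectra = pl.subject_spectra(rec, qc=None, grid=grid)
        for cond in (SLOW, FAST):
            coh[cond].append(spectra["coherence"][cond].values)
            pow_[cond].append(spectra["power"][cond].values)
        ent, tgt = pl._subject_source_responses(spectra, model, 0.05, 20.0)
        roi_ent.append(ent.assign(subject=s))
        roi_tgt.append(tgt.assign(subject=s))
        erfs.append(erf_mod.condition_erf(erf_mod.omission_epochs(rec)))
    return {
        "config": cfg,
        "grid": grid,
        "model": model,
        "coherence": {c: np.array(v) for c, v in coh.items()},
        "power": {c: np.array(v) for c, v in pow_.items()},
        "erfs": erfs,
        "roi_ent": pd.concat(roi_ent, ignore_index=True),
        "roi_tgt": pd.concat(roi_tgt, ignore_index=True),
        "truth0": truth0,
    }


@pytest.fixture(scope="session")
def tiny_recording(model):
    """One 16-trial subject with default amplitudes, for epoch-level tests."""
    cfg = sim.SimConfig(n_subjects=2, n_trials=16, seed=7)
    plan = sim.generate_plan_for(cfg, subject=0)
    rec, truth = sim.simulate_subject(
        cfg, plan, model, sim.subject_seeds(cfg.seed, 1)[0]
    )
    return rec, truth, cfg
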