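"""Shared fixtures: reduced simulation configs sized for Monte-Carlo testing.

Monte-Carlo checks keep the study's repetition structure (18 stimuli x 10
presentations, default habituation profiles) and participant counts, but use
two planted disjoint spatial sources over 12 channels and 50-sample epochs so
that 50-100 simulated cohorts fit in a test run.  Cohort-scale structural
checks (factor counts, pooled ROIs) use the full 99-channel, 200-sample
configuration once, via a session-scoped fixture.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegrs.containers import ROI, ROISet
from eegrs.energy import energy_table
from eegrs.preprocess import preprocess_cohort
from eegrs.simulate import SimConfig, default_rs_profiles, generate_cohort

SUBGROUPS = ("control", "fxs_low", "fxs_high")


def two_block_topographies(n_channels: int = 12) -> np.ndarray:
    """Two orthogonal unit-norm sources with disjoint channel support."""
    half = n_channels // 2
    topo = np.zeros((2, n_channels))
    topo[0, :half] = 1.0 / np.sqrt(half)
    topo[1, half:] = 1.0 / np.sqrt(n_channels - half)
    return topo


def two_block_rois(n_channels: int = 12) -> ROISet:
    half = n_channels // 2
    return ROISet([
        ROI("roiA", [f"E{i + 1}" for i in range(half)], "sim", 1),
        ROI("roiB", [f"E{i + 1}" for i in range(half, n_channels)], "sim", 2),
    ])


def small_config(seed: int, null: bool = False, source_weight: float = 2.0,
                 **overrides) -> SimConfig:
    """Reduced two-source cohort config with the study's trial structure."""
    profiles = default_rs_profiles(10)
    if null:
        profiles = {g: np.ones(10) for g in profiles}
    base = dict(
        n_controls=26, n_fxs_low=8, n_fxs_high=6,
        n_channels=12, n_samples=50,
        topographies=two_block_topographies(),
        source_names=["A", "B"],
        source_weights={g: source_weight * np.ones(2) for g in SUBGROUPS},
        rs_profiles=profiles,
        induced_amp_cv=0.3,
        artifact_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def fxs_only(cohort, metas):
    ids = {m.participant_id for m in metas if m.group == "fxs"}
    return ([c for c in cohort if c.participant_id in ids],
            [m for m in metas if m.participant_id in ids])


def small_energy_table(seed: int, null: bool = False, **overrides):
    cfg = small_config(seed, null=null, **overrides)
    cohort, metas = generate_cohort(cfg)
    return energy_table(cohort, metas, rois=two_block_rois(cfg.n_channels)), metas


@pytest.fixture(scope="session")
def study_scale_run():
    """One full-scale cohort (99 channels, 200 samples) through preprocessing.

    Returns (channel-level energy table, metas, rejection logs).  Shared by
    the structural recovery and scale checks to amortize the ~40 s cost.
    """
    cfg = SimConfig(seed=42)
    cohort, metas = generate_cohort(cfg)
    clean, logs = preprocess_cohort(cohort)
    table = energy_table(clean, metas)
    return table, metas, logs
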