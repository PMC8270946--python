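"""Shared fixtures: small seeded synthetic subjects reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from imanifold import synthetic as syn
from imanifold.config import PipelineConfig
from imanifold.datatypes import ParcellatedTimeseries


@pytest.fixture(scope="session")
def two_stage_subject():
    """Small two-stage subject with disjoint coupling blocks (planted truth)."""
    stages = ["Awake", "N3"]
    templates = syn.stage_coupling_templates(
        12, stages, n_blocks=[2, 1], gain=2.0, seed=0
    )
    spec = syn.SimulationSpec(
        n_regions=12, templates=templates, dwell_mean_trs=60, seed=11
    )
    ts, labels = syn.simulate_subject(300, spec)
    return ts, labels


@pytest.fixture(scope="session")
def two_stage_artifacts(two_stage_subject):
    from imanifold.model import embed_subject

    ts, labels = two_stage_subject
    cfg = PipelineConfig(dim=3, seed=7)
    return embed_subject(ts, labels, cfg)


@pytest.fixture
def sinusoid_ts():
    """Three regions: in-band cosines at distinct frequencies, TR = 2.08 s."""
    tr = 2.08
    t = np.arange(1500) * tr
    data = np.vstack(
        [
            np.cos(2 * np.pi * 0.055 * t),
            np.cos(2 * np.pi * 0.045 * t + 0.7),
            np.cos(2 * np.pi * 0.065 * t - 1.1),
        ]
    )
    return ParcellatedTimeseries(data=data, tr_seconds=tr)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
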