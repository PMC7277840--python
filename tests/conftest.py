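"""Shared fixtures: small simulated cohorts, preprocessed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import echoview as ev
from echoview.core import CohortSpec
from echoview.orchestrate import default_config, prepare_framesets, scaled_strata


@pytest.fixture(scope="session")
def pp_config() -> dict:
    return default_config()["preprocess"]


@pytest.fixture(scope="session")
def small_cohort(pp_config):
    """16 studies, all clips preprocessed: (framesets[pid][view], lvef[pid])."""
    spec = CohortSpec(strata=scaled_strata(16), seed=42)
    return prepare_framesets(ev.iter_cohort(spec), pp_config)


@pytest.fixture(scope="session")
def one_study() -> ev.EchoStudy:
    """A single fully rendered study (with burned-in metadata)."""
    spec = CohortSpec(strata=((40.0, 60.0, 1),), seed=7)
    return next(ev.iter_cohort(spec))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
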