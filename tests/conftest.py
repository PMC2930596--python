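from __future__ import annotations

from dataclasses import dataclass

import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci",
        deadline=None,
        derandomize=True,
        max_examples=60,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # hypothesis-based tests will be skipped by their module
    pass

from metaconsensus import integrate, name_match, synthfix


@dataclass
class PipelineRun:
    dba: tuple
    dbb: tuple
    truth: synthfix.GroundTruth
    model: name_match.NameModel
    state: integrate.MatchState
    tiers: integrate.TierAssignment


def run_pipeline(dba, dbb, truth, model=None) -> PipelineRun:
    if model is None:
        pairs = name_match.build_training_set(list(dba[0]) + list(dbb[0]), seed=0)
        model = name_match.train(pairs)
    state = integrate.iterate_to_fixpoint(dba, dbb, model)
    tiers = integrate.assign_tiers(dba, dbb, state)
    return PipelineRun(dba, dbb, truth, model, state, tiers)


@pytest.fixture(scope="session")
def synth_run() -> PipelineRun:
    """Full pipeline on the default synthetic pair (the study condition)."""
    spec = synthfix.FixtureSpec()
    dba, dbb, truth = synthfix.generate(spec)
    pairs = name_match.build_training_set(
        list(dba[0]) + list(dbb[0]), seed=spec.seed
    )
    model = name_match.train(pairs)
    return run_pipeline(dba, dbb, truth, model)


@pytest.fixture(scope="session")
def tca_run() -> PipelineRun:
    dba, dbb, truth = synthfix.tca_fixture()
    return run_pipeline(dba, dbb, truth, model=name_match.heuristic_model())


@pytest.fixture(scope="session")
def showcase_run() -> PipelineRun:
    dba, dbb, truth = synthfix.showcase_fixture()
    return run_pipeline(dba, dbb, truth, model=name_match.heuristic_model())
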