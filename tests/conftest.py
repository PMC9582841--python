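"""Shared fixtures.

Full 8-week simulations and the 25-run sensitivity scan are expensive
enough to share: they are computed once per session and reused by the unit
and acceptance tests.  Everything is deterministic, so sharing cannot leak
state between tests.
"""

from __future__ import annotations

import pytest

import myogrowth as mg
from myogrowth import experiments


@pytest.fixture(scope="session")
def pathway_params() -> mg.PathwayParameters:
    return mg.PathwayParameters()


@pytest.fixture(scope="session")
def material() -> mg.MaterialParameters:
    return mg.MaterialParameters()


@pytest.fixture(scope="session")
def structure() -> mg.MuscleStructure:
    return mg.MuscleStructure()


@pytest.fixture(scope="session")
def stimulus() -> mg.StimulusParameters:
    return mg.StimulusParameters()


@pytest.fixture(scope="session")
def baseline_result() -> mg.SimulationResult:
    """The full 8-week beta-feedback reference run at study conditions."""
    return mg.run_protocol()


@pytest.fixture(scope="session")
def sensitivity_report() -> experiments.ScanReport:
    """The +/-1% one-at-a-time scan (25 eight-week runs)."""
    return experiments.sensitivity_scan()


@pytest.fixture(scope="session")
def frequency_report() -> experiments.ScanReport:
    return experiments.frequency_scan()


@pytest.fixture(scope="session")
def kappa_report() -> experiments.ScanReport:
    return experiments.kappa_scan()


@pytest.fixture(scope="session")
def short_config() -> mg.SimulationConfig:
    """A 2-week protocol for cheap structural tests."""
    from dataclasses import replace

    cfg = mg.SimulationConfig()
    return replace(cfg, protocol=replace(cfg.protocol, total_weeks=2,
                                         n_sessions=None))
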