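"""Shared fixtures: synthetic study fixtures are generated once per session."""

from __future__ import annotations

import pytest

from cdmine import clusterfind, csrscan
from cdmine.synthetic_data import (SimConfig, build_synthetic_genome,
                                   build_synthetic_proteome)


@pytest.fixture(scope="session")
def refset():
    return csrscan.builtin_refset()


@pytest.fixture(scope="session")
def abc_seed(refset):
    return next(s for s in refset if s.architecture == "ABC")


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def proteome_fixture(sim_config):
    """(proteins, truth) for the default synthetic proteome."""
    return build_synthetic_proteome(sim_config)


@pytest.fixture(scope="session")
def genome_fixture(sim_config):
    return build_synthetic_genome(sim_config)


@pytest.fixture(scope="session")
def genome_roles(genome_fixture):
    """Role assignments for the default genome fixture (expensive; shared)."""
    return clusterfind.assign_roles(genome_fixture.proteins)


@pytest.fixture(scope="session")
def proteome_scans(proteome_fixture):
    """Per-protein (anchor, report, class) for the default proteome."""
    proteins, _ = proteome_fixture
    return {p.id: csrscan.scan_protein(p) for p in proteins}
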