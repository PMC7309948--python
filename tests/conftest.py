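"""Shared fixtures: code maps and two reusable synthetic populations.

``edge_run`` is a small population with the deterministic edge-case
patients appended, analyzed end to end; ``big_run`` is a 5000-patient
population used by the distributional, identity and directionality checks.
Both are session-scoped so the expensive generation happens once.
"""

from __future__ import annotations

import pytest

from ibd_claims.codemaps import load_charlson_map, load_drug_code_maps
from ibd_claims.config import SimConfig, StudyConfig
from ibd_claims.outcomes import CpiTable
from ibd_claims.pipeline import run_analysis
from ibd_claims.synthetic import generate_population, inject_edge_cases


@pytest.fixture(scope="session")
def maps():
    return load_drug_code_maps()


@pytest.fixture(scope="session")
def charlson_map():
    return load_charlson_map()


@pytest.fixture(scope="session")
def cpi_identity():
    return CpiTable.identity()


@pytest.fixture(scope="session")
def edge_tables():
    tables = generate_population(SimConfig(n_patients=300, seed=7))
    return inject_edge_cases(tables)


@pytest.fixture(scope="session")
def edge_run(edge_tables):
    return run_analysis(edge_tables, StudyConfig())


@pytest.fixture(scope="session")
def big_tables():
    return generate_population(SimConfig(n_patients=5000, seed=11))


@pytest.fixture(scope="session")
def big_run(big_tables):
    return run_analysis(big_tables, StudyConfig())
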