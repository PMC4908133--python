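from __future__ import annotations

import numpy as np
import pytest

from tagdge import mapping, qc, reference, simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(n_genes=300, depth=100_000, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_db(small_study):
    return reference.scan_catg_tags(small_study["transcripts"])


@pytest.fixture(scope="session")
def small_clean(small_study):
    return {
        stage: qc.filter_raw_tags(lib)[0]
        for stage, lib in small_study["libraries"].items()
    }


@pytest.fixture(scope="session")
def small_assignments(small_clean, small_db):
    out = {}
    for stage, clean in small_clean.items():
        out[stage] = mapping.map_tags(clean, small_db)
    return out


@pytest.fixture(scope="session")
def small_table(small_assignments, small_clean, small_study):
    return mapping.quantify(
        {s: a for s, (a, _) in small_assignments.items()},
        small_clean,
        [t.gene_id for t in small_study["transcripts"]],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
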