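"""Shared fixtures: one session-scoped synthetic dataset at desk scale."""

import warnings

import pytest

from plastohotspot import extract_syntenic_loci, mean_sv_table
from plastohotspot.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def desk_dataset():
    """10 ingroup taxa + 3 outgroups + reference, 15 kb, 4 hotspot loci."""
    cfg = SimConfig.desk(seed=2)
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def desk_loci(desk_dataset):
    _, records, _ = desk_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_syntenic_loci(records, reference_id="REF")


@pytest.fixture(scope="session")
def desk_sv_table(desk_loci):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mean_sv_table(desk_loci)
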