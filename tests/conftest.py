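import dataclasses

import pytest

from starcohort import default_heart_surgery_config, generate

from .oracle import WarehouseDump
from .toybuild import Toy


@pytest.fixture()
def toy(tmp_path):
    return Toy(tmp_path / "toy.sqlite")


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """Moderate synthetic warehouse shared across read-only tests."""
    path = tmp_path_factory.mktemp("synth") / "small.sqlite"
    cfg = default_heart_surgery_config(300, seed=11)
    db, truth = generate(cfg, str(path))
    return db, truth, cfg


@pytest.fixture(scope="session")
def oracle_db(tmp_path_factory):
    """Small warehouse (≤10,000 facts) for brute-force cross-checks."""
    path = tmp_path_factory.mktemp("synth") / "oracle.sqlite"
    cfg = dataclasses.replace(
        default_heart_surgery_config(100, seed=5), followup_days=365
    )
    db, truth = generate(cfg, str(path))
    dump = WarehouseDump(db)
    assert dump.n_facts() <= 10_000
    return db, truth, dump
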