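import pathlib

import pytest
from hypothesis import HealthCheck, settings

from neohybrid.synthetic_data import WorldConfig, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


SMALL_WORLD = dict(
    n_regions=60,
    n_genera=200,
    n_genera_checklist=150,
    n_triplets=12,
    seed=123,
)


@pytest.fixture(scope="session")
def world_dir(tmp_path_factory) -> pathlib.Path:
    """A small synthetic world shared across the suite (seeded, read-only)."""
    d = tmp_path_factory.mktemp("world")
    simulate(WorldConfig(**SMALL_WORLD), d)
    return d


@pytest.fixture(scope="session")
def world_truth(world_dir):
    import json

    return json.loads((world_dir / "ground_truth.json").read_text())


@pytest.fixture()
def four_tip_tree(tmp_path):
    """The hand-solvable balanced 4-tip tree ((A:1,B:1):1,(C:1,D:1):1)."""
    from neohybrid import read_tree

    p = tmp_path / "four.nwk"
    p.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
    return read_tree(p).records
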