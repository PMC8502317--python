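import numpy as np
import pytest

from engage.catalog import build_default_catalogs
from engage.synthetic import SimulationConfig, fixture_table3, generate_cohort


@pytest.fixture(scope="session")
def catalog():
    return build_default_catalogs()


@pytest.fixture(scope="session")
def table3_records():
    return {rec.parent_id: rec for rec in fixture_table3()}


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """One modest synthetic cohort reused across read-only tests."""
    cfg = SimulationConfig(seed=20260930, n_parents_per_arm=8)
    return generate_cohort(cfg, catalog)


def random_record(rng: np.random.Generator, catalog):
    """A random valid participation record in a random arm."""
    from engage.records import ParentRecord

    key = list(catalog.arms)[rng.integers(len(catalog.arms))]
    arm = catalog.arms[key]
    counts = {}
    for name in sorted(arm.offered):
        if rng.random() < 0.4:
            continue
        rule = catalog.activity(name).frequency_rule
        if rule.kind == "per_timepoint_binned":
            counts[name] = tuple(
                int(c) for c in rng.integers(0, rule.max_raw + 1, size=rule.timepoints)
            )
        else:
            counts[name] = int(rng.integers(0, rule.max_raw + 1))
    return ParentRecord(f"r{rng.integers(1 << 30)}", key[0], key[1], counts)
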