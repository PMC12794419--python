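import numpy as np
import pandas as pd
import pytest

from polarisc import (
    Region,
    RunConfig,
    SimulationConfig,
    compute_ias,
    generate_cohort,
    grouped_isc,
    median_split,
    prepare_cohort,
)


def tiny_simulation_config(**overrides) -> SimulationConfig:
    """A fast cohort with a strong planted contrast: 5 subjects per group,
    6^3 grid, 12 statements, 60% group share (detectable through the
    exhaustive 2^10-flip permutation null on a 216-voxel family)."""
    base = dict(
        n_per_group=5,
        grid_shape=(6, 6, 6),
        n_statements=12,
        common_share=0.6,
        group_share=0.6,
        noise_share=0.4,
        polarized_region_spec=(
            Region((1, 1, 1), 1.5, "both"),
            Region((4, 4, 4), 1.5, "anti"),
        ),
        common_region_spec=(Region((4, 1, 4), 1.2),),
        seed=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_simulation_config()


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_config, tiny_cohort):
    """Prepared time series, median-split assignment and grouped maps."""
    rc = RunConfig(simulation=tiny_config, n_perm=500, seed=1)
    prepared, kept, excluded = prepare_cohort(tiny_cohort, rc)
    assignment = median_split(compute_ias(tiny_cohort.ratings))
    maps = grouped_isc(prepared, assignment)
    return dict(prepared=prepared, kept=kept, excluded=excluded,
                assignment=assignment, maps=maps, cohort=tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_ratings(per_subject: dict[str, dict[str, list[int]]]) -> pd.DataFrame:
    """Long ratings table from {subject: {'pro': [...], 'anti': [...]}}."""
    rows = []
    for sid, by_type in per_subject.items():
        i = 0
        for stype, vals in by_type.items():
            for v in vals:
                rows.append(dict(subject_id=sid, statement_id=f"s{i:03d}",
                                 statement_type=stype, rating=v))
                i += 1
    return pd.DataFrame(rows)
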