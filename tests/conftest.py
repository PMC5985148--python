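import numpy as np
import pytest

from canalize.io import Dataset, SpecimenRecord
from canalize.simulate import simulate_populations, table1_template
from canalize.variation import filter_min_individuals, summarize_dataset


def make_record(sid, species, period, arms, **kw):
    return SpecimenRecord(
        specimen_id=sid, species=species, period=period,
        arm_counts=tuple(arms), **kw,
    )


@pytest.fixture
def tiny_dataset():
    """Two species, two periods, hand-countable numbers."""
    return Dataset(
        [
            make_record("A1", "Alpha sp", "Ordovician", (2, 3)),
            make_record("A2", "Alpha sp", "Ordovician", (3, 4)),
            make_record("B1", "Beta sp", "Silurian", (3, 3, 3)),
            make_record("B2", "Beta sp", "Silurian", (3,)),
        ],
        provenance="hand-built fixture",
    )


@pytest.fixture(scope="session")
def template_run():
    """One template-composition simulation shared across tests: the
    dataset, its truth dict, all summaries, and the filtered subset."""
    ds, truth = simulate_populations(table1_template(), seed=11)
    summaries = summarize_dataset(ds.records)
    filtered = filter_min_individuals(summaries, 5)
    return ds, truth, summaries, filtered


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
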