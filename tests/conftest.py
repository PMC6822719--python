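import hypothesis
import numpy as np
import pytest

from seedfate.plates import (
    CONTROL,
    Dataset,
    PlateRecord,
    Species,
    Temperature,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_record(group, temp, rep, species, counts, n_total=10):
    g, d, dorm = counts
    return PlateRecord(
        group=group,
        temperature=Temperature(temp),
        replicate=rep,
        species=Species(species),
        n_germinated=g,
        n_dead=d,
        n_dormant=dorm,
        n_total=n_total,
    )


def build_dataset(cells, n_total=10):
    """Build a Dataset from {(group, temp): [(brto_counts, plov_counts), ...]}.

    Each replicate entry is a pair of (germ, dead, dormant) tuples, one per
    species, so plates are always paired.
    """
    records = []
    for (group, temp), plates in cells.items():
        for rep, (brto, plov) in enumerate(plates, start=1):
            records.append(make_record(group, temp, rep, "BRTO", brto, n_total))
            records.append(make_record(group, temp, rep, "PLOV", plov, n_total))
    return Dataset(records=tuple(records))


def germination_dataset(group_germ, control_germ, temp="summer", n_total=10):
    """Paired dataset where only germination counts vary; one strain + control.

    ``group_germ`` / ``control_germ`` are lists of germinated counts applied
    to both species identically.
    """
    cells = {
        ("01", temp): [((g, 0, n_total - g), (g, 0, n_total - g)) for g in group_germ],
        (CONTROL, temp): [
            ((g, 0, n_total - g), (g, 0, n_total - g)) for g in control_germ
        ],
    }
    return build_dataset(cells, n_total=n_total)


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


@pytest.fixture(scope="session")
def strain_table():
    from seedfate.plates import load_strain_metadata

    return load_strain_metadata()


@pytest.fixture(scope="session")
def standard_dataset():
    """One draw of the full 18-strain x 2-regime x 5-replicate design."""
    from seedfate.simulate import generate, standard_design_config

    return generate(standard_design_config(rng_seed=11))
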