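import numpy as np
import pytest

from metasex.genome import ChromRecord, GenomeSpec, Role, SexSystem, bundled_spec
from metasex.idxstats import IdxstatsRow, IdxstatsTable
from metasex.kde import train_model
from metasex.simulate import TRAINING_DEPTHS, SimParams, samples_to_metrics, simulate_grid


def make_table(counts, lengths, sample_id="s1"):
    """Build an IdxstatsTable from {id: mapped} and {id: length} mappings."""
    rows = {
        cid: IdxstatsRow(length=int(lengths[cid]), mapped=int(n), unmapped=0)
        for cid, n in counts.items()
    }
    rows["*"] = IdxstatsRow(length=0, mapped=0, unmapped=0)
    return IdxstatsTable(sample_id=sample_id, rows=rows)


def table_for_spec(spec, counts, sample_id="s1"):
    lengths = {rec.id: rec.length for rec in spec.chromosomes}
    return make_table(counts, lengths, sample_id=sample_id)


@pytest.fixture
def tiny_spec():
    """Three-chromosome XY toy: A (1 kb), X (0.5 kb), Y (0.1 kb)."""
    return GenomeSpec(
        system=SexSystem.XY,
        chromosomes=(
            ChromRecord(id="A", length=1000, role=Role.AUTOSOME),
            ChromRecord(id="X", length=500, role=Role.SEX_HOMOGAMETIC),
            ChromRecord(id="Y", length=100, role=Role.SEX_HETEROGAMETIC),
        ),
    )


@pytest.fixture
def toy_spec():
    """Two-autosome XY toy matching the worked coverage examples."""
    return GenomeSpec(
        system=SexSystem.XY,
        chromosomes=(
            ChromRecord(id="A1", length=100, role=Role.AUTOSOME),
            ChromRecord(id="A2", length=200, role=Role.AUTOSOME),
            ChromRecord(id="X", length=150, role=Role.SEX_HOMOGAMETIC),
            ChromRecord(id="Y", length=50, role=Role.SEX_HETEROGAMETIC),
        ),
    )


@pytest.fixture(scope="session")
def human_spec():
    return bundled_spec("human")


@pytest.fixture(scope="session")
def small_model(human_spec):
    """KDE model trained on a reduced grid: 12 depths x 2 sexes x 100 reps."""
    params = SimParams(
        spec=human_spec, depth_targets=TRAINING_DEPTHS, replicates_per_cell=100, seed=7
    )
    samples = simulate_grid(params)
    return train_model(samples_to_metrics(samples, human_spec), human_spec.system, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
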