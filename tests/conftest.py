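import numpy as np
import pytest

from regumirror.formats import DEGRecord, DEGTable
from regumirror.simulate import gen_regulatory_fixture, load_fixture


def make_table(rows, dataset_id="t", species="mouse"):
    """rows: iterable of (gene, log2fc, padj-or-None)."""
    return DEGTable(
        dataset_id=dataset_id,
        species=species,
        records=[DEGRecord(g, lfc, padj) for g, lfc, padj in rows],
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One generated regulatory fixture shared across the session."""
    d = tmp_path_factory.mktemp("regfix")
    truth = gen_regulatory_fixture(
        n_genes=48, n_targets=19, decoys_per_stage=3, seed=11, out_dir=d
    )
    return d, truth


@pytest.fixture(scope="session")
def fixture_inputs(fixture_dir):
    d, _truth = fixture_dir
    return load_fixture(d)


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)
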