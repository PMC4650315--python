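import numpy as np
import pytest

from clockminer import DatasetRecord, HitMatrix, Registry, paper_registry


@pytest.fixture(scope="session")
def registry():
    return paper_registry()


@pytest.fixture
def toy_registry():
    """Two unit-weight datasets of 5 expected hits over 10 genes."""
    return Registry(
        records=(
            DatasetRecord("d1", "toy one", "chipseq", 1, "ebox", 5),
            DatasetRecord("d2", "toy two", "proteomics", 1, "none", 5),
        ),
        n_genes=10,
    )


@pytest.fixture
def full_hit_gene(registry):
    """A 3-gene matrix: one gene hit everywhere, one nowhere, one only in the
    weight-3 dataset."""
    values = np.zeros((3, len(registry)), dtype=np.int8)
    values[0, :] = 1
    values[2, registry.dataset_ids.index("rey_bmal1")] = 1
    return HitMatrix(
        gene_ids=("all_hits", "no_hits", "rey_only"),
        dataset_ids=registry.dataset_ids,
        values=values,
    )
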