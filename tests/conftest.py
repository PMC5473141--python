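from pathlib import Path

import pytest

from splice_shift.annotation import GeneModel, GeneModelSet

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def two_exon_gene() -> GeneModel:
    return GeneModel("g1", "chr1", "+", ((1, 100), (201, 300)))


@pytest.fixture
def three_exon_gene() -> GeneModel:
    return GeneModel("g3", "chr2", "+", ((1, 100), (201, 300), (401, 500)))


@pytest.fixture
def minus_three_exon_gene() -> GeneModel:
    return GeneModel("gm", "chr1", "-", ((1, 100), (201, 300), (401, 500)))


@pytest.fixture
def small_models(two_exon_gene, three_exon_gene) -> GeneModelSet:
    return GeneModelSet([two_exon_gene, three_exon_gene])


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR
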