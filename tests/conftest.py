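import pytest

from lariatfold.alu_catalog import AluCategory
from lariatfold.structure_stats import MaxPairFolder
from lariatfold.synthetic_data import make_genome


@pytest.fixture(scope="session")
def folder():
    return MaxPairFolder()


@pytest.fixture(scope="session")
def mixed_ledger():
    """Small genome with one intron of each Alu category."""
    plan = {
        "gene1.intron1": AluCategory.NONE,
        "gene2.intron1": AluCategory.SINGLE,
        "gene3.intron1": AluCategory.MULTI_SAME,
        "gene4.intron1": AluCategory.IR,
    }
    return make_genome(seed=11, n_genes=4, alu_plan=plan, intron_length_range=(900, 1100))


@pytest.fixture(scope="session")
def plain_ledger():
    """Alu-free genome for mapper tests (background only, unique 20-mers)."""
    return make_genome(seed=23, n_genes=4, intron_length_range=(400, 600))
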