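import numpy as np
import pytest

from mitochronos.mito_io import GeneEntry, GeneMap, MitogenomeRecord


@pytest.fixture
def toy_genemap() -> GeneMap:
    """One 12-nt plus-strand gene (3 codons + TAA), then a control region."""
    return GeneMap(
        entries=[
            GeneEntry("g1", 1, 12, "+", "protein"),
            GeneEntry("CR", 13, 22, "+", "control"),
        ],
        reference_id="ref",
    )


@pytest.fixture
def toy_reference() -> MitogenomeRecord:
    # g1: ATG GGA CTT TAA (Met Gly Leu stop); control: ACGTACGTAC
    return MitogenomeRecord(id="ref", sequence="ATGGGACTTTAA" + "ACGTACGTAC")


def mutate(record: MitogenomeRecord, position: int, base: str, new_id: str) -> MitogenomeRecord:
    seq = list(record.sequence)
    seq[position - 1] = base
    return MitogenomeRecord(id=new_id, sequence="".join(seq))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170705)
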