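import pytest

from cytgrn.grn_model import CytokineGRN, InteractionRecord
from cytgrn.synthetic_data import generate_world


def make_record(tf, cyt, species="human", assays=("functional",),
                activity="unknown", pmids=("1",)):
    return InteractionRecord(tf_symbol=tf, cytokine_symbol=cyt,
                             species=species,
                             assay_categories=frozenset(assays),
                             regulatory_activity=activity,
                             article_ids=tuple(pmids))


@pytest.fixture
def toy_grn():
    """TF degrees A:5, B:3, C:1, D:1 over seven cytokines."""
    edges = [("A", c) for c in ["IL6", "TNF", "IL10", "CCL2", "CCL5"]]
    edges += [("B", c) for c in ["IL6", "TNF", "IL4"]]
    edges += [("C", "IL6"), ("D", "IFNG")]
    records = [make_record(t, c) for t, c in edges]
    return CytokineGRN("human", records)


@pytest.fixture(scope="session")
def world():
    """One synthetic world shared by the recovery tests."""
    return generate_world(seed=11)
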