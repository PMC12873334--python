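import numpy as np
import pandas as pd
import pytest

from kgdemand.knowledge_graph import (
    DrugRecord,
    RelationEdge,
    assemble_graph,
    substitution_edges,
)
from kgdemand.synthetic_data import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_records():
    """Five drugs: two ATC level-4 groups plus one device."""
    return [
        DrugRecord("A", "Amoxicillin 500 mg", "amoxicillin", atc_code="J01CA04"),
        DrugRecord("B", "Ampicillin 250 mg", "ampicillin", atc_code="J01CA01"),
        DrugRecord("C", "Cefalexin 500 mg", "cefalexin", atc_code="J01DB01"),
        DrugRecord("D", "Cefadroxil 500 mg", "cefadroxil", atc_code="J01DB05"),
        DrugRecord("E", "mask", "mask", item_type="device"),
    ]


@pytest.fixture
def small_graph(small_records):
    edges = substitution_edges(small_records) + [RelationEdge("B", "C", "combination")]
    return assemble_graph(small_records, edges)


@pytest.fixture
def chain_graph():
    """Path graph A-B-C-D as a KnowledgeGraph."""
    records = [DrugRecord(x, x.lower(), x.lower()) for x in "ABCD"]
    edges = [
        RelationEdge("A", "B", "combination"),
        RelationEdge("B", "C", "combination"),
        RelationEdge("C", "D", "combination"),
    ]
    return assemble_graph(records, edges)


@pytest.fixture
def transactions():
    return pd.DataFrame(
        {
            "drug_id": ["X", "X", "X", "X", "Y"],
            "date": ["2023-01-02", "2023-01-04", "2023-01-06", "2023-01-18", "2023-01-03"],
            "quantity": [1, 2, 3, 5, 4],
        }
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulated dataset, shared across tests (read-only)."""
    return generate_dataset(SimConfig())


def random_adjacency(rng, n, p=0.4):
    """Random symmetric 0/1 adjacency with zero diagonal."""
    m = (rng.random((n, n)) < p).astype(float)
    m = np.triu(m, 1)
    return m + m.T
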