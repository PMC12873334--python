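"""Drug knowledge-graph construction.

Drugs are nodes; two relation types supply the edges:

* **substitution** — drugs sharing the same ATC level-4 chemical subgroup
  (identical first five characters of the seven-character ATC code) are
  treated as therapeutic substitutes;
* **combination** — drug pairs with a recorded drug–drug interaction (DDI),
  standing in for co-prescription.

Both relations carry a uniform edge weight of 1 in the adjacency matrix:
relative importance of neighbours is learned downstream by the GCN weight
matrices, not encoded in the graph. Medical devices and consumables have no
ATC code or DDI records and therefore stay isolated nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DrugRecord",
    "RelationEdge",
    "KnowledgeGraph",
    "clean_product_name",
    "match_catalog",
    "substitution_edges",
    "combination_edges",
    "assemble_graph",
    "khop_subgraph",
]

SUBSTITUTION = "substitution"
COMBINATION = "combination"

#: ATC level 4 (chemical subgroup) is the first five characters of the code.
ATC_LEVEL4_LEN = 5

_UNIT = r"(?:mg|mcg|µg|ug|g|ml|l|iu|%)"
# number + unit, optionally a compound like "120 mg/5 ml"
_DOSE_RE = re.compile(
    rf"\b\d+(?:[.,]\d+)?\s*{_UNIT}(?:\s*/\s*\d*(?:[.,]\d+)?\s*{_UNIT})?(?=\s|$)",
    flags=re.IGNORECASE,
)
# pack counts: "x10", "x 10", "10's", "10s"
_PACK_RE = re.compile(r"\b(?:x\s*\d+|\d+\s*'?s)\b", flags=re.IGNORECASE)


@dataclass(frozen=True)
class DrugRecord:
    """One catalog item: a pharmaceutical drug or a medical device."""

    drug_id: str
    raw_name: str
    core_name: str
    item_type: str = "pharmaceutical"  # or "device"
    inn_name: str | None = None
    atc_code: str | None = None

    def __post_init__(self) -> None:
        if self.item_type not in ("pharmaceutical", "device"):
            raise ValueError(f"unknown item_type {self.item_type!r}")
        if self.item_type == "device" and self.atc_code is not None:
            raise ValueError("device records carry no ATC code")


@dataclass(frozen=True)
class RelationEdge:
    """Unordered drug pair with a relation label; endpoints stored sorted."""

    endpoint_a: str
    endpoint_b: str
    relation: str

    def __post_init__(self) -> None:
        if self.endpoint_a == self.endpoint_b:
            raise ValueError("self-edges are not allowed")
        if self.relation not in (SUBSTITUTION, COMBINATION):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.endpoint_a > self.endpoint_b:
            a, b = self.endpoint_b, self.endpoint_a
            object.__setattr__(self, "endpoint_a", a)
            object.__setattr__(self, "endpoint_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.endpoint_a, self.endpoint_b)


@dataclass
class KnowledgeGraph:
    """Binary symmetric adjacency over an ordered drug index.

    ``adjacency`` has a zero diagonal: self-loops are added later by the
    GCN normalisation, not stored in the graph.
    """

    node_index: list[str]
    adjacency: np.ndarray
    relation_labels: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.node_index)
        a = np.asarray(self.adjacency)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} != ({n}, {n})")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1-valued")
        self.adjacency = a.astype(float)
        self._position = {d: i for i, d in enumerate(self.node_index)}
        if len(self._position) != n:
            raise ValueError("duplicate drug_id in node_index")

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    def position(self, drug_id: str) -> int:
        try:
            return self._position[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug_id {drug_id!r}") from None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_index)
        rows, cols = np.nonzero(np.triu(self.adjacency))
        for i, j in zip(rows, cols):
            pair = tuple(sorted((self.node_index[i], self.node_index[j])))
            g.add_edge(*pair, relations=sorted(self.relation_labels.get(pair, ())))
        return g

    def edge_list(self) -> pd.DataFrame:
        """Long-form edge table (one row per pair-relation)."""
        rows = [
            {"drug_id_a": a, "drug_id_b": b, "relation": rel}
            for (a, b), rels in sorted(self.relation_labels.items())
            for rel in sorted(rels)
        ]
        return pd.DataFrame(rows, columns=["drug_id_a", "drug_id_b", "relation"])


def clean_product_name(raw_name: str) -> str:
    """Strip dosage/strength and pack-count tokens from a product name.

    Lower-cases, removes number+unit tokens (``500 mg``, ``120 mg/5 ml``,
    ``5%``, ``x10``, ``10's``) and collapses whitespace, retaining the core
    drug name used for INN standardisation.
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise ValueError("raw_name must be a non-empty string")
    name = raw_name.lower()
    name = _DOSE_RE.sub(" ", name)
    name = _PACK_RE.sub(" ", name)
    return " ".join(name.split())


def _as_unique_mapping(table: Mapping[str, str] | pd.DataFrame, key: str, value: str) -> dict[str, str]:
    if isinstance(table, pd.DataFrame):
        if table[key].duplicated().any():
            dupes = table.loc[table[key].duplicated(), key].tolist()
            raise ValueError(f"duplicate keys in mapping table: {dupes}")
        return dict(zip(table[key], table[value]))
    return dict(table)


def match_catalog(
    core_names: Iterable[str],
    inn_map: Mapping[str, str] | pd.DataFrame,
    drug_db: Mapping[str, str] | pd.DataFrame,
    *,
    id_prefix: str = "D",
) -> tuple[list[DrugRecord], list[str]]:
    """Resolve core names to INN, then to an ATC code, via lookup tables.

    Names missing from either table land in ``unmatched``; nothing is
    silently dropped (``len(matched) + len(unmatched)`` equals the input
    count). Matched records get sequential ids ``{id_prefix}0001``…
    """
    inn_lookup = _as_unique_mapping(inn_map, "core_name", "inn")
    atc_lookup = _as_unique_mapping(drug_db, "inn", "atc_code")
    matched: list[DrugRecord] = []
    unmatched: list[str] = []
    for i, name in enumerate(core_names):
        inn = inn_lookup.get(name)
        atc = atc_lookup.get(inn) if inn is not None else None
        if inn is None or atc is None:
            unmatched.append(name)
            continue
        matched.append(
            DrugRecord(
                drug_id=f"{id_prefix}{i + 1:04d}",
                raw_name=name,
                core_name=name,
                inn_name=inn,
                atc_code=atc,
            )
        )
    return matched, unmatched


def substitution_edges(records: Iterable[DrugRecord]) -> list[RelationEdge]:
    """One substitution edge per pair sharing an ATC level-4 prefix.

    Records without an ATC code (devices) contribute no edges.
    """
    records = list(records)
    ids = [r.drug_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate drug_id in records")
    groups: dict[str, list[str]] = {}
    for r in records:
        if r.atc_code is None:
            continue
        if len(r.atc_code) < ATC_LEVEL4_LEN:
            raise ValueError(
                f"ATC code {r.atc_code!r} of {r.drug_id} shorter than {ATC_LEVEL4_LEN} characters"
            )
        groups.setdefault(r.atc_code[:ATC_LEVEL4_LEN], []).append(r.drug_id)
    edges = []
    for members in groups.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                edges.append(RelationEdge(a, b, SUBSTITUTION))
    return edges


def combination_edges(
    records: Iterable[DrugRecord],
    ddi_pairs: pd.DataFrame | Iterable[tuple[str, str]],
) -> list[RelationEdge]:
    """One combination edge per DDI pair with both endpoints in the catalog.

    The strict intersection with the catalog drops pairs referencing
    unknown drugs; order-swapped duplicates collapse to one edge, and
    degenerate rows (``a == b``) are rejected with a warning.
    """
    import warnings

    known = {r.drug_id for r in records}
    if isinstance(ddi_pairs, pd.DataFrame):
        pairs = list(zip(ddi_pairs["drug_id_a"], ddi_pairs["drug_id_b"]))
    else:
        pairs = list(ddi_pairs)
    seen: set[tuple[str, str]] = set()
    edges: list[RelationEdge] = []
    for a, b in pairs:
        if a == b:
            warnings.warn(f"DDI row with identical endpoints {a!r} rejected", stacklevel=2)
            continue
        if a not in known or b not in known:
            continue
        pair = tuple(sorted((a, b)))
        if pair in seen:
            continue
        seen.add(pair)
        edges.append(RelationEdge(pair[0], pair[1], COMBINATION))
    return edges


def assemble_graph(records: Iterable[DrugRecord], edges: Iterable[RelationEdge]) -> KnowledgeGraph:
    """Build the binary adjacency in catalog order with uniform edge weight 1.

    A pair related as both substitute and combination still has a single
    1-entry; the two labels are kept in ``relation_labels``. Devices remain
    isolated because no edge builder produces edges for them.
    """
    records = list(records)
    node_index = [r.drug_id for r in records]
    pos = {d: i for i, d in enumerate(node_index)}
    n = len(node_index)
    adjacency = np.zeros((n, n))
    labels: dict[tuple[str, str], set[str]] = {}
    for e in edges:
        if e.endpoint_a not in pos or e.endpoint_b not in pos:
            raise ValueError(f"edge {e.pair} references a drug_id outside the catalog")
        i, j = pos[e.endpoint_a], pos[e.endpoint_b]
        adjacency[i, j] = adjacency[j, i] = 1.0
        labels.setdefault(e.pair, set()).add(e.relation)
    return KnowledgeGraph(node_index=node_index, adjacency=adjacency, relation_labels=labels)


def khop_subgraph(
    graph: KnowledgeGraph, target: str, k: int = 2
) -> tuple[list[str], np.ndarray, int]:
    """Nodes within graph distance ``k`` of ``target`` plus induced adjacency.

    Returns ``(nodes, induced_adjacency, target_position)`` with nodes in
    catalog order. ``k`` defaults to 2, the receptive field of the two-layer
    GCN. ``k=0`` gives the single-node graph of the target.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    graph.position(target)  # raises KeyError on unknown target
    g = graph.to_networkx()
    lengths = nx.single_source_shortest_path_length(g, target, cutoff=k)
    order = {d: i for i, d in enumerate(graph.node_index)}
    nodes = sorted(lengths, key=order.__getitem__)
    idx = np.array([order[d] for d in nodes])
    induced = graph.adjacency[np.ix_(idx, idx)]
    return nodes, induced, nodes.index(target)
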