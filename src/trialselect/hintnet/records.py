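"""Domain records: trials and the disease-code ontology."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["TrialRecord", "Ontology", "NODE_NAMES", "K_NODES", "PHASES"]

PHASES = ("I", "II", "III")

# Fixed row order of the layer-0 node-embedding matrix: the three input nodes
# (disease, drug, protocol), the six pretrained knowledge nodes (five ADMET
# properties plus disease risk), the three aggregation nodes and the
# prediction node.
NODE_NAMES = (
    "disease", "drug", "protocol",
    "absorption", "distribution", "metabolism", "excretion", "toxicity",
    "disease_risk",
    "pk", "interaction", "augmented",
    "prediction",
)
K_NODES = len(NODE_NAMES)
assert K_NODES == 13


@dataclass
class TrialRecord:
    """One clinical trial: its treatment set, target diseases and protocol.

    ``drugs`` holds SMILES strings, ``diseases`` ontology codes, and
    ``protocol`` (tag, sentence) pairs where tag is '+' for inclusion and '-'
    for exclusion criteria.  ``label`` is 1 for an approved trial, 0 for a
    failed one, and None before the outcome is known.
    """

    trial_id: str
    drugs: list[str]
    diseases: list[str]
    protocol: list[tuple[str, str]] = field(default_factory=list)
    phase: str = "I"
    start_date: _dt.date | None = None
    completion_date: _dt.date | None = None
    label: int | None = None

    def __post_init__(self):
        if not self.drugs:
            raise ValueError(f"trial {self.trial_id}: needs at least one drug")
        if not self.diseases:
            raise ValueError(f"trial {self.trial_id}: needs at least one disease")
        if self.phase not in PHASES:
            raise ValueError(f"trial {self.trial_id}: phase must be one of {PHASES}")
        for tag, _ in self.protocol:
            if tag not in ("+", "-"):
                raise ValueError(f"trial {self.trial_id}: criterion tag {tag!r}")
        if (self.start_date is not None and self.completion_date is not None
                and self.completion_date < self.start_date):
            raise ValueError(f"trial {self.trial_id}: completion before start")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"trial {self.trial_id}: label must be 0/1")

    @property
    def inclusion(self) -> list[str]:
        return [s for t, s in self.protocol if t == "+"]

    @property
    def exclusion(self) -> list[str]:
        return [s for t, s in self.protocol if t == "-"]


class Ontology:
    """A rooted DAG of disease codes (ICD-10-like hierarchy).

    Stores child -> parent edges; ancestor queries return the code itself
    plus all its ancestors up to the single root, the set the hierarchical
    disease encoder attends over.
    """

    def __init__(self, parent_edges: list[tuple[str, str]]):
        g = nx.DiGraph()
        for child, parent in parent_edges:
            if child == parent:
                raise ValueError(f"self-edge on code {child!r}")
            g.add_edge(child, parent)
        if g.number_of_nodes() == 0:
            raise ValueError("empty ontology")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology has a cycle through edge {cycle[0][:2]}")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have a single root, found {sorted(roots)}")
        self._graph = g
        self.root = roots[0]
        self.codes = frozenset(g.nodes)
        self._ancestor_cache: dict[str, tuple[str, ...]] = {}

    @classmethod
    def single_root(cls, root: str = "ROOT") -> "Ontology":
        ont = cls.__new__(cls)
        g = nx.DiGraph()
        g.add_node(root)
        ont._graph = g
        ont.root = root
        ont.codes = frozenset([root])
        ont._ancestor_cache = {}
        return ont

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    def ancestors(self, code: str) -> tuple[str, ...]:
        """The code itself plus every ancestor, ordered code -> root."""
        if code not in self.codes:
            raise KeyError(f"unknown ontology code {code!r}")
        if code not in self._ancestor_cache:
            anc = list(nx.topological_sort(
                self._graph.subgraph({code} | nx.descendants(self._graph, code))))
            self._ancestor_cache[code] = tuple(anc)
        return self._ancestor_cache[code]

    def leaves(self) -> list[str]:
        return sorted(n for n in self._graph.nodes if self._graph.in_degree(n) == 0)

    def parent_edges(self) -> list[tuple[str, str]]:
        return sorted(self._graph.edges)
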