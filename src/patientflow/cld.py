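"""Signed causal loop diagrams: feedback loop enumeration and polarity.

A causal loop diagram (CLD) is a signed directed graph: each link
``source -> target`` carries a polarity (POSITIVE: the target moves in
the same direction as the source; NEGATIVE: opposite).  A feedback loop
is a simple directed cycle; its polarity follows the parity rule — the
loop is REINFORCING when it contains an even number of negative links
(the product of link signs is positive) and BALANCING otherwise.

The packaged reference diagram encodes the feedback structure of a
patient-centric healthcare system: a core chain through which engagement,
satisfaction, participation, education and empowerment reinforce
patient-centric care; technology-integration and digital-health loops;
a resource-optimization loop; and a single balancing loop in which the
insurance authorization process constrains resource allocation.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from itertools import pairwise

import networkx as nx

__all__ = [
    "Polarity",
    "LoopPolarity",
    "CausalLink",
    "CausalGraph",
    "FeedbackLoop",
    "CLDError",
    "classify_loop",
    "find_feedback_loops",
    "reference_cld",
    "export_dot",
    "load_edge_csv",
    "save_edge_csv",
]


class Polarity(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class LoopPolarity(str, Enum):
    REINFORCING = "REINFORCING"
    BALANCING = "BALANCING"


class CLDError(ValueError):
    """Raised for structural problems: codes NOT_A_CYCLE, LIMIT_EXCEEDED,
    DUPLICATE_LINK, UNKNOWN_NODE, SELF_LOOP."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


@dataclass(frozen=True)
class CausalLink:
    """One signed influence; ``provenance`` records the narrative basis
    for including the edge (encoded diagrams are reconstructions)."""

    source: str
    target: str
    polarity: Polarity = Polarity.POSITIVE
    provenance: str = field(default="", compare=False)

    def __post_init__(self):
        if self.source == self.target:
            raise CLDError("SELF_LOOP", f"self-link on {self.source!r}")
        object.__setattr__(self, "polarity", Polarity(self.polarity))


@dataclass(frozen=True)
class CausalGraph:
    """A signed digraph; at most one link per ordered node pair."""

    nodes: frozenset[str]
    links: tuple[CausalLink, ...]

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "links", tuple(self.links))
        seen = set()
        for link in self.links:
            pair = (link.source, link.target)
            if pair in seen:
                raise CLDError("DUPLICATE_LINK", f"duplicate link {pair}")
            seen.add(pair)
            for node in pair:
                if node not in self.nodes:
                    raise CLDError("UNKNOWN_NODE", f"link endpoint {node!r} not in nodes")

    @classmethod
    def from_links(cls, links: list[CausalLink] | tuple[CausalLink, ...]) -> "CausalGraph":
        nodes = {l.source for l in links} | {l.target for l in links}
        return cls(nodes=frozenset(nodes), links=tuple(links))

    def link(self, source: str, target: str) -> CausalLink:
        for l in self.links:
            if l.source == source and l.target == target:
                return l
        raise CLDError("UNKNOWN_NODE", f"no link {source!r} -> {target!r}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for l in self.links:
            g.add_edge(l.source, l.target, polarity=l.polarity)
        return g


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with its traversed links and polarity.

    ``cycle`` lists the nodes in traversal order starting from the
    lexicographically smallest node; the closing edge back to the first
    node is implied.
    """

    cycle: tuple[str, ...]
    links: tuple[CausalLink, ...]
    polarity: LoopPolarity

    def __len__(self) -> int:
        return len(self.cycle)


def classify_loop(links: list[CausalLink] | tuple[CausalLink, ...]) -> LoopPolarity:
    """Polarity of a cycle of links: REINFORCING iff the number of
    NEGATIVE links is even (equivalently, the product of signs is +1)."""
    links = tuple(links)
    if not links:
        raise CLDError("NOT_A_CYCLE", "empty link list")
    for a, b in pairwise(links):
        if a.target != b.source:
            raise CLDError("NOT_A_CYCLE", f"link into {b.source!r} does not follow {a.target!r}")
    if links[-1].target != links[0].source:
        raise CLDError("NOT_A_CYCLE", "links do not close into a cycle")
    negatives = sum(1 for l in links if l.polarity is Polarity.NEGATIVE)
    return LoopPolarity.REINFORCING if negatives % 2 == 0 else LoopPolarity.BALANCING


def _canonical(cycle: list[str]) -> tuple[str, ...]:
    """Rotate a cycle so it starts at its lexicographically smallest node."""
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def find_feedback_loops(
    graph: CausalGraph, max_len: int = 12, *, cap: int = 10_000
) -> list[FeedbackLoop]:
    """Enumerate every simple directed cycle of length <= ``max_len``.

    Each loop is returned exactly once in canonical rotation, with its
    computed polarity.  Results are sorted (by length, then node tuple)
    so enumeration is invariant to input link ordering.  Raises
    ``CLDError(LIMIT_EXCEEDED)`` if more than ``cap`` cycles are found,
    which guards against pathological dense graphs.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    g = graph.to_networkx()
    loops: list[FeedbackLoop] = []
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        if len(cycle) < 2:
            continue  # self-loops are rejected at construction anyway
        nodes = _canonical(list(cycle))
        links = tuple(
            graph.link(nodes[i], nodes[(i + 1) % len(nodes)]) for i in range(len(nodes))
        )
        loops.append(FeedbackLoop(cycle=nodes, links=links, polarity=classify_loop(links)))
        if len(loops) > cap:
            raise CLDError("LIMIT_EXCEEDED", f"more than {cap} cycles; raise the cap explicitly")
    loops.sort(key=lambda lp: (len(lp.cycle), lp.cycle))
    return loops


def export_dot(graph: CausalGraph) -> str:
    """Deterministic Graphviz DOT text; negative links are dashed and
    labelled with a minus sign."""
    lines = ["digraph CLD {", '  rankdir=LR;']
    for node in sorted(graph.nodes):
        lines.append(f'  "{node}";')
    for link in sorted(graph.links, key=lambda l: (l.source, l.target)):
        if link.polarity is Polarity.NEGATIVE:
            attrs = ' [style=dashed, label="−"]'
        else:
            attrs = ' [label="+"]'
        lines.append(f'  "{link.source}" -> "{link.target}"{attrs};')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# edge-list CSV round trip


_CSV_HEADER = ["source", "target", "polarity", "provenance"]


def save_edge_csv(graph: CausalGraph) -> str:
    """Serialize as edge-list CSV (source, target, polarity, provenance)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_HEADER)
    for link in sorted(graph.links, key=lambda l: (l.source, l.target)):
        writer.writerow([link.source, link.target, link.polarity.value, link.provenance])
    return buf.getvalue()


def load_edge_csv(text: str) -> CausalGraph:
    reader = csv.reader(_io.StringIO(text))
    header = next(reader)
    if header != _CSV_HEADER:
        raise CLDError("UNKNOWN_NODE", f"bad edge CSV header {header!r}")
    links = [
        CausalLink(row[0], row[1], Polarity(row[2]), row[3] if len(row) > 3 else "")
        for row in reader
        if row
    ]
    return CausalGraph.from_links(links)


def reference_cld() -> CausalGraph:
    """The packaged patient-centric causal loop diagram.

    Encodes the feedback structure described for the healthcare system:

    * the patient-centric care chain — engagement raises satisfaction,
      satisfaction drives active participation, participation feeds
      education programs, outcome-informed practices and empowerment,
      which close back into patient-centric care and engagement;
    * an intention chain — perceived usefulness and ease of use raise
      patients' intention to participate, which feeds engagement, and
      better clinical outcomes feed back into perceived usefulness;
    * two technology-integration loops — service creation, iterative
      correction, smooth tech integration and continuous improvement;
      and tech integration enabling telecare-based health tracking that
      empowers patients and sustains the improvement cycle;
    * a digital-health loop — patient experience drives digital health
      innovation and tools, which empower patients and improve their
      experience;
    * a resource-optimization loop — resource allocation supports
      streamlined delivery and quality of care, sustaining long-term
      viability and provider incentives that replenish allocation;
    * the authorization balancing loop — rising resource allocation
      expands service requests, requests trigger utilization review,
      and authorization denials constrain further allocation (the one
      negative link).

    The exact edge list of the source diagram is not published as data;
    each packaged edge carries a provenance note naming the narrative
    relationship it encodes.
    """
    text = resources.files("patientflow.data").joinpath("cld_edges.csv").read_text()
    return load_edge_csv(text)
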