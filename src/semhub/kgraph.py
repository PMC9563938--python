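"""Typed heterogeneous predication knowledge graph.

Nodes are biomedical concepts carrying a semantic-type code (UMLS-style:
DSYN disease/syndrome, PHSU pharmacologic substance, GNGM gene/genome,
AAPP protein, BACS biologically active substance, TOPP procedure, ...).
Edges are directed subject--PREDICATE--object predications weighted by
occurrence count; duplicate triples are merged by summing counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

#: Semantic-type registry seed; unknown types are accepted with a warning
#: and registered on the fly.
KNOWN_NTYPES = {"DSYN", "TOPP", "AAPP", "BACS", "GNGM", "PHSU", "NEOP",
                "ORCH", "CELC"}

#: Predicates used for entity prediction from hub nodes.
SIX_PREDICATES = ("CAUSES", "PRECEDES", "AUGMENTS", "DISRUPTS",
                  "STIMULATES", "AFFECTS")

#: Node types admitted into predicted hub neighborhoods.
FIVE_NTYPES = ("AAPP", "BACS", "DSYN", "GNGM", "PHSU")

#: Generic high-frequency concepts that add noise rather than signal;
#: matched on normalized lowercase name or on id.  User-extensible.
DEFAULT_GENERIC_STOPLIST = frozenset({"protein", "complication", "infection",
                                      "disease"})


@dataclass(frozen=True)
class Node:
    id: str
    name: str
    ntype: str


@dataclass(frozen=True)
class Edge:
    head: str
    predicate: str
    tail: str
    weight: float = 1.0


class KnowledgeGraph:
    """Directed typed multigraph keyed by concept id, with degree caches."""

    def __init__(self):
        self.nodes: dict[str, Node] = {}
        self.edges: dict[tuple[str, str, str], float] = {}
        self._out: dict[str, list[tuple[str, str]]] = {}   # head -> [(pred, tail)]
        self._in: dict[str, list[tuple[str, str]]] = {}    # tail -> [(pred, head)]
        self.ntypes: set[str] = set(KNOWN_NTYPES)

    # -- construction -------------------------------------------------------

    def add_node(self, node: Node) -> None:
        if node.ntype not in self.ntypes:
            log.warning("unknown semantic type %r registered", node.ntype)
            self.ntypes.add(node.ntype)
        existing = self.nodes.get(node.id)
        if existing is not None and existing != node:
            raise ValueError(f"conflicting redefinition of node {node.id}")
        self.nodes[node.id] = node
        self._out.setdefault(node.id, [])
        self._in.setdefault(node.id, [])

    def add_edge(self, head: str, predicate: str, tail: str,
                 weight: float = 1.0) -> None:
        if head not in self.nodes or tail not in self.nodes:
            raise KeyError(f"edge endpoints must exist: {head} -> {tail}")
        if weight <= 0:
            raise ValueError("edge weight must be positive")
        key = (head, predicate, tail)
        if key in self.edges:
            self.edges[key] += weight
        else:
            self.edges[key] = weight
            self._out[head].append((predicate, tail))
            self._in[tail].append((predicate, head))

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        g.ntypes = set(self.ntypes)
        for node in self.nodes.values():
            g.add_node(node)
        for (h, p, t), w in self.edges.items():
            g.add_edge(h, p, t, w)
        return g

    # -- queries ------------------------------------------------------------

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_of_type(self, ntypes) -> list[str]:
        allowed = set(ntypes)
        return sorted(i for i, n in self.nodes.items() if n.ntype in allowed)

    def _incident(self, node: str, direction: str):
        """Yield (predicate, neighbor, weight) under the direction filter."""
        if direction not in ("out", "in", "both"):
            raise ValueError(f"bad direction {direction!r}")
        if direction in ("out", "both"):
            for p, t in self._out[node]:
                yield p, t, self.edges[(node, p, t)]
        if direction in ("in", "both"):
            for p, h in self._in[node]:
                yield p, h, self.edges[(h, p, node)]

    def neighbors(self, node: str, predicates=None, ntypes=None,
                  direction: str = "both") -> list[tuple[str, float]]:
        """Unique neighbors with aggregated weights under the filters.

        Deterministic order: weight descending, then id.
        """
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        preds = set(predicates) if predicates is not None else None
        types = set(ntypes) if ntypes is not None else None
        agg: dict[str, float] = {}
        for p, other, w in self._incident(node, direction):
            if preds is not None and p not in preds:
                continue
            if types is not None and self.nodes[other].ntype not in types:
                continue
            agg[other] = agg.get(other, 0.0) + w
        return sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))

    def degree(self, node: str, scope: str = "total"):
        """Weighted and unweighted degree: scalar pair or per-key dict pairs.

        scope: "total", "per-predicate", or "per-ntype" (neighbor type).
        """
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        if scope == "total":
            ws = [w for _, _, w in self._incident(node, "both")]
            return sum(ws), len(ws)
        out: dict[str, tuple[float, int]] = {}
        for p, other, w in self._incident(node, "both"):
            key = p if scope == "per-predicate" else self.nodes[other].ntype
            tot, cnt = out.get(key, (0.0, 0))
            out[key] = (tot + w, cnt + 1)
        if scope not in ("per-predicate", "per-ntype"):
            raise ValueError(f"bad scope {scope!r}")
        return out

    def weighted_degree(self, node: str) -> float:
        return self.degree(node)[0]


def remove_generic_nodes(g: KnowledgeGraph,
                         stoplist=DEFAULT_GENERIC_STOPLIST) -> KnowledgeGraph:
    """Copy of ``g`` without stoplisted nodes (matched on lowercase name or
    id) and their incident edges; the input graph is unmodified."""
    stop = {s.lower() for s in stoplist}
    dropped = {i for i, n in g.nodes.items()
               if n.name.lower() in stop or n.id.lower() in stop or i in stoplist}
    out = KnowledgeGraph()
    out.ntypes = set(g.ntypes)
    for node in g.nodes.values():
        if node.id not in dropped:
            out.add_node(node)
    for (h, p, t), w in g.edges.items():
        if h not in dropped and t not in dropped:
            out.add_edge(h, p, t, w)
    return out


# ---------------------------------------------------------------------------
# predication TSV io
#
# Dialects: 8-column (..., count) and 7-column (unit count per row).

_COLUMNS = ("subject_id", "subject_name", "subject_type", "predicate",
            "object_id", "object_name", "object_type")


def load_predications(path, dialect: str = "auto",
                      delimiter: str = "\t") -> KnowledgeGraph:
    """Load SemMedDB-like predication rows into a KnowledgeGraph.

    Duplicate triples are merged by summing counts; a missing count column
    contributes weight 1 per row.  Malformed rows raise with a line number.
    """
    g = KnowledgeGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if dialect == "auto":
                row_dialect = {7: "7col", 8: "8col"}.get(len(fields))
                if row_dialect is None:
                    raise ValueError(
                        f"{path}:{lineno}: expected 7 or 8 columns, got {len(fields)}")
            else:
                row_dialect = dialect
                want = 8 if dialect == "8col" else 7
                if len(fields) != want:
                    raise ValueError(
                        f"{path}:{lineno}: expected {want} columns, got {len(fields)}")
            sid, sname, stype, pred, oid, oname, otype = fields[:7]
            if not (sid and oid and pred):
                raise ValueError(f"{path}:{lineno}: empty id or predicate")
            if row_dialect == "8col":
                try:
                    weight = float(fields[7])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad count {fields[7]!r}") from exc
            else:
                weight = 1.0
            for nid, name, ntype in ((sid, sname, stype.upper()),
                                     (oid, oname, otype.upper())):
                if nid not in g.nodes:
                    g.add_node(Node(id=nid, name=name, ntype=ntype))
            g.add_edge(sid, pred.upper(), oid, weight)
    return g


def write_predications(g: KnowledgeGraph, path, delimiter: str = "\t") -> None:
    """Canonical 8-column export: sorted by (head, predicate, tail)."""
    with open(path, "w") as fh:
        for (h, p, t) in sorted(g.edges):
            w = g.edges[(h, p, t)]
            s, o = g.nodes[h], g.nodes[t]
            wtxt = f"{int(w)}" if float(w).is_integer() else f"{w}"
            fh.write(delimiter.join(
                (s.id, s.name, s.ntype, p, o.id, o.name, o.ntype, wtxt)) + "\n")


def write_graph_tables(g: KnowledgeGraph, node_path, edge_path,
                       delimiter: str = "\t") -> None:
    with open(node_path, "w") as fh:
        fh.write(delimiter.join(("id", "name", "ntype")) + "\n")
        for nid in sorted(g.nodes):
            n = g.nodes[nid]
            fh.write(delimiter.join((n.id, n.name, n.ntype)) + "\n")
    with open(edge_path, "w") as fh:
        fh.write(delimiter.join(("head", "predicate", "tail", "weight")) + "\n")
        for (h, p, t) in sorted(g.edges):
            fh.write(delimiter.join((h, p, t, str(g.edges[(h, p, t)]))) + "\n")
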