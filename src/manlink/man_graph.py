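"""Molecular association network (MAN): typed nodes, typed undirected edges, I/O.

The MAN is an undirected heterogeneous graph over five molecule kinds
(drug, disease, protein, miRNA, lncRNA) connected by nine association
kinds.  All edges carry unit weight by default; the weight field is kept
for generality.  The graph object exposes the quantities the embedding
stage needs: per-node weighted degree ``d_a``, total edge weight ``W``
and neighbour lists ``N(i)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

NODE_KINDS = ("drug", "disease", "protein", "mirna", "lncrna")

#: The nine association kinds and the (unordered) endpoint kinds each connects.
EDGE_KINDS: dict[str, tuple[str, str]] = {
    "drug-disease": ("drug", "disease"),
    "drug-protein": ("drug", "protein"),
    "protein-protein": ("protein", "protein"),
    "protein-disease": ("protein", "disease"),
    "lncrna-protein": ("lncrna", "protein"),
    "lncrna-disease": ("lncrna", "disease"),
    "mirna-protein": ("mirna", "protein"),
    "mirna-disease": ("mirna", "disease"),
    "mirna-lncrna": ("mirna", "lncrna"),
}


class GraphError(ValueError):
    """Malformed input or inconsistent graph construction."""


def normalize_id(raw: str, kind: str) -> str:
    """Normalize a node identifier.

    Whitespace is trimmed for every kind; disease names are additionally
    case-folded (MeSH headings are written with inconsistent capitalisation
    across sources).  Drug / protein / RNA accessions are case-sensitive in
    their home databases and are kept verbatim.
    """
    out = raw.strip()
    if kind == "disease":
        out = out.casefold()
    if not out:
        raise GraphError(f"empty {kind} identifier after normalization: {raw!r}")
    return out


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node: (id, kind) is the unique key within a graph."""

    id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise GraphError(f"unknown node kind: {self.kind!r}")


@dataclass(frozen=True)
class AssociationEdge:
    """An undirected typed edge; endpoints are stored in sorted order."""

    u: NodeRef
    v: NodeRef
    edge_kind: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.edge_kind not in EDGE_KINDS:
            raise GraphError(f"unknown edge kind: {self.edge_kind!r}")
        if self.u == self.v:
            raise GraphError(f"self-loop on {self.u.id!r}")
        if self.weight <= 0:
            raise GraphError("edge weight must be positive")
        ku, kv = EDGE_KINDS[self.edge_kind]
        if {self.u.kind, self.v.kind} != {ku, kv}:
            raise GraphError(
                f"edge kind {self.edge_kind!r} incompatible with endpoints "
                f"({self.u.kind}, {self.v.kind})"
            )
        # canonical endpoint order so undirected duplicates hash equally
        if (self.v.kind, self.v.id) < (self.u.kind, self.u.id):
            u, v = self.u, self.v
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)

    @property
    def key(self) -> tuple[NodeRef, NodeRef, str]:
        return (self.u, self.v, self.edge_kind)


class MANGraph:
    """Deduplicated undirected multi-kind association graph."""

    def __init__(self, edges: Iterable[AssociationEdge] = ()) -> None:
        self._edges: dict[tuple, AssociationEdge] = {}
        self._adj: dict[NodeRef, list[tuple[NodeRef, float]]] = {}
        for e in edges:
            self.add_edge(e)

    def add_edge(self, e: AssociationEdge) -> bool:
        """Add an edge; returns False if an identical undirected edge exists."""
        if e.key in self._edges:
            return False
        self._edges[e.key] = e
        self._adj.setdefault(e.u, []).append((e.v, e.weight))
        self._adj.setdefault(e.v, []).append((e.u, e.weight))
        return True

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> list[NodeRef]:
        return sorted(self._adj)

    @property
    def edges(self) -> list[AssociationEdge]:
        return list(self._edges.values())

    def __len__(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: NodeRef) -> bool:
        return node in self._adj

    def neighbors(self, node: NodeRef) -> list[tuple[NodeRef, float]]:
        return list(self._adj[node])

    def degree(self, node: NodeRef) -> float:
        """Weighted degree d_a = sum of incident edge weights."""
        return sum(w for _, w in self._adj[node])

    @property
    def total_weight(self) -> float:
        """W = sum of all edge weights."""
        return sum(e.weight for e in self._edges.values())

    def nodes_of_kind(self, kind: str) -> list[NodeRef]:
        return [n for n in self.nodes if n.kind == kind]

    def has_edge(self, a: NodeRef, b: NodeRef, edge_kind: str) -> bool:
        return AssociationEdge(a, b, edge_kind).key in self._edges

    def without_edges(self, drop: Iterable[AssociationEdge]) -> "MANGraph":
        """Copy of the graph with the given edges removed (by undirected key)."""
        gone = {e.key for e in drop}
        return MANGraph(e for e in self._edges.values() if e.key not in gone)

    def kind_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {k: 0 for k in NODE_KINDS}
        for n in self._adj:
            counts[n.kind] += 1
        return counts

    def edge_kind_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {k: 0 for k in EDGE_KINDS}
        for e in self._edges.values():
            counts[e.edge_kind] += 1
        return counts


# -- operations ----------------------------------------------------------

def load_edge_list(path: str | Path, edge_kind: str) -> list[AssociationEdge]:
    """Read one association file: TSV ``source_id<TAB>target_id``.

    Node kinds are inferred from *edge_kind* (source kind first).  ``#``
    comment lines and blank lines are ignored.  Duplicate rows collapse to
    a single edge; self-loop rows are skipped with a warning; a row with
    fewer than two columns raises naming the line number.
    """
    if edge_kind not in EDGE_KINDS:
        raise GraphError(f"unknown edge kind: {edge_kind!r}")
    ku, kv = EDGE_KINDS[edge_kind]
    seen: dict[tuple, AssociationEdge] = {}
    n_dup = 0
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise GraphError(f"{path}:{lineno}: malformed row {line!r}")
            u = NodeRef(normalize_id(parts[0], ku), ku)
            v = NodeRef(normalize_id(parts[1], kv), kv)
            if u == v:
                logger.warning("%s:%d: self-loop %r skipped", path, lineno, u.id)
                continue
            e = AssociationEdge(u, v, edge_kind)
            if e.key in seen:
                n_dup += 1
            else:
                seen[e.key] = e
    if n_dup:
        logger.info("%s: collapsed %d duplicate rows", path, n_dup)
    return list(seen.values())


def build_graph(
    edge_lists: Sequence[tuple[Sequence[AssociationEdge], str]],
) -> MANGraph:
    """Union the per-kind edge lists into one MANGraph.

    Requires at least one drug-disease edge.  Logs per-kind node and edge
    counts so a run records the shape of its network.
    """
    g = MANGraph()
    for edges, kind in edge_lists:
        for e in edges:
            if e.edge_kind != kind:
                raise GraphError(
                    f"edge of kind {e.edge_kind!r} in list declared {kind!r}"
                )
            g.add_edge(e)
    if g.n_edges == 0:
        raise GraphError("empty graph: no edges in any input list")
    if g.edge_kind_counts()["drug-disease"] == 0:
        raise GraphError("graph has no drug-disease edges; nothing to predict")
    logger.info("MAN nodes by kind: %s", g.kind_counts())
    logger.info("MAN edges by kind: %s", g.edge_kind_counts())
    return g


def degree_distribution(g: MANGraph) -> dict[NodeRef, float]:
    """Weighted degree of every node; sums to 2 W (handshake)."""
    if len(g) == 0:
        raise GraphError("empty graph")
    return {n: g.degree(n) for n in g.nodes}


# -- serialization -------------------------------------------------------

def dump_graph(g: MANGraph, path: str | Path) -> None:
    """TSV dump: ``u_id u_kind v_id v_kind edge_kind weight``."""
    with Path(path).open("w") as fh:
        fh.write("#u_id\tu_kind\tv_id\tv_kind\tedge_kind\tweight\n")
        for e in sorted(g.edges, key=lambda e: e.key):
            fh.write(
                f"{e.u.id}\t{e.u.kind}\t{e.v.id}\t{e.v.kind}\t{e.edge_kind}\t{e.weight:g}\n"
            )


def load_graph(path: str | Path) -> MANGraph:
    g = MANGraph()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise GraphError(f"{path}:{lineno}: malformed graph row")
            uid, uk, vid, vk, ek, w = parts
            g.add_edge(
                AssociationEdge(
                    NodeRef(normalize_id(uid, uk), uk),
                    NodeRef(normalize_id(vid, vk), vk),
                    ek,
                    float(w),
                )
            )
    return g
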