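"""Labeled multigraph data model, JSON I/O, builtin graphs and truncation.

The combinatorial substrate of the whole package is a multigraph whose
edges carry unique string labels (loops and parallel edges allowed).
Vertices are 0-based integers; edge order is insertion order and is
preserved bit-identically through JSON round-trips so that every
downstream polynomial is reproducible.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import GraphFormatError, PreconditionError

Edge = tuple[int, int, str]


@dataclass(frozen=True)
class LabeledMultigraph:
    """A multigraph with uniquely labeled edges.

    ``vertices`` is an ordered tuple of integer ids and ``edges`` an
    ordered tuple of ``(u, v, label)`` triples.  A loop has ``u == v``
    and contributes 2 to the degree of its vertex.
    """

    vertices: tuple[int, ...]
    edges: tuple[Edge, ...]
    name: str | None = field(default=None, compare=False)

    def __post_init__(self):
        vset = set(self.vertices)
        if len(vset) != len(self.vertices):
            raise GraphFormatError("duplicate vertex id")
        labels = set()
        for u, v, lab in self.edges:
            for end in (u, v):
                if end not in vset:
                    raise GraphFormatError(
                        f"edge ({u}, {v}, {lab!r}) references undeclared vertex {end}"
                    )
            if lab in labels:
                raise GraphFormatError(f"duplicate edge label {lab!r}")
            labels.add(lab)

    # -- basic queries ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, _, lab in self.edges)

    def degree(self, v: int) -> int:
        d = 0
        for u, w, _ in self.edges:
            if u == v:
                d += 1
            if w == v:
                d += 1
        return d

    def degrees(self) -> dict[int, int]:
        d = {v: 0 for v in self.vertices}
        for u, w, _ in self.edges:
            d[u] += 1
            d[w] += 1
        return d

    def is_cubic(self) -> bool:
        return all(d == 3 for d in self.degrees().values())

    def has_loops(self) -> bool:
        return any(u == v for u, v, _ in self.edges)

    def incident_labels(self, v: int) -> list[str]:
        """Labels of edges incident with v; a loop is listed twice."""
        out = []
        for u, w, lab in self.edges:
            if u == v:
                out.append(lab)
            if w == v:
                out.append(lab)
        return out

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.vertices)
        for u, v, lab in self.edges:
            g.add_edge(u, v, key=lab, label=lab)
        return g

    # -- serialization ------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "vertices": list(self.vertices),
            "edges": [[u, v, lab] for u, v, lab in self.edges],
        }

    def __str__(self) -> str:
        name = self.name or "graph"
        return f"{name}(n={self.n_vertices}, m={self.n_edges})"


@dataclass(frozen=True)
class GraphStats:
    n_vertices: int
    n_edges: int
    degree_sequence: tuple[int, ...]
    is_cubic: bool
    bridges: tuple[str, ...]
    blocks: tuple[tuple[str, ...], ...]


def load_graph(path: str | Path) -> LabeledMultigraph:
    """Read a graph from the JSON edge-list dialect.

    The dialect is ``{"vertices": [0, 1, ...], "edges": [[u, v, "label"], ...]}``.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GraphFormatError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(data, dict) or "vertices" not in data or "edges" not in data:
        raise GraphFormatError(f"{path}: expected object with 'vertices' and 'edges'")
    vertices = data["vertices"]
    if not all(isinstance(v, int) for v in vertices):
        raise GraphFormatError(f"{path}: vertex ids must be integers")
    edges = []
    for rec in data["edges"]:
        if (
            not isinstance(rec, list)
            or len(rec) != 3
            or not isinstance(rec[0], int)
            or not isinstance(rec[1], int)
            or not isinstance(rec[2], str)
        ):
            raise GraphFormatError(f"{path}: bad edge record {rec!r}")
        edges.append((rec[0], rec[1], rec[2]))
    return LabeledMultigraph(tuple(vertices), tuple(edges), name=path.stem)


def save_graph(graph: LabeledMultigraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph.to_json_dict()) + "\n")


# ---------------------------------------------------------------------
# Builtin graph library
# ---------------------------------------------------------------------

def _theta_m(m: int) -> LabeledMultigraph:
    if m < 2:
        raise GraphFormatError("generalized theta needs at least 2 parallel edges")
    return LabeledMultigraph(
        (0, 1), tuple((0, 1, f"a{k}") for k in range(1, m + 1)), name=f"theta_{m}"
    )


def _tetrahedron() -> LabeledMultigraph:
    # K4 with the labeling that puts the triangles on {a4,a5,a6},
    # {a2,a3,a4}, {a1,a3,a5}, {a1,a2,a6} and the perfect matchings on
    # {a1,a4}, {a2,a5}, {a3,a6}.
    edges = (
        (0, 2, "a1"),
        (0, 3, "a2"),
        (0, 1, "a3"),
        (1, 3, "a4"),
        (1, 2, "a5"),
        (2, 3, "a6"),
    )
    return LabeledMultigraph((0, 1, 2, 3), edges, name="tetrahedron")


def _cube() -> LabeledMultigraph:
    # Vertices 0-3 top face, 4-7 bottom face, verticals a9..a12.
    edges = (
        (0, 1, "a1"),
        (1, 2, "a2"),
        (2, 3, "a3"),
        (3, 0, "a4"),
        (4, 5, "a5"),
        (5, 6, "a6"),
        (6, 7, "a7"),
        (7, 4, "a8"),
        (0, 4, "a9"),
        (1, 5, "a10"),
        (2, 6, "a11"),
        (3, 7, "a12"),
    )
    return LabeledMultigraph(tuple(range(8)), edges, name="cube")


def _prism3() -> LabeledMultigraph:
    edges = (
        (0, 1, "a1"),
        (1, 2, "a2"),
        (2, 0, "a3"),
        (3, 4, "a4"),
        (4, 5, "a5"),
        (5, 3, "a6"),
        (0, 3, "a7"),
        (1, 4, "a8"),
        (2, 5, "a9"),
    )
    return LabeledMultigraph(tuple(range(6)), edges, name="prism3")


_BUILTIN_NAMES = ("theta", "theta_m(m)", "tetrahedron", "cube", "prism3")


def builtin_graph(name: str) -> LabeledMultigraph:
    """Return a named builtin graph.

    Accepted names: ``theta``, ``theta_m(M)`` (generalized theta with M
    parallel edges), ``tetrahedron``, ``cube``, ``prism3``.
    """
    name = name.strip()
    if name == "theta":
        g = _theta_m(3)
        return LabeledMultigraph(g.vertices, g.edges, name="theta")
    if name.startswith("theta_m(") and name.endswith(")"):
        try:
            m = int(name[len("theta_m(") : -1])
        except ValueError:
            raise GraphFormatError(f"bad generalized-theta spec {name!r}") from None
        return _theta_m(m)
    if name == "tetrahedron":
        return _tetrahedron()
    if name == "cube":
        return _cube()
    if name == "prism3":
        return _prism3()
    raise GraphFormatError(
        f"unknown builtin graph {name!r}; valid names: {', '.join(_BUILTIN_NAMES)}"
    )


# ---------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------

def graph_stats(graph: LabeledMultigraph) -> GraphStats:
    """Degree sequence, bridges and 2-connected blocks of the graph."""
    g = graph.to_networkx()
    loops = {lab for u, v, lab in graph.edges if u == v}
    bridges = tuple(
        lab
        for u, v, lab in graph.edges
        if lab not in loops and _is_bridge(g, u, v, lab)
    )
    # Two biconnected components share at most one vertex, so each
    # non-loop edge lies in exactly one component's vertex set.
    comps = [set(c) for c in nx.biconnected_components(g)]
    blocks_map: dict[int, list[str]] = {}
    for u, v, lab in graph.edges:
        if lab in loops:
            continue
        idx = next(i for i, c in enumerate(comps) if u in c and v in c)
        blocks_map.setdefault(idx, []).append(lab)
    blocks = [tuple(sorted(labs)) for labs in blocks_map.values()]
    for lab in sorted(loops):
        blocks.append((lab,))
    degs = graph.degrees()
    return GraphStats(
        n_vertices=graph.n_vertices,
        n_edges=graph.n_edges,
        degree_sequence=tuple(sorted(degs.values())),
        is_cubic=graph.is_cubic(),
        bridges=bridges,
        blocks=tuple(sorted(blocks)),
    )


def _is_bridge(g: nx.MultiGraph, u: int, v: int, key: str) -> bool:
    # An edge is a bridge iff removing it disconnects u from v.
    g.remove_edge(u, v, key=key)
    try:
        connected = nx.has_path(g, u, v)
    finally:
        g.add_edge(u, v, key=key, label=key)
    return not connected


def structural_truncate(graph: LabeledMultigraph) -> LabeledMultigraph:
    """Truncate a cubic graph: subdivide every edge twice, then replace
    every original degree-3 vertex star by a triangle (Y-Δ).

    The image of original edge ``a_k`` keeps its identity as ``a_k'``;
    the three triangle edges created at vertex ``v_j`` are labeled
    ``b<j>_1..b<j>_3``.  The result has 2m vertices and 3m edges.
    """
    if not graph.is_cubic():
        for v, d in graph.degrees().items():
            if d != 3:
                raise PreconditionError(
                    f"truncation needs a cubic graph; vertex {v} has degree {d}"
                )
    # Half-edges: each edge has two sides; each side becomes a new vertex.
    new_id: dict[tuple[str, int], int] = {}
    counter = 0
    for _, _, lab in graph.edges:
        for side in (0, 1):
            new_id[(lab, side)] = counter
            counter += 1
    new_vertices = tuple(range(counter))
    new_edges: list[Edge] = []
    for u, v, lab in graph.edges:
        new_edges.append((new_id[(lab, 0)], new_id[(lab, 1)], f"{lab}'"))
    # Triangle at each original vertex over its three half-edge vertices.
    for j in graph.vertices:
        corners = []
        for u, v, lab in graph.edges:
            if u == j:
                corners.append(new_id[(lab, 0)])
            if v == j:
                corners.append(new_id[(lab, 1)])
        assert len(corners) == 3
        c1, c2, c3 = corners
        new_edges.append((c1, c2, f"b{j}_1"))
        new_edges.append((c2, c3, f"b{j}_2"))
        new_edges.append((c3, c1, f"b{j}_3"))
    name = f"{graph.name}_truncated" if graph.name else "truncated"
    return LabeledMultigraph(new_vertices, tuple(new_edges), name=name)


def truncation_label_collapse(truncated: LabeledMultigraph) -> dict[str, str]:
    """Map the per-edge labels of a structural truncation onto the two
    generic labels: original-edge images -> ``a``, triangle edges -> ``b``."""
    mapping = {}
    for _, _, lab in truncated.edges:
        mapping[lab] = "a" if lab.endswith("'") else "b"
    return mapping


def random_cubic_multigraph(n_vertices: int, seed: int) -> LabeledMultigraph:
    """Random cubic multigraph from a seeded pairing of 3n half-edges.

    Loops and parallel edges are allowed (the pairing model produces
    them); identical seeds produce identical graphs.
    """
    if n_vertices < 2 or n_vertices % 2:
        raise PreconditionError(
            f"pairing model needs an even vertex count >= 2, got {n_vertices}"
        )
    rng = random.Random(seed)
    stubs = [v for v in range(n_vertices) for _ in range(3)]
    rng.shuffle(stubs)
    edges = []
    for k in range(0, len(stubs), 2):
        u, v = stubs[k], stubs[k + 1]
        edges.append((min(u, v), max(u, v), f"a{k // 2 + 1}"))
    return LabeledMultigraph(
        tuple(range(n_vertices)), tuple(edges), name=f"random_cubic_{n_vertices}_{seed}"
    )
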