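"""Labeled adjacencies, the adjacency graph AG(A,B) and the DCJ distance.

Only the markers common to both genomes carry graph structure.  Each
adjacency of a genome is the pair of common-marker extremities (or
telomeres) flanking a possibly empty *label* of markers unique to that
genome.  The bipartite graph with one edge per common-marker extremity
decomposes into cycles, AA-/BB-/AB-paths and singletons; the DCJ
distance is ``n - (c + b/2)`` with ``n`` common markers, ``c`` cycles
and ``b`` AB-paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .genome_model import Genome, MarkerPartition, SignedMarker

HEAD = "h"
TAIL = "t"


@dataclass(frozen=True, order=True)
class Extremity:
    """A telomere (marker is None) or one end of a common marker."""

    marker: Optional[str]
    end: Optional[str] = None  # HEAD or TAIL when marker-end

    @property
    def is_telomere(self) -> bool:
        return self.marker is None

    def __str__(self) -> str:
        return "o" if self.is_telomere else f"{self.marker}^{self.end}"


TELOMERE = Extremity(None, None)


@dataclass(frozen=True)
class LabeledAdjacency:
    """A pair of extremities plus the label of unique markers between them.

    ``circular_singleton`` marks a whole circular chromosome of unique
    markers; it has no extremities.  A ``o l o`` adjacency (both
    extremities telomeric, non-empty label) is a linear chromosome of
    unique markers (linear singleton).
    """

    side: str  # "A" or "B"
    gamma1: Optional[Extremity]
    gamma2: Optional[Extremity]
    label: tuple[SignedMarker, ...] = ()
    circular_singleton: bool = False

    def __post_init__(self) -> None:
        if self.circular_singleton:
            assert self.gamma1 is None and self.gamma2 is None and self.label
        else:
            assert self.gamma1 is not None and self.gamma2 is not None

    @property
    def is_linear_singleton(self) -> bool:
        return (
            not self.circular_singleton
            and self.gamma1.is_telomere
            and self.gamma2.is_telomere
            and bool(self.label)
        )

    @property
    def labeled(self) -> bool:
        return bool(self.label)

    def marker_extremities(self) -> list[Extremity]:
        if self.circular_singleton:
            return []
        return [g for g in (self.gamma1, self.gamma2) if not g.is_telomere]

    def __str__(self) -> str:
        lab = "".join(str(m) for m in self.label)
        if self.circular_singleton:
            return f"{self.side}[|{lab}|]"
        return f"{self.side}[{self.gamma1} {lab} {self.gamma2}]"


def build_adjacencies(
    g: Genome, p: MarkerPartition, side: str
) -> list[LabeledAdjacency]:
    """Decompose a genome into its adjacencies w.r.t. the common markers.

    Every common-marker extremity ends up in exactly one adjacency and
    every unique marker in exactly one label.  Chromosomes with no
    common marker become singletons.
    """
    common = p.common
    out: list[LabeledAdjacency] = []
    for chrom in g.chromosomes:
        positions = [i for i, m in enumerate(chrom.markers) if m.id in common]
        if not positions:
            if chrom.circular:
                out.append(
                    LabeledAdjacency(side, None, None, tuple(chrom.markers), True)
                )
            else:
                out.append(
                    LabeledAdjacency(side, TELOMERE, TELOMERE, tuple(chrom.markers))
                )
            continue
        if chrom.circular:
            # one adjacency per gap between consecutive common markers
            k = len(positions)
            for j in range(k):
                i1, i2 = positions[j], positions[(j + 1) % k]
                m1, m2 = chrom.markers[i1], chrom.markers[i2]
                g1 = Extremity(m1.id, HEAD if m1.forward else TAIL)
                g2 = Extremity(m2.id, TAIL if m2.forward else HEAD)
                if i2 > i1:
                    between = chrom.markers[i1 + 1 : i2]
                else:  # wrap-around gap (includes the single-common-marker case)
                    between = chrom.markers[i1 + 1 :] + chrom.markers[:i2]
                out.append(LabeledAdjacency(side, g1, g2, tuple(between)))
        else:
            # leading telomere .. first common marker
            first, last = positions[0], positions[-1]
            m = chrom.markers[first]
            out.append(
                LabeledAdjacency(
                    side,
                    TELOMERE,
                    Extremity(m.id, TAIL if m.forward else HEAD),
                    tuple(chrom.markers[:first]),
                )
            )
            for j in range(len(positions) - 1):
                i1, i2 = positions[j], positions[j + 1]
                m1, m2 = chrom.markers[i1], chrom.markers[i2]
                out.append(
                    LabeledAdjacency(
                        side,
                        Extremity(m1.id, HEAD if m1.forward else TAIL),
                        Extremity(m2.id, TAIL if m2.forward else HEAD),
                        tuple(chrom.markers[i1 + 1 : i2]),
                    )
                )
            m = chrom.markers[last]
            out.append(
                LabeledAdjacency(
                    side,
                    Extremity(m.id, HEAD if m.forward else TAIL),
                    TELOMERE,
                    tuple(chrom.markers[last + 1 :]),
                )
            )
    return out


class ComponentKind(str, Enum):
    CYCLE = "cycle"
    AA = "AA-path"
    BB = "BB-path"
    AB = "AB-path"
    LIN_SINGLETON_A = "linear-singleton-A"
    LIN_SINGLETON_B = "linear-singleton-B"
    CIRC_SINGLETON_A = "circular-singleton-A"
    CIRC_SINGLETON_B = "circular-singleton-B"


@dataclass
class Component:
    """A connected component of AG(A,B) with a canonical vertex order.

    Paths are listed from the A-side endpoint when one exists (AB-paths
    therefore read from A to B); cycles start at a deterministic least
    vertex.  Vertices alternate between the two genomes.
    """

    kind: ComponentKind
    vertices: list[LabeledAdjacency]

    @property
    def n_edges(self) -> int:
        if self.kind == ComponentKind.CYCLE:
            return len(self.vertices)
        if self.kind in (
            ComponentKind.AA,
            ComponentKind.BB,
            ComponentKind.AB,
        ):
            return len(self.vertices) - 1
        return 0

    @property
    def is_path(self) -> bool:
        """Paths in the wide sense: linear singletons are degenerate
        AA-/BB-paths."""
        return self.kind in (
            ComponentKind.AA,
            ComponentKind.BB,
            ComponentKind.AB,
            ComponentKind.LIN_SINGLETON_A,
            ComponentKind.LIN_SINGLETON_B,
        )

    @property
    def is_singleton(self) -> bool:
        return self.kind in (
            ComponentKind.LIN_SINGLETON_A,
            ComponentKind.LIN_SINGLETON_B,
            ComponentKind.CIRC_SINGLETON_A,
            ComponentKind.CIRC_SINGLETON_B,
        )

    @property
    def dcj_sorted(self) -> bool:
        """Singletons, 1-edge AB-paths and 2-edge cycles are DCJ-sorted."""
        if self.is_singleton:
            return True
        if self.kind == ComponentKind.AB:
            return self.n_edges == 1
        if self.kind == ComponentKind.CYCLE:
            return self.n_edges == 2
        return False


@dataclass
class AdjacencyGraph:
    vertices_a: list[LabeledAdjacency]
    vertices_b: list[LabeledAdjacency]
    partition: MarkerPartition
    # edge map: extremity -> (a-index, b-index)
    edges: dict[Extremity, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.edges:
            return
        loc: dict[tuple[str, Extremity], int] = {}
        for side, verts in (("A", self.vertices_a), ("B", self.vertices_b)):
            for i, v in enumerate(verts):
                for ext in v.marker_extremities():
                    key = (side, ext)
                    if key in loc:
                        raise ValueError(f"extremity {ext} occurs twice in {side}")
                    loc[key] = i
        for m in self.partition.common:
            for end in (HEAD, TAIL):
                ext = Extremity(m, end)
                self.edges[ext] = (loc[("A", ext)], loc[("B", ext)])


def build_graph(
    adj_a: list[LabeledAdjacency], adj_b: list[LabeledAdjacency], p: MarkerPartition
) -> AdjacencyGraph:
    """Assemble AG(A,B): one edge per common-marker extremity."""
    return AdjacencyGraph(adj_a, adj_b, p)


def _vertex_key(side: str, v: LabeledAdjacency) -> tuple:
    exts = sorted(str(e) for e in (v.gamma1, v.gamma2) if e is not None)
    return (side, exts, tuple(str(m) for m in v.label))


def components(graph: AdjacencyGraph) -> list[Component]:
    """Decompose AG(A,B) into cycles, paths and singletons.

    Deterministic: vertices within a component are ordered canonically
    (see :class:`Component`), components are listed A-side vertices
    first in input order.
    """
    # neighbor structure: vertex id = (side, index)
    nbrs: dict[tuple[str, int], list[tuple[tuple[str, int], Extremity]]] = {}
    verts = {"A": graph.vertices_a, "B": graph.vertices_b}
    for ext, (ia, ib) in graph.edges.items():
        nbrs.setdefault(("A", ia), []).append((("B", ib), ext))
        nbrs.setdefault(("B", ib), []).append((("A", ia), ext))

    seen: set[tuple[str, int]] = set()
    out: list[Component] = []

    def vertex(vid: tuple[str, int]) -> LabeledAdjacency:
        return verts[vid[0]][vid[1]]

    def walk(start: tuple[str, int]) -> list[tuple[str, int]]:
        """Walk a path from an endpoint, or a cycle from any vertex."""
        order = [start]
        seen.add(start)
        prev_ext: Optional[Extremity] = None
        cur = start
        while True:
            unvisited = [
                (w, e)
                for (w, e) in nbrs.get(cur, [])
                if e != prev_ext and w not in seen
            ]
            if not unvisited:
                break
            cur, prev_ext = unvisited[0]
            order.append(cur)
            seen.add(cur)
        return order

    all_ids = [("A", i) for i in range(len(graph.vertices_a))] + [
        ("B", i) for i in range(len(graph.vertices_b))
    ]

    # path endpoints: degree < 2 (vertices with a telomere), A side first
    endpoints = [
        vid
        for vid in all_ids
        if len(nbrs.get(vid, [])) == 1
    ]
    for vid in endpoints:
        if vid in seen:
            continue
        order = walk(vid)
        # prefer A-side start; if both ends same side, pick lexicographic least
        if order[0][0] != "A" and order[-1][0] == "A":
            order.reverse()
        elif order[0][0] == order[-1][0]:
            if _vertex_key(order[-1][0], vertex(order[-1])) < _vertex_key(
                order[0][0], vertex(order[0])
            ):
                order.reverse()
        first, last = order[0][0], order[-1][0]
        if first == "A" and last == "A":
            kind = ComponentKind.AA
        elif first == "B" and last == "B":
            kind = ComponentKind.BB
        else:
            kind = ComponentKind.AB
        out.append(Component(kind, [vertex(v) for v in order]))

    # remaining degree-2 vertices form cycles
    for vid in all_ids:
        if vid in seen or not nbrs.get(vid):
            continue
        order = walk(vid)
        # canonical rotation: start at least vertex key
        keys = [_vertex_key(w[0], vertex(w)) for w in order]
        i0 = keys.index(min(keys))
        order = order[i0:] + order[:i0]
        out.append(Component(ComponentKind.CYCLE, [vertex(v) for v in order]))

    # singletons: vertices with no marker extremity
    for side, vs in (("A", graph.vertices_a), ("B", graph.vertices_b)):
        for v in vs:
            if v.circular_singleton:
                kind = (
                    ComponentKind.CIRC_SINGLETON_A
                    if side == "A"
                    else ComponentKind.CIRC_SINGLETON_B
                )
                out.append(Component(kind, [v]))
            elif v.is_linear_singleton:
                kind = (
                    ComponentKind.LIN_SINGLETON_A
                    if side == "A"
                    else ComponentKind.LIN_SINGLETON_B
                )
                out.append(Component(kind, [v]))
    return out


def dcj_distance_from_components(comps: list[Component], p: MarkerPartition) -> int:
    c = sum(1 for comp in comps if comp.kind == ComponentKind.CYCLE)
    b = sum(1 for comp in comps if comp.kind == ComponentKind.AB)
    assert b % 2 == 0, "AB-path count must be even"
    return p.n - (c + b // 2)


def dcj_distance(graph: AdjacencyGraph, p: MarkerPartition) -> int:
    """The DCJ distance ``n - (c + b/2)`` over the common markers."""
    return dcj_distance_from_components(components(graph), p)
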