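"""Runs of unique markers, indel- and substitution-potentials, bounds.

Reading the labels of a component in canonical order yields maximal
*runs* of markers unique to one genome.  Their count Λ(C) determines

* the indel-potential  λ(C) = ⌈(Λ+1)/2⌉   (0 for a clean component):
  the fewest runs reachable by optimally DCJ-sorting C, hence the
  number of indels C costs under a DCJ-indel model;
* the substitution-potential  σ(C) = ⌈λ(C)/2⌉ = ⌈(Λ+1)/4⌉  (0 for a
  clean component): pairs of consecutive runs can be accumulated into
  two adjacent adjacencies and wiped by a single substitution.

Disjoint pairs of same-topology singletons (one per genome) are each
sorted by one whole-chromosome substitution, saving one step per pair.
Adding everything up gives the upper bound

    d_DCJ + Σσ(C) − P_L − P_C

which is the exact DCJ-substitution distance for co-tailed genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional

from .adjacency_graph import (
    AdjacencyGraph,
    Component,
    ComponentKind,
    Extremity,
    build_adjacencies,
    build_graph,
    components,
    dcj_distance_from_components,
)
from .genome_model import Genome, MarkerPartition, partition_markers


@dataclass(frozen=True)
class RunSequence:
    """Alternating run tags of one component, in canonical reading order."""

    runs: tuple[str, ...]  # each tag "A" or "B"

    def __post_init__(self) -> None:
        for x, y in zip(self.runs, self.runs[1:]):
            assert x != y, "runs must alternate"

    @property
    def lambda_count(self) -> int:
        """Λ(C): the number of runs."""
        return len(self.runs)


def component_runs(c: Component) -> RunSequence:
    """Count maximal runs of unique markers along a component.

    Labels are concatenated in vertex order; a maximal stretch of one
    genome's markers is a single run, so consecutive labeled vertices of
    the same genome (with only clean vertices between) merge.  For a
    cycle the reading is cyclic, which realizes the canonical start
    vertex prescribed for cycles labeled in both genomes; a cycle
    labeled in a single genome yields one run wherever reading starts.
    """
    tags = [v.side for v in c.vertices if v.labeled]
    if not tags:
        return RunSequence(())
    merged: list[str] = []
    for t in tags:
        if not merged or merged[-1] != t:
            merged.append(t)
    if c.kind == ComponentKind.CYCLE and len(merged) > 1 and merged[0] == merged[-1]:
        merged.pop()  # wrap-around: first and last stretch are one run
    return RunSequence(tuple(merged))


def indel_potential(r: RunSequence) -> int:
    """λ(C) = ⌈(Λ+1)/2⌉ for Λ ≥ 1, else 0."""
    lam = r.lambda_count
    return ceil((lam + 1) / 2) if lam >= 1 else 0


def substitution_potential(r: RunSequence) -> int:
    """σ(C) = ⌈λ(C)/2⌉ for Λ ≥ 1, else 0 (never exceeds λ)."""
    lam = r.lambda_count
    return ceil(indel_potential(r) / 2) if lam >= 1 else 0


def singleton_pairs(comps: list[Component]) -> tuple[int, int]:
    """Maximum disjoint singleton pairs (P_L, P_C), never mixing a linear
    with a circular chromosome."""
    def count(kind: ComponentKind) -> int:
        return sum(1 for c in comps if c.kind == kind)

    p_l = min(count(ComponentKind.LIN_SINGLETON_A), count(ComponentKind.LIN_SINGLETON_B))
    p_c = min(
        count(ComponentKind.CIRC_SINGLETON_A), count(ComponentKind.CIRC_SINGLETON_B)
    )
    return p_l, p_c


@dataclass
class PotentialSummary:
    """Per-component run/potential table plus the totals entering the bound."""

    per_component: list[tuple[Component, RunSequence, int, int]] = field(
        default_factory=list
    )
    total_runs: int = 0
    total_lambda: int = 0
    total_sigma: int = 0
    p_l: int = 0
    p_c: int = 0

    @classmethod
    def from_components(cls, comps: list[Component]) -> "PotentialSummary":
        rows = []
        for c in comps:
            r = component_runs(c)
            rows.append((c, r, indel_potential(r), substitution_potential(r)))
        p_l, p_c = singleton_pairs(comps)
        return cls(
            per_component=rows,
            total_runs=sum(r.lambda_count for _, r, _, _ in rows),
            total_lambda=sum(lam for _, _, lam, _ in rows),
            total_sigma=sum(sig for _, _, _, sig in rows),
            p_l=p_l,
            p_c=p_c,
        )


def upper_bound_distance(
    graph: AdjacencyGraph, p: MarkerPartition, summary: PotentialSummary
) -> int:
    """The bound d_DCJ + Σσ(C) − P_L − P_C (exact for co-tailed genomes)."""
    comps = [c for c, _, _, _ in summary.per_component]
    d_dcj = dcj_distance_from_components(comps, p)
    return d_dcj + summary.total_sigma - summary.p_l - summary.p_c


def _tails(adjs) -> frozenset[Extremity]:
    tails = set()
    for v in adjs:
        if v.circular_singleton:
            continue
        g1, g2 = v.gamma1, v.gamma2
        if g1.is_telomere != g2.is_telomere:
            tails.add(g2 if g1.is_telomere else g1)
    return frozenset(tails)


def cotailed(a: Genome, b: Genome) -> bool:
    """True when the common-marker tail sets of both genomes coincide
    (in particular for two fully circular genomes)."""
    p = partition_markers(a, b)
    adj_a = build_adjacencies(a, p, "A")
    adj_b = build_adjacencies(b, p, "B")
    return _tails(adj_a) == _tails(adj_b)


def cotailed_distance(a: Genome, b: Genome) -> Optional[int]:
    """Exact DCJ-substitution distance for co-tailed genomes, else None.

    For co-tailed genomes no distance-reducing recombination between
    components exists and the upper bound is tight.
    """
    if not cotailed(a, b):
        return None
    p = partition_markers(a, b)
    graph = build_graph(
        build_adjacencies(a, p, "A"), build_adjacencies(b, p, "B"), p
    )
    summary = PotentialSummary.from_components(components(graph))
    return upper_bound_distance(graph, p, summary)
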