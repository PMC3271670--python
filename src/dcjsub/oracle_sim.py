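"""Operation engine, brute-force distance oracle and pair generator.

The engine applies double-cut-and-join (DCJ) operations and block
substitutions to whole genomes.  DCJs are handled in the standard
adjacency formalism: a genome is a matching on marker extremities
(telomeric adjacencies are singleton sets), and a DCJ replaces one or
two adjacencies by a different re-pairing of the same extremities.
Because unique markers are ordinary markers here, every cut position
inside an adjacency label is available.

The oracle searches breadth-first over a restricted move set — all
DCJs, plus substitutions whose removed block is a maximal contiguous
block of markers absent from the target and whose inserted block occurs
contiguously in the target.  Every move sequence it finds is a valid
sorting scenario, so its result is an upper bound on the true distance;
agreement with the closed formula certifies both.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Iterator, Optional

from .genome_model import Chromosome, Genome, GenomeError, SignedMarker

Ext = tuple[str, str]  # (marker id, "h" | "t")
Adjacency = frozenset  # frozenset[Ext], size 1 (telomeric) or 2


# ---------------------------------------------------------------------------
# genome <-> extremity matching

def genome_to_matching(g: Genome) -> frozenset:
    """The set of adjacencies (as frozensets of extremities) of a genome."""
    adjs: set[Adjacency] = set()

    def tail(m: SignedMarker) -> Ext:
        return (m.id, "t" if m.forward else "h")

    def head(m: SignedMarker) -> Ext:
        return (m.id, "h" if m.forward else "t")

    for chrom in g.chromosomes:
        ms = chrom.markers
        for m1, m2 in zip(ms, ms[1:]):
            adjs.add(frozenset({head(m1), tail(m2)}))
        if chrom.circular:
            adj = frozenset({head(ms[-1]), tail(ms[0])})
            if len(ms) == 1:
                # single-marker circle: adjacency joins the marker's own ends
                adj = frozenset({(ms[0].id, "h"), (ms[0].id, "t")})
            adjs.add(adj)
        else:
            adjs.add(frozenset({tail(ms[0])}))
            adjs.add(frozenset({head(ms[-1])}))
    return frozenset(adjs)


def matching_to_genome(adjs: frozenset, marker_ids: set[str], name: str) -> Genome:
    """Rebuild chromosomes from an extremity matching."""
    partner: dict[Ext, Optional[Ext]] = {}
    for adj in adjs:
        items = list(adj)
        if len(items) == 1:
            partner[items[0]] = None
        else:
            partner[items[0]] = items[1]
            partner[items[1]] = items[0]

    def other_end(x: Ext) -> Ext:
        return (x[0], "h" if x[1] == "t" else "t")

    used: set[str] = set()
    chromosomes: list[Chromosome] = []

    # linear chromosomes: start from telomeric extremities
    telomeric = sorted(x for x, pr in partner.items() if pr is None)
    for start in telomeric:
        if start[0] in used:
            continue
        markers: list[SignedMarker] = []
        x = start
        while True:
            markers.append(SignedMarker(x[0], x[1] == "t"))
            used.add(x[0])
            nxt = partner.get(other_end(x))
            if nxt is None:
                break
            x = nxt
        chromosomes.append(Chromosome(tuple(markers), circular=False))

    # remaining markers lie on circular chromosomes
    for mid in sorted(marker_ids):
        if mid in used:
            continue
        markers = []
        x: Ext = (mid, "t")
        while True:
            markers.append(SignedMarker(x[0], x[1] == "t"))
            used.add(x[0])
            x = partner[other_end(x)]
            if x[0] == mid:
                break
        chromosomes.append(Chromosome(tuple(markers), circular=True))
    return Genome(name, chromosomes)


# ---------------------------------------------------------------------------
# DCJ operations

@dataclass(frozen=True)
class DcjOperation:
    """Replace ``removed`` adjacencies by ``added`` ones (same extremities)."""

    removed: frozenset  # frozenset[Adjacency]
    added: frozenset

    def inverse(self) -> "DcjOperation":
        return DcjOperation(self.added, self.removed)


def apply_dcj(g: Genome, op: DcjOperation) -> Genome:
    """Apply a DCJ; the inverse operation restores the input."""
    adjs = genome_to_matching(g)
    if not op.removed <= adjs:
        raise ValueError("DCJ cut positions not present in genome")
    new = (adjs - op.removed) | op.added
    exts_removed = {x for a in op.removed for x in a}
    exts_added = {x for a in op.added for x in a}
    if exts_removed != exts_added:
        raise ValueError("DCJ must re-pair exactly the cut extremities")
    return matching_to_genome(new, g.marker_ids(), g.name)


def _pairings(u: tuple, v: tuple) -> list[frozenset]:
    """Alternative re-pairings of the (padded) extremity pairs u and v."""
    (p, q), (r, s) = u, v
    outs = []
    for a1, a2 in (((p, r), (q, s)), ((p, s), (q, r))):
        new = set()
        for pair in (a1, a2):
            elems = frozenset(x for x in pair if x is not None)
            if elems:
                new.add(elems)
        outs.append(frozenset(new))
    return outs


def dcj_operations(g: Genome) -> list[DcjOperation]:
    """All single DCJ operations applicable to a genome."""
    adjs = sorted(genome_to_matching(g), key=lambda a: sorted(a))
    ops: list[DcjOperation] = []
    seen: set[tuple[frozenset, frozenset]] = set()

    def pad(a: Adjacency) -> tuple:
        items = sorted(a)
        return (items[0], items[1]) if len(items) == 2 else (items[0], None)

    for i in range(len(adjs)):
        for j in range(i + 1, len(adjs)):
            u, v = adjs[i], adjs[j]
            removed = frozenset({u, v})
            for added in _pairings(pad(u), pad(v)):
                if added == removed:
                    continue
                key = (removed, added)
                if key not in seen:
                    seen.add(key)
                    ops.append(DcjOperation(removed, added))
        # fission: split one 2-adjacency into two telomeres
        u = adjs[i]
        if len(u) == 2:
            x, y = sorted(u)
            removed = frozenset({u})
            added = frozenset({frozenset({x}), frozenset({y})})
            ops.append(DcjOperation(removed, added))
    return ops


# ---------------------------------------------------------------------------
# substitutions

@dataclass(frozen=True)
class SubstitutionOperation:
    """Replace a contiguous block of markers in one chromosome.

    ``chrom`` indexes ``genome.chromosomes``; ``chrom is None`` inserts a
    brand-new chromosome (``removed`` must then be empty and
    ``new_circular`` gives its topology).  A whole-chromosome
    replacement keeps the chromosome's topology: substituting a linear
    by a circular chromosome (or vice versa) is not allowed.
    """

    chrom: Optional[int]
    start: int
    removed: tuple[SignedMarker, ...]
    inserted: tuple[SignedMarker, ...]
    new_circular: bool = False

    def inverse_on(self, g: Genome) -> "SubstitutionOperation":
        """The substitution undoing self after it was applied to g."""
        if self.chrom is None:
            # inserted a new chromosome (appended last): delete it again
            return SubstitutionOperation(
                len(g.chromosomes), 0, self.inserted, (), self.new_circular
            )
        return replace(self, removed=self.inserted, inserted=self.removed)


def apply_substitution(g: Genome, op: SubstitutionOperation) -> Genome:
    """Apply a substitution (indels are the empty-block special cases)."""
    if not op.removed and not op.inserted:
        raise ValueError("empty substitution")
    chroms = list(g.chromosomes)
    if op.chrom is None:
        if op.removed:
            raise ValueError("new-chromosome insertion cannot remove markers")
        chroms.append(Chromosome(op.inserted, op.new_circular))
        return Genome(g.name, chroms)
    chrom = chroms[op.chrom]
    seg = chrom.markers[op.start : op.start + len(op.removed)]
    if seg != op.removed:
        raise ValueError("removed block not present at the stated position")
    markers = chrom.markers[: op.start] + op.inserted + chrom.markers[
        op.start + len(op.removed) :
    ]
    if not markers:
        del chroms[op.chrom]  # whole-chromosome deletion
    else:
        chroms[op.chrom] = Chromosome(markers, chrom.circular)
    return Genome(g.name, chroms)


def _absent_blocks(chrom: Chromosome, present: set[str]) -> list[tuple[int, int]]:
    """Maximal runs (start, length) of markers whose ids are not in
    ``present``.  For circular chromosomes a run wrapping the origin is
    reported from its true start."""
    m = len(chrom.markers)
    flags = [mk.id not in present for mk in chrom.markers]
    if all(flags):
        return [(0, m)]
    blocks = []
    if not chrom.circular:
        i = 0
        while i < m:
            if flags[i]:
                j = i
                while j < m and flags[j]:
                    j += 1
                blocks.append((i, j - i))
                i = j
            else:
                i += 1
    else:
        # rotate so position 0 is a present marker, then scan
        shift = flags.index(False)
        i = 0
        while i < m:
            k = (shift + i) % m
            if flags[k]:
                j = i
                while j < m and flags[(shift + j) % m]:
                    j += 1
                blocks.append(((shift + i) % m, j - i))
                i = j
            else:
                i += 1
    return blocks


def _target_blocks(target: Genome, present: set[str]) -> list[tuple[SignedMarker, ...]]:
    """Maximal contiguous blocks of target markers missing from ``present``."""
    out = []
    for chrom in target.chromosomes:
        for start, length in _absent_blocks(chrom, present):
            if start + length <= len(chrom.markers):
                block = chrom.markers[start : start + length]
            else:  # wrap-around on a circular chromosome
                block = (
                    chrom.markers[start:] + chrom.markers[: (start + length) % len(chrom.markers)]
                )
            out.append(tuple(block))
    return out


def _reverse_block(block: tuple[SignedMarker, ...]) -> tuple[SignedMarker, ...]:
    return tuple(m.reverse() for m in reversed(block))


def substitution_operations(g: Genome, target: Genome) -> list[SubstitutionOperation]:
    """Restricted substitution moves for sorting ``g`` toward ``target``.

    Removed blocks are maximal contiguous blocks of markers absent from
    the target; inserted blocks occur contiguously in the target and are
    not yet present in ``g`` (either reading direction).
    """
    g_ids = g.marker_ids()
    target_ids = target.marker_ids()
    candidates = _target_blocks(target, g_ids)
    ins_options: list[tuple[SignedMarker, ...]] = []
    seen_blocks = set()
    for block in candidates:
        for b in (block, _reverse_block(block)):
            key = tuple((m.id, m.forward) for m in b)
            if key not in seen_blocks:
                seen_blocks.add(key)
                ins_options.append(b)

    target_chrom_canon = {
        c.canonical(): c.circular for c in target.chromosomes
    }

    ops: list[SubstitutionOperation] = []
    for ci, chrom in enumerate(g.chromosomes):
        m = len(chrom.markers)
        for start, length in _absent_blocks(chrom, target_ids):
            if start + length <= m:
                removed = chrom.markers[start : start + length]
            else:
                continue  # wrapped block on circular: rotation-equivalent op exists
            whole = length == m
            # deletion
            ops.append(SubstitutionOperation(ci, start, tuple(removed), ()))
            # substitution by an insert candidate
            for ins in ins_options:
                if whole:
                    # whole-chromosome substitution: topology must match,
                    # and only by a whole chromosome of the target
                    canon = Chromosome(ins, chrom.circular).canonical()
                    if target_chrom_canon.get(canon) == chrom.circular:
                        ops.append(
                            SubstitutionOperation(ci, start, tuple(removed), ins)
                        )
                else:
                    ops.append(SubstitutionOperation(ci, start, tuple(removed), ins))
        # pure insertions into this chromosome
        positions = range(m + 1) if not chrom.circular else range(m)
        for ins in ins_options:
            for pos in positions:
                ops.append(SubstitutionOperation(ci, pos, (), ins))
    # insertion of a whole target chromosome as a new chromosome
    for chrom in target.chromosomes:
        if all(mk.id not in g_ids for mk in chrom.markers):
            ops.append(
                SubstitutionOperation(None, 0, (), tuple(chrom.markers), chrom.circular)
            )
    return ops


# ---------------------------------------------------------------------------
# brute-force distance oracle

class OracleCapError(ValueError):
    """Instance exceeds the size cap of the brute-force oracle."""


def oracle_distance(
    a: Genome,
    b: Genome,
    max_depth: int = 8,
    marker_cap: int = 7,
    dcj_only: bool = False,
) -> Optional[int]:
    """Length of the shortest restricted move sequence between A and B.

    Breadth-first search over DCJs plus target-directed substitutions,
    run in both directions (the operations are closed under inversion,
    so the distance is symmetric; a scenario that accumulates markers
    with DCJs before deleting them is only visible to the search in one
    of the two directions).  Returns None when no scenario of length
    <= max_depth exists.
    """
    d1 = _directed_oracle(a, b, max_depth, marker_cap, dcj_only)
    if d1 == 0:
        return 0
    d2 = _directed_oracle(b, a, max_depth if d1 is None else d1 - 1, marker_cap, dcj_only)
    if d2 is not None:
        return d2
    return d1


def _directed_oracle(
    a: Genome,
    b: Genome,
    max_depth: int,
    marker_cap: int,
    dcj_only: bool,
) -> Optional[int]:
    n_markers = len(a.marker_ids() | b.marker_ids())
    if n_markers > marker_cap:
        raise OracleCapError(
            f"{n_markers} distinct markers exceed the oracle cap of {marker_cap}"
        )
    goal = b.canonical()
    start = a.canonical()
    if start == goal:
        return 0
    frontier: list[Genome] = [a]
    visited = {start}
    for depth in range(1, max_depth + 1):
        nxt: list[Genome] = []
        for g in frontier:
            neighbors: list[Genome] = []
            for op in dcj_operations(g):
                neighbors.append(apply_dcj(g, op))
            if not dcj_only:
                for sop in substitution_operations(g, b):
                    neighbors.append(apply_substitution(g, sop))
            for h in neighbors:
                key = h.canonical()
                if key == goal:
                    return depth
                if key not in visited:
                    visited.add(key)
                    nxt.append(h)
        frontier = nxt
        if not frontier:
            break
    return None


# ---------------------------------------------------------------------------
# delta metrics

@dataclass(frozen=True)
class DeltaMetrics:
    delta_lambda_runs: int  # change in total run count
    delta_sigma: int  # change in total substitution-potential
    delta_dcj: int  # 0 optimal, +1 neutral, +2 counter-optimal
    delta_d: int  # delta_dcj + delta_sigma


def _graph_stats(a: Genome, b: Genome):
    from .adjacency_graph import build_adjacencies, build_graph, components, ComponentKind
    from .genome_model import partition_markers
    from .potentials import PotentialSummary

    p = partition_markers(a, b)
    comps = components(
        build_graph(build_adjacencies(a, p, "A"), build_adjacencies(b, p, "B"), p)
    )
    summary = PotentialSummary.from_components(comps)
    c = sum(1 for x in comps if x.kind == ComponentKind.CYCLE)
    bb = sum(1 for x in comps if x.kind == ComponentKind.AB)
    return c, bb, summary


def measure_deltas(a: Genome, b: Genome, op, side: str = "A") -> DeltaMetrics:
    """Graph-level deltas of a DCJ (or substitution) applied to one genome."""
    c0, b0, s0 = _graph_stats(a, b)
    if side == "A":
        a2, b2 = _apply_any(a, op, b), b
    else:
        a2, b2 = a, _apply_any(b, op, a)
    c1, b1, s1 = _graph_stats(a2, b2)
    if isinstance(op, DcjOperation):
        if c1 == c0 + 1 or b1 == b0 + 2:
            delta_dcj = 0
        elif c1 == c0 and b1 == b0:
            delta_dcj = 1
        elif c1 == c0 - 1 or b1 == b0 - 2:
            delta_dcj = 2
        else:  # pragma: no cover - impossible for a single DCJ
            raise AssertionError("single DCJ changed c/b by more than one unit")
    else:
        delta_dcj = 0
    return DeltaMetrics(
        delta_lambda_runs=s1.total_runs - s0.total_runs,
        delta_sigma=s1.total_sigma - s0.total_sigma,
        delta_dcj=delta_dcj,
        delta_d=delta_dcj + (s1.total_sigma - s0.total_sigma),
    )


def _apply_any(g: Genome, op, target: Genome) -> Genome:
    if isinstance(op, DcjOperation):
        return apply_dcj(g, op)
    if isinstance(op, SubstitutionOperation):
        return apply_substitution(g, op)
    raise TypeError(f"unsupported operation {op!r}")


# ---------------------------------------------------------------------------
# synthetic genome-pair generator

def _random_ancestor(
    rng: random.Random, n_common: int, a_blocks: list[list[str]]
) -> Genome:
    """Ancestor over common markers plus contiguous A-unique blocks."""
    commons = [str(i + 1) for i in range(n_common)]
    rng.shuffle(commons)
    units: list[list[str]] = [[c] for c in commons] + [list(b) for b in a_blocks]
    rng.shuffle(units)
    if not units:
        raise GenomeError("cannot build an empty ancestor")
    # chromosome cuts only at unit boundaries so planted blocks stay intact
    boundaries = []
    pos = 0
    for unit in units[:-1]:
        pos += len(unit)
        boundaries.append(pos)
    tokens = [t for unit in units for t in unit]
    signed = [SignedMarker(t, rng.random() < 0.5) for t in tokens]
    n_chrom = rng.randint(1, max(1, min(3, len(boundaries) + 1)))
    cut_points = sorted(rng.sample(boundaries, n_chrom - 1)) if n_chrom > 1 else []
    bounds = [0] + cut_points + [len(signed)]
    chroms = []
    for lo, hi in zip(bounds, bounds[1:]):
        chroms.append(Chromosome(tuple(signed[lo:hi]), circular=rng.random() < 0.3))
    return Genome("A", chroms)


def random_genome_pair(
    n_common: int,
    n_unique_a: int,
    n_unique_b: int,
    n_dcj: int,
    n_subst: int,
    seed: int,
) -> tuple[Genome, Genome, int]:
    """Plant a known scenario: B is derived from an ancestor A by
    ``n_subst`` substitutions (consuming every A-unique and B-unique
    marker exactly once) followed by ``n_dcj`` random DCJs.

    Returns (A, B, planted_count); the planted count is an upper bound
    on the true DCJ-substitution distance.
    """
    if min(n_common, n_unique_a, n_unique_b, n_dcj, n_subst) < 0:
        raise ValueError("parameters must be non-negative")
    if n_subst == 0 and (n_unique_a or n_unique_b):
        raise ValueError("unique markers require at least one substitution")
    if n_subst > n_unique_a + n_unique_b:
        raise ValueError("insufficient unique markers for requested substitutions")
    if n_common == 0 and n_unique_a == 0:
        raise ValueError("ancestor would be empty")
    rng = random.Random(seed)

    a_ids = [f"a{i+1}" for i in range(n_unique_a)]
    b_ids = [f"b{i+1}" for i in range(n_unique_b)]

    def partition_blocks(ids: list[str], k: int) -> list[list[str]]:
        """Split ids into exactly k contiguous blocks (some possibly empty)."""
        if k == 0:
            return []
        cuts = sorted(rng.choices(range(len(ids) + 1), k=k - 1))
        bounds = [0] + cuts + [len(ids)]
        return [ids[lo:hi] for lo, hi in zip(bounds, bounds[1:])]

    rem_blocks = partition_blocks(a_ids, n_subst)
    ins_blocks = partition_blocks(b_ids, n_subst)
    rng.shuffle(rem_blocks)
    rng.shuffle(ins_blocks)
    # every substitution must do something
    for i in range(n_subst):
        if not rem_blocks[i] and not ins_blocks[i]:
            donors = [j for j in range(n_subst) if len(rem_blocks[j]) > 1] + [
                j for j in range(n_subst) if len(ins_blocks[j]) > 1
            ]
            if not donors:
                raise ValueError("insufficient unique markers for requested substitutions")
            j = donors[0]
            if len(rem_blocks[j]) > 1:
                rem_blocks[i].append(rem_blocks[j].pop())
            else:
                ins_blocks[i].append(ins_blocks[j].pop())

    ancestor = _random_ancestor(rng, n_common, [b for b in rem_blocks if b])
    genome_a = Genome("A", list(ancestor.chromosomes))

    # derive B: substitutions first (on known contiguous blocks), then DCJs
    b_genome = Genome("B", list(ancestor.chromosomes))
    # apply block-removing substitutions before pure insertions so an
    # insertion cannot split a planted block that is yet to be replaced
    ordered = sorted(zip(rem_blocks, ins_blocks), key=lambda p: not p[0])
    for rem, ins in ordered:
        ins_markers = tuple(SignedMarker(t, rng.random() < 0.5) for t in ins)
        if rem:
            ci, start = _locate_block(b_genome, rem)
            removed = b_genome.chromosomes[ci].markers[start : start + len(rem)]
            b_genome = apply_substitution(
                b_genome, SubstitutionOperation(ci, start, tuple(removed), ins_markers)
            )
        else:
            ci = rng.randrange(len(b_genome.chromosomes))
            chrom = b_genome.chromosomes[ci]
            pos = rng.randint(0, len(chrom.markers) - (1 if chrom.circular else 0))
            b_genome = apply_substitution(
                b_genome, SubstitutionOperation(ci, pos, (), ins_markers)
            )
    for _ in range(n_dcj):
        ops = dcj_operations(b_genome)
        if not ops:
            break
        b_genome = apply_dcj(b_genome, rng.choice(ops))
    return genome_a, b_genome, n_dcj + n_subst


def _locate_block(g: Genome, ids: list[str]) -> tuple[int, int]:
    """Find a planted contiguous block; on circular chromosomes it may
    wrap the origin, in which case the chromosome is rotated first."""
    for ci, chrom in enumerate(g.chromosomes):
        seq = [m.id for m in chrom.markers]
        for start in range(len(seq) - len(ids) + 1):
            if seq[start : start + len(ids)] == ids:
                return ci, start
    for ci, chrom in enumerate(g.chromosomes):
        if not chrom.circular or len(chrom.markers) < len(ids):
            continue
        seq = [m.id for m in chrom.markers]
        doubled = seq + seq
        for start in range(len(seq)):
            if doubled[start : start + len(ids)] == ids:
                rotated = chrom.markers[start:] + chrom.markers[:start]
                g.chromosomes[ci] = Chromosome(rotated, circular=True)
                return ci, 0
    raise AssertionError(f"planted block {ids} not found")
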