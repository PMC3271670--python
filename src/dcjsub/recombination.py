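"""Path classification, recombination groups and the exact distance.

A DCJ acting on two components (a *recombination*) can beat sorting the
components separately: specific combinations of labeled path types
reduce the total operation count below the per-component bound.  The
complete catalogue of distance-reducing recombinations (and of the
neutral ones that create new sources for them) is shipped as a
plain-text table; it was derived by exhaustive enumeration of run-word
recombinations and is re-validated on load (delta arithmetic, the
sigma-drop bound of -2, A/B mirror closure) and against the brute-force
oracle in the test suite.

Path taxonomy: a path is AA, BB or AB by its endpoints; its run
structure is ``eps`` (clean) or ``4i+k`` runs with ``k`` in 1..4 and the
first run's genome.  Reading direction is free for AA/BB paths (so even
``k`` has no chirality) and fixed A-to-B for AB-paths.  Substitution
potentials depend only on ``i`` and ``k`` (sigma = i+1 for k<=3, i+2
for k=4), which is why recombination rules are i-independent.

The total *deduction* is the maximum sum of |delta_d| over sequences of
recombinations drawn from the table.  It is computed exactly by a
memoized search over the multiset of path types and reported as group
counts U..Z (chains classified by the tier taxonomy: U single -2,
V/W chains of distance-reducing recombinations, X single -1, Y/Z chains
through a neutral source-creating recombination), so that

    distance = d_DCJ + sum(sigma) - P_L - P_C - (2U + 3V + 2W + X + 2Y + Z)
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Optional

from .adjacency_graph import (
    Component,
    ComponentKind,
    build_adjacencies,
    build_graph,
    components,
    dcj_distance_from_components,
)
from .genome_model import Genome
from .potentials import (
    PotentialSummary,
    RunSequence,
    component_runs,
    cotailed,
    upper_bound_distance,
)
from .genome_model import partition_markers


# ---------------------------------------------------------------------------
# path classification

@dataclass(frozen=True)
class PathClass:
    """A path kind plus its run-structure class (the 4i+k taxonomy)."""

    path_kind: str  # "AA" | "BB" | "AB"
    empty: bool = True
    first_run: Optional[str] = None  # "A" | "B"
    k: Optional[int] = None  # 1..4
    i: int = 0
    singleton: bool = False

    @property
    def token(self) -> str:
        """Type token as used in the rule table (i-independent)."""
        if self.empty:
            return f"{self.path_kind}_e"
        letter = "a" if self.first_run == "A" else "b"
        prefix = "s" if self.singleton else ""
        return f"{prefix}{self.path_kind}.{letter}{self.k}"

    def __str__(self) -> str:
        return self.token if self.empty else f"{self.token}(i={self.i})"


def classify_path(c: Component, r: Optional[RunSequence] = None) -> PathClass:
    """Classify a path component; cycles and circular singletons are not
    sources of recombinations and are rejected."""
    if not c.is_path:
        raise ValueError(f"cannot classify {c.kind.value}: not a path")
    if r is None:
        r = component_runs(c)
    kind = {
        ComponentKind.AA: "AA",
        ComponentKind.LIN_SINGLETON_A: "AA",
        ComponentKind.BB: "BB",
        ComponentKind.LIN_SINGLETON_B: "BB",
        ComponentKind.AB: "AB",
    }[c.kind]
    singleton = c.kind in (
        ComponentKind.LIN_SINGLETON_A,
        ComponentKind.LIN_SINGLETON_B,
    )
    lam = r.lambda_count
    if lam == 0:
        return PathClass(kind, empty=True, singleton=singleton)
    k = ((lam - 1) % 4) + 1
    i = (lam - k) // 4
    first = r.runs[0]
    # AA/BB paths read in either direction: even run counts lose chirality
    if kind in ("AA", "BB") and lam % 2 == 0:
        first = "A"
    return PathClass(kind, False, first, k, i, singleton)


# ---------------------------------------------------------------------------
# rule table

@dataclass(frozen=True)
class RecombinationRule:
    """One recombination: an unordered source pair, the achievable
    resultant alternatives, and its deltas."""

    table: int  # 1 (distance-reducing) or 2 (neutral, source-creating)
    group: str  # U | V | W | X | Y | Z
    sources: tuple[str, str]
    delta_sigma: int
    delta_dcj: int
    delta_d: int
    score: Fraction
    resultants: tuple[tuple[str, ...], ...]  # alternatives


class RuleTableError(ValueError):
    pass


_MIRROR_LETTER = {"a": "b", "b": "a"}


def mirror_token(token: str) -> str:
    """Image of a type token under swapping the roles of genomes A and B."""
    s = ""
    if token.startswith("s"):
        s, token = "s", token[1:]
    kind, _, rest = token.partition(".")
    if not rest:  # eps types: AA_e <-> BB_e, AB_e self
        kind = kind.split("_")[0]
        mk = {"AA": "BB", "BB": "AA", "AB": "AB"}[kind]
        return f"{s}{mk}_e"
    letter, k = rest[0], int(rest[1])
    if kind in ("AA", "BB"):
        mk = "BB" if kind == "AA" else "AA"
        ml = _MIRROR_LETTER[letter] if k % 2 == 1 else letter
        return f"{s}{mk}.{ml}{k}"
    # AB path: reading direction reverses and letters flip; for odd k the
    # first letter flips, for even k it is restored by the reversal.
    ml = _MIRROR_LETTER[letter] if k % 2 == 1 else letter
    return f"{s}AB.{ml}{k}"


def load_rule_table(path: Optional[str] = None) -> list[RecombinationRule]:
    """Load and validate the recombination rule table."""
    if path is None:
        content = (
            resources.files("dcjsub").joinpath("data/recombination_rules.tsv").read_text()
        )
    else:
        with open(path) as fh:
            content = fh.read()
    lines = content.splitlines()
    if not lines or not lines[0].startswith("# checksum:"):
        raise RuleTableError("missing checksum line")
    digest = lines[0].split(":", 1)[1].strip()
    body = "\n".join(lines[1:]) + "\n"
    if hashlib.sha256(body.encode()).hexdigest()[:16] != digest:
        raise RuleTableError("rule table checksum mismatch")
    header = lines[1].split("\t")
    expected = [
        "table", "group", "source1", "source2",
        "delta_sigma", "delta_dcj", "delta_d", "score", "resultants",
    ]
    if header != expected:
        raise RuleTableError(f"unexpected header {header}")
    rules: list[RecombinationRule] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise RuleTableError(f"row {lineno}: expected 9 columns")
        table, group = int(f[0]), f[1]
        ds, dc, dd = int(f[4]), int(f[5]), int(f[6])
        if dd != ds + dc:
            raise RuleTableError(f"row {lineno}: delta_d != delta_sigma + delta_dcj")
        if ds < -2:
            raise RuleTableError(f"row {lineno}: delta_sigma below the -2 bound")
        if table == 1 and dd > -1:
            raise RuleTableError(f"row {lineno}: table-1 rule with delta_d > -1")
        if table == 2 and dd != 0:
            raise RuleTableError(f"row {lineno}: table-2 rule with delta_d != 0")
        if group not in set("UVWXYZ"):
            raise RuleTableError(f"row {lineno}: bad group {group!r}")
        resultants = tuple(tuple(alt.split("+")) for alt in f[8].split("|"))
        rules.append(
            RecombinationRule(
                table, group, (f[2], f[3]), ds, dc, dd,
                Fraction(f[7]), resultants,
            )
        )
    _validate_rules(rules)
    return rules


def _validate_rules(rules: list[RecombinationRule]) -> None:
    groups = {r.group for r in rules}
    if groups != set("UVWXYZ"):
        raise RuleTableError(f"missing group tags: {set('UVWXYZ') - groups}")
    t1_sources = {t for r in rules if r.table == 1 for t in r.sources}
    for r in rules:
        if r.table == 2 and not any(
            t in t1_sources for alt in r.resultants for t in alt
        ):
            raise RuleTableError(
                f"table-2 rule {r.sources} creates no table-1 source"
            )
    # closure under swapping the genomes
    index: dict[tuple, set] = {}
    for r in rules:
        index.setdefault((r.table, tuple(sorted(r.sources))), set()).add(
            (r.delta_sigma, r.delta_dcj)
        )
    for r in rules:
        msrc = tuple(sorted(mirror_token(t) for t in r.sources))
        deltas = index.get((r.table, msrc))
        if deltas is None or (r.delta_sigma, r.delta_dcj) not in deltas:
            raise RuleTableError(f"rule {r.sources} has no mirror image {msrc}")


_RULES_CACHE: Optional[list[RecombinationRule]] = None


def default_rules() -> list[RecombinationRule]:
    global _RULES_CACHE
    if _RULES_CACHE is None:
        _RULES_CACHE = load_rule_table()
    return _RULES_CACHE


# ---------------------------------------------------------------------------
# optimal recombination plan

@dataclass(frozen=True)
class GroupCounts:
    U: int = 0
    V: int = 0
    W: int = 0
    X: int = 0
    Y: int = 0
    Z: int = 0

    @property
    def deduction(self) -> int:
        return 2 * self.U + 3 * self.V + 2 * self.W + self.X + 2 * self.Y + self.Z


def _rule_index(rules):
    by_pair: dict[tuple[str, str], list[RecombinationRule]] = {}
    for r in rules:
        by_pair.setdefault(tuple(sorted(r.sources)), []).append(r)
    return by_pair


def _optimal_plan(counts: Counter, rules) -> tuple[int, list]:
    """Maximum total |delta_d| over recombination sequences, plus one
    optimal op sequence as witness.

    Memoized exhaustive search over the type multiset; every applicable
    rule strictly reduces the total substitution-potential, so the
    search depth is bounded by the initial sigma total.
    """
    by_pair = _rule_index(rules)
    t1_sources = {t for r in rules if r.table == 1 for t in r.sources}
    memo: dict[tuple, tuple[int, list]] = {}

    def best(ms: Counter) -> tuple[int, list]:
        key = tuple(sorted(ms.items()))
        if key in memo:
            return memo[key]
        memo[key] = (0, [])
        res, plan = 0, []
        items = sorted(ms)
        for ii, x in enumerate(items):
            for y in items[ii:]:
                if x == y and ms[x] < 2:
                    continue
                pair = (x, y)
                for rule in by_pair.get(pair, ()):
                    for alt in rule.resultants:
                        nxt = Counter(ms)
                        nxt[x] -= 1
                        nxt[y] -= 1
                        for t in alt:
                            # only table-1 sources can ever matter again
                            if t in t1_sources:
                                nxt[t] += 1
                        nxt = +nxt
                        sub, subplan = best(nxt)
                        total = -rule.delta_d + sub
                        if total > res:
                            res = total
                            plan = [(rule, pair, alt)] + subplan
        memo[key] = (res, plan)
        return res, plan

    relevant = Counter(
        {t: n for t, n in counts.items() if t in {s for r in rules for s in r.sources}}
    )
    return best(relevant)


def _classify_plan(plan) -> GroupCounts:
    """Partition an optimal op sequence into recombination groups.

    Ops consuming a resultant of an earlier op belong to that op's
    chain.  Chains of distance-reducing recombinations alone count as
    U (single op, delta_d -2), X (single op, -1), W (-2 total) or V
    (-3 total); chains routed through a neutral source-creating
    recombination count as Y (-2) or Z (-1).  Longer chains decompose
    greedily into these units.
    """
    n = len(plan)
    chain_id = list(range(n))

    def find(i):
        while chain_id[i] != i:
            chain_id[i] = chain_id[chain_id[i]]
            i = chain_id[i]
        return i

    avail: list[tuple[int, str]] = []  # (op index, type) of unconsumed resultants
    for idx, (rule, pair, alt) in enumerate(plan):
        for t in pair:
            for j, (src_idx, typ) in enumerate(avail):
                if typ == t:
                    chain_id[find(idx)] = find(src_idx)
                    avail.pop(j)
                    break
        for t in alt:
            avail.append((idx, t))

    chains: dict[int, list] = {}
    for idx, op in enumerate(plan):
        chains.setdefault(find(idx), []).append(op)

    U = V = W = X = Y = Z = 0
    for ops in chains.values():
        total = -sum(rule.delta_d for rule, _, _ in ops)
        has_t2 = any(rule.table == 2 for rule, _, _ in ops)
        if len(ops) == 1 and not has_t2:
            U += total // 2
            X += total % 2
        elif has_t2:
            Y += total // 2
            Z += total % 2
        else:
            V += total // 3
            rem = total % 3
            W += rem // 2
            X += rem % 2
    return GroupCounts(U, V, W, X, Y, Z)


def greedy_groups(
    path_classes, rules: Optional[list[RecombinationRule]] = None
) -> GroupCounts:
    """Group counts U..Z of an optimal recombination plan for a multiset
    of path classes.

    The result depends only on the counts of each type (the plan search
    is deterministic over the sorted multiset), and the deduction
    2U + 3V + 2W + X + 2Y + Z equals the optimum over all rule
    application sequences.
    """
    if rules is None:
        rules = default_rules()
    counts = Counter(
        pc.token if isinstance(pc, PathClass) else str(pc) for pc in path_classes
    )
    _, plan = _optimal_plan(counts, rules)
    return _classify_plan(plan)


# ---------------------------------------------------------------------------
# the distance

@dataclass
class DistanceReport:
    """All quantities entering the DCJ-substitution distance."""

    n: int
    c: int
    b: int
    d_dcj: int
    sum_lambda: int
    sum_sigma: int
    p_l: int
    p_c: int
    groups: GroupCounts
    d_upper: int
    d_dcjsub: int
    co_tailed: bool
    per_component: list[tuple[str, int, int, int, str]] = field(default_factory=list)
    # rows: (kind, Lambda, lambda, sigma, path-class token or "-")

    @property
    def deduction(self) -> int:
        return self.groups.deduction

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "c": self.c,
            "b": self.b,
            "d_dcj": self.d_dcj,
            "sum_lambda": self.sum_lambda,
            "sum_sigma": self.sum_sigma,
            "p_l": self.p_l,
            "p_c": self.p_c,
            "U": self.groups.U,
            "V": self.groups.V,
            "W": self.groups.W,
            "X": self.groups.X,
            "Y": self.groups.Y,
            "Z": self.groups.Z,
            "deduction": self.deduction,
            "d_upper": self.d_upper,
            "d_dcjsub": self.d_dcjsub,
            "co_tailed": self.co_tailed,
        }


def recombination_pool(comps: list[Component]) -> list[PathClass]:
    """Path classes eligible as recombination sources.

    Labeled AA-/BB-/AB-paths enter with their type.  Linear singletons
    are degenerate k=1 paths: after the maximum disjoint pairing P_L is
    set aside (one whole-chromosome substitution per pair), the excess
    ones join the pool as restricted singleton types.  Circular
    singletons, clean paths and cycles are never sources.
    """
    pool: list[PathClass] = []
    lin_a = [c for c in comps if c.kind == ComponentKind.LIN_SINGLETON_A]
    lin_b = [c for c in comps if c.kind == ComponentKind.LIN_SINGLETON_B]
    p_l = min(len(lin_a), len(lin_b))
    for c in comps:
        if c.kind in (ComponentKind.AA, ComponentKind.BB, ComponentKind.AB):
            r = component_runs(c)
            if r.lambda_count:
                pool.append(classify_path(c, r))
    for extra in lin_a[p_l:]:
        pool.append(classify_path(extra))
    for extra in lin_b[p_l:]:
        pool.append(classify_path(extra))
    return pool


def dcjsub_distance(
    a: Genome, b: Genome, rules: Optional[list[RecombinationRule]] = None
) -> DistanceReport:
    """The DCJ-substitution distance between two genomes.

    ``d_DCJ + sum(sigma) - P_L - P_C - deduction`` with the deduction
    from an optimal recombination plan over the labeled paths.
    """
    if rules is None:
        rules = default_rules()
    p = partition_markers(a, b)
    graph = build_graph(
        build_adjacencies(a, p, "A"), build_adjacencies(b, p, "B"), p
    )
    comps = components(graph)
    summary = PotentialSummary.from_components(comps)
    d_dcj = dcj_distance_from_components(comps, p)
    d_upper = upper_bound_distance(graph, p, summary)
    groups = greedy_groups(recombination_pool(comps), rules)
    dist = d_upper - groups.deduction
    assert dist >= 0, "deduction exceeded the upper bound"
    c_count = sum(1 for c in comps if c.kind == ComponentKind.CYCLE)
    b_count = sum(1 for c in comps if c.kind == ComponentKind.AB)
    per_component = []
    for comp, runs, lam, sig in summary.per_component:
        token = classify_path(comp, runs).token if comp.is_path else "-"
        per_component.append((comp.kind.value, runs.lambda_count, lam, sig, token))
    return DistanceReport(
        n=p.n,
        c=c_count,
        b=b_count,
        d_dcj=d_dcj,
        sum_lambda=summary.total_lambda,
        sum_sigma=summary.total_sigma,
        p_l=summary.p_l,
        p_c=summary.p_c,
        groups=groups,
        d_upper=d_upper,
        d_dcjsub=dist,
        co_tailed=cotailed(a, b),
        per_component=per_component,
    )
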