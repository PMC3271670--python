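import itertools
import random

import pytest

from conftest import graph_of, make_pair

from dcjsub.adjacency_graph import ComponentKind
from dcjsub.potentials import component_runs
from dcjsub.recombination import (
    GroupCounts,
    PathClass,
    RuleTableError,
    classify_path,
    dcjsub_distance,
    default_rules,
    greedy_groups,
    load_rule_table,
    mirror_token,
    recombination_pool,
)


# ---------------------------------------------------------------- classify

class TestClassifyPath:
    def test_clean_ab_path(self):
        a, b = make_pair([([1], False)], [([1], False)])
        _, _, comps = graph_of(a, b)
        ab = [c for c in comps if c.kind == ComponentKind.AB]
        pc = classify_path(ab[0])
        assert pc.empty and pc.token == "AB_e"

    def test_bb_path_with_four_runs(self):
        a, b = make_pair(
            [([1, "u2", -2, "u1"], True)],
            [([1, "v1", 2, "v2"], False)],
        )
        _, _, comps = graph_of(a, b)
        bb = [c for c in comps if c.kind == ComponentKind.BB][0]
        pc = classify_path(bb)
        assert pc.k == 4 and pc.i == 0 and not pc.empty
        # four runs on a BB path: chirality is lost (read either way)
        assert pc.token == "BB.a4"

    def test_aa_path_single_a_run(self):
        a, b = make_pair([([1, "x"], False)], [([1], True)])
        _, _, comps = graph_of(a, b)
        aa = [c for c in comps if c.kind == ComponentKind.AA][0]
        pc = classify_path(aa)
        assert pc.token == "AA.a1" and pc.k == 1 and pc.i == 0

    def test_cycle_rejected(self):
        a, b = make_pair([([1, 2], True)], [([1, 2], True)])
        _, _, comps = graph_of(a, b)
        cyc = [c for c in comps if c.kind == ComponentKind.CYCLE][0]
        with pytest.raises(ValueError):
            classify_path(cyc)

    def test_circular_singleton_rejected(self):
        a, b = make_pair([(["x"], True), ([1], False)], [([1], False)])
        _, _, comps = graph_of(a, b)
        circ = [c for c in comps if c.kind == ComponentKind.CIRC_SINGLETON_A][0]
        with pytest.raises(ValueError):
            classify_path(circ)


# ---------------------------------------------------------------- rule table

class TestRuleTable:
    def test_loads_and_has_all_groups(self):
        rules = default_rules()
        assert {r.group for r in rules} == set("UVWXYZ")

    def test_u_rule(self):
        u = [r for r in default_rules() if r.group == "U"]
        assert len(u) == 1
        assert (u[0].delta_sigma, u[0].delta_dcj, u[0].delta_d) == (-2, 0, -2)
        assert set(u[0].sources) == {"AA.a4", "BB.a4"}

    def test_delta_arithmetic_holds(self):
        for r in default_rules():
            assert r.delta_d == r.delta_sigma + r.delta_dcj
            assert r.delta_sigma >= -2
            if r.table == 1:
                assert r.delta_d <= -1
            else:
                assert r.delta_d == 0

    def test_mirror_closure(self):
        rules = default_rules()
        pairs = {(r.table, tuple(sorted(r.sources))) for r in rules}
        for r in rules:
            msrc = tuple(sorted(mirror_token(t) for t in r.sources))
            assert (r.table, msrc) in pairs

    def test_corrupt_table_rejected(self, tmp_path):
        import hashlib

        src = (tmp_path / "rules.tsv")
        header = "table\tgroup\tsource1\tsource2\tdelta_sigma\tdelta_dcj\tdelta_d\tscore\tresultants"
        bad_row = "1\tU\tAA.a4\tBB.a4\t-2\t0\t-1\t-1\tAB_e+AB_e"  # -2+0 != -1
        body = header + "\n" + bad_row + "\n"
        digest = hashlib.sha256(body.encode()).hexdigest()[:16]
        src.write_text(f"# checksum:{digest}\n" + body)
        with pytest.raises(RuleTableError, match="delta_d"):
            load_rule_table(str(src))

    def test_checksum_guard(self, tmp_path):
        src = tmp_path / "rules.tsv"
        src.write_text("# checksum:deadbeefdeadbeef\nnot a table\n")
        with pytest.raises(RuleTableError, match="checksum"):
            load_rule_table(str(src))

    def test_shipped_table_matches_fresh_derivation(self):
        from importlib import resources

        from dcjsub._rulegen import generate_table_body

        shipped = (
            resources.files("dcjsub")
            .joinpath("data/recombination_rules.tsv")
            .read_text()
        )
        assert shipped.split("\n", 1)[1] == generate_table_body()


# ---------------------------------------------------------------- groups

def brute_force_deduction(tokens, rules):
    """Independent oracle: explore every recombination sequence."""
    from collections import Counter

    by_pair = {}
    for r in rules:
        by_pair.setdefault(tuple(sorted(r.sources)), []).append(r)
    source_types = {t for r in rules for t in r.sources}

    def explore(ms):
        best = 0
        items = sorted(ms)
        for x, y in itertools.combinations_with_replacement(sorted(set(items)), 2):
            if x == y and ms[x] < 2:
                continue
            if ms[x] < 1 or ms[y] < 1:
                continue
            for rule in by_pair.get(tuple(sorted((x, y))), ()):
                for alt in rule.resultants:
                    nxt = Counter(ms)
                    nxt[x] -= 1
                    nxt[y] -= 1
                    for t in alt:
                        if t in source_types:
                            nxt[t] += 1
                    best = max(best, -rule.delta_d + explore(+nxt))
        return best

    from collections import Counter as C

    return explore(C(tokens))


SOURCE_TOKENS = sorted({t for r in default_rules() for t in r.sources})


class TestGreedyGroups:
    def test_empty_pool(self):
        assert greedy_groups([]) == GroupCounts()

    def test_u_pair_counted(self):
        g = greedy_groups(["AA.a4", "BB.a4"])
        assert g.U == 1 and g.deduction == 2

    def test_matches_exhaustive_enumeration(self):
        rules = default_rules()
        rng = random.Random(42)
        for _ in range(60):
            size = rng.randint(2, 5)
            ms = [rng.choice(SOURCE_TOKENS) for _ in range(size)]
            got = greedy_groups(ms, rules).deduction
            want = brute_force_deduction(ms, rules)
            assert got == want, f"multiset {ms}: {got} != {want}"

    def test_depends_only_on_counts(self):
        rules = default_rules()
        ms = ["AA.a4", "BB.a4", "AB.a4", "AA.a1", "BB.b1"]
        base = greedy_groups(ms, rules)
        for perm in itertools.permutations(ms):
            assert greedy_groups(list(perm), rules) == base

    def test_deduction_formula(self):
        g = GroupCounts(U=1, V=2, W=1, X=3, Y=1, Z=2)
        assert g.deduction == 2 + 6 + 2 + 3 + 2 + 2


# ---------------------------------------------------------------- distance

class TestDistance:
    def test_identical_genomes(self):
        a, b = make_pair([([1, 2, 3], False)], [([1, 2, 3], False)])
        assert dcjsub_distance(a, b).d_dcjsub == 0

    def test_single_substitution_distance_one(self, substitution_pair):
        rep = dcjsub_distance(*substitution_pair)
        assert rep.d_dcjsub == 1
        assert rep.sum_sigma == 1 and rep.d_dcj == 0

    def test_symmetry_on_random_instances(self):
        from conftest import random_small_pair

        checked = 0
        for trial in range(120):
            pair = random_small_pair(trial)
            if pair is None:
                continue
            a, b, _ = pair
            assert dcjsub_distance(a, b).d_dcjsub == dcjsub_distance(b, a).d_dcjsub
            checked += 1
        assert checked >= 80

    def test_report_invariants(self):
        from conftest import random_small_pair

        for trial in range(60):
            pair = random_small_pair(trial)
            if pair is None:
                continue
            a, b, _ = pair
            rep = dcjsub_distance(a, b)
            assert 0 <= rep.d_dcjsub <= rep.d_upper
            assert rep.d_upper <= rep.d_dcj + rep.sum_lambda
            assert rep.b % 2 == 0

    def test_triangle_inequality_can_fail(self):
        # A and C share all five markers but are three inversions apart;
        # B keeps only marker 1, so both legs through B cost one
        # substitution-like step plus nothing else.
        a = make_pair([([1, 2, 3, 4, 5], False)], [([1], False)])[0]
        b = make_pair([([1], False)], [([1], False)])[0]
        c = make_pair([([1, 4, -2, 5, 3], False)], [([1], False)])[0]
        d_ab = dcjsub_distance(a, b).d_dcjsub
        d_bc = dcjsub_distance(b, c).d_dcjsub
        d_ac = dcjsub_distance(a, c).d_dcjsub
        assert d_ac > d_ab + d_bc

    def test_duplicate_marker_rejected(self):
        from dcjsub.genome_model import GenomeError

        with pytest.raises(GenomeError):
            make_pair([([1, 1], False)], [([1], False)])


class TestPool:
    def test_paired_singletons_stay_out(self):
        a, b = make_pair(
            [(["x"], False), ([1], False)],
            [(["y"], False), ([1], False)],
        )
        _, _, comps = graph_of(a, b)
        assert recombination_pool(comps) == []

    def test_excess_singleton_enters_restricted(self):
        a, b = make_pair(
            [(["x"], False), (["w"], False), ([1], False)],
            [(["y"], False), ([1], False)],
        )
        _, _, comps = graph_of(a, b)
        pool = recombination_pool(comps)
        assert [pc.token for pc in pool] == ["sAA.a1"]

    def test_circular_singletons_never_enter(self):
        a, b = make_pair(
            [(["x"], True), ([1], False)],
            [([1], False)],
        )
        _, _, comps = graph_of(a, b)
        assert recombination_pool(comps) == []
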