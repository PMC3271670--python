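import random

import pytest

from conftest import make_pair, random_small_pair

from dcjsub.genome_model import Chromosome, SignedMarker, genome_from_lists
from dcjsub.oracle_sim import (
    DcjOperation,
    OracleCapError,
    SubstitutionOperation,
    apply_dcj,
    apply_substitution,
    dcj_operations,
    genome_to_matching,
    matching_to_genome,
    oracle_distance,
    random_genome_pair,
    substitution_operations,
)


class TestMatching:
    def test_roundtrip(self):
        g = genome_from_lists("G", [([1, -2, 3], False), ([4, 5], True)])
        adjs = genome_to_matching(g)
        back = matching_to_genome(adjs, g.marker_ids(), "G")
        assert back.equivalent(g)

    def test_single_marker_circle(self):
        g = genome_from_lists("G", [([1], True)])
        back = matching_to_genome(genome_to_matching(g), {"1"}, "G")
        assert back.equivalent(g)


class TestApplyDcj:
    def test_inversion_of_middle_marker(self):
        g = genome_from_lists("G", [([1, 2, 3], False)])
        target = genome_from_lists("G", [([1, -2, 3], False)])
        assert any(
            apply_dcj(g, op).equivalent(target) for op in dcj_operations(g)
        )

    def test_fission_of_circular(self):
        g = genome_from_lists("G", [([1, 2], True)])
        target = genome_from_lists("G", [([1], True), ([2], True)])
        assert any(
            apply_dcj(g, op).equivalent(target) for op in dcj_operations(g)
        )

    def test_inverse_restores(self):
        rng = random.Random(3)
        g = genome_from_lists("G", [([1, 2, 3, 4], False), ([5, 6], True)])
        ops = dcj_operations(g)
        for op in rng.sample(ops, min(100, len(ops))):
            h = apply_dcj(g, op)
            assert apply_dcj(h, op.inverse()).equivalent(g)

    def test_invalid_cut_rejected(self):
        g = genome_from_lists("G", [([1, 2], False)])
        bogus = DcjOperation(
            frozenset({frozenset({("9", "h")})}),
            frozenset({frozenset({("9", "h")})}),
        )
        with pytest.raises(ValueError):
            apply_dcj(g, bogus)


class TestApplySubstitution:
    def test_block_substitution(self, substitution_pair):
        a, b = substitution_pair
        op = SubstitutionOperation(
            0, 1,
            removed=(SignedMarker("s"), SignedMarker("u")),
            inserted=(SignedMarker("x"), SignedMarker("y")),
        )
        assert apply_substitution(a, op).equivalent(b)

    def test_insertion_and_deletion(self):
        g = genome_from_lists("G", [(["a", "b"], False)])
        ins = SubstitutionOperation(0, 1, (), (SignedMarker("x"),))
        g2 = apply_substitution(g, ins)
        assert [m.id for m in g2.chromosomes[0].markers] == ["a", "x", "b"]
        dele = SubstitutionOperation(0, 1, (SignedMarker("x"),), ())
        assert apply_substitution(g2, dele).equivalent(g)

    def test_substitute_then_invert_restores(self):
        g = genome_from_lists("G", [(["a", "s", "b"], False)])
        op = SubstitutionOperation(0, 1, (SignedMarker("s"),), (SignedMarker("t"),))
        h = apply_substitution(g, op)
        assert apply_substitution(h, op.inverse_on(h)).equivalent(g)

    def test_block_must_be_present(self):
        g = genome_from_lists("G", [(["a", "b"], False)])
        op = SubstitutionOperation(0, 0, (SignedMarker("z"),), ())
        with pytest.raises(ValueError):
            apply_substitution(g, op)

    def test_whole_chromosome_topology_preserved(self):
        # whole-chromosome substitutions never swap linear and circular:
        # the generated moves only offer same-topology replacements
        a = genome_from_lists("A", [(["x"], False), ([1], False)])
        b = genome_from_lists("B", [(["y"], True), ([1], False)])
        moves = substitution_operations(a, b)
        for op in moves:
            if op.chrom == 0 and len(op.removed) == 1 and op.inserted:
                # in-place whole replacement of the linear (x) by circular
                # content is not offered
                assert [m.id for m in op.inserted] != ["y"]
        # the circular chromosome (y) still arrives as a new chromosome
        assert any(
            op.chrom is None and op.new_circular for op in moves
        )


class TestOracle:
    def test_identical_zero(self):
        a, b = make_pair([([1, 2], False)], [([1, 2], False)])
        assert oracle_distance(a, b) == 0

    def test_single_substitution(self, substitution_pair):
        assert oracle_distance(*substitution_pair) == 1

    def test_single_inversion(self):
        a, b = make_pair([([1, 2, 3], False)], [([1, -2, 3], False)])
        assert oracle_distance(a, b) == 1

    def test_cap_refused(self):
        a, b = make_pair([([1, 2, 3, 4, 5, 6, 7, 8], False)],
                         [([1, 2, 3, 4, 5, 6, 7, 8], False)])
        with pytest.raises(OracleCapError):
            oracle_distance(a, b)


class TestGenerator:
    def test_no_ops_identical(self):
        a, b, planted = random_genome_pair(3, 0, 0, 0, 0, seed=5)
        assert planted == 0
        assert a.equivalent(b)

    def test_deterministic_under_seed(self):
        a1, b1, _ = random_genome_pair(4, 2, 2, 2, 2, seed=11)
        a2, b2, _ = random_genome_pair(4, 2, 2, 2, 2, seed=11)
        assert a1.equivalent(a2) and b1.equivalent(b2)

    def test_unique_marker_bookkeeping(self):
        from dcjsub.genome_model import partition_markers

        for seed in range(30):
            a, b, _ = random_genome_pair(3, 2, 2, 1, 2, seed=seed)
            p = partition_markers(a, b)
            assert p.unique_a <= {"a1", "a2"}
            assert p.unique_b <= {"b1", "b2"}
            assert p.common == {"1", "2", "3"}

    def test_planted_bounds_distance(self):
        from dcjsub.recombination import dcjsub_distance

        checked = 0
        for trial in range(300):
            pair = random_small_pair(trial)
            if pair is None:
                continue
            a, b, planted = pair
            assert dcjsub_distance(a, b).d_dcjsub <= planted
            checked += 1
        assert checked >= 200

    def test_insufficient_uniques_rejected(self):
        with pytest.raises(ValueError):
            random_genome_pair(2, 1, 0, 0, 3, seed=0)
        with pytest.raises(ValueError):
            random_genome_pair(2, 1, 1, 0, 0, seed=0)
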