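"""Structure decomposition, hit location, qualification rules, star
inference, duplex statistics and the final rule engine."""

import numpy as np
import pytest

from premir.config import QualConfig, RuleConfig
from premir.formats import from_dot_bracket
from premir.hairpin import (
    StarInferenceError,
    apply_rules,
    decompose,
    disqualify,
    duplex_stats,
    infer_star,
    locate_hit,
)
from premir.simulate import HairpinParams, make_hairpin

from conftest import brute_force_element_kinds, random_nested_structure


class TestDecompose:
    def test_simple_hairpin(self):
        s = from_dot_bracket("GGGGAAAACCCC", "((((....))))")
        elements = decompose(s)
        kinds = sorted(e.kind for e in elements)
        assert kinds == ["hairpin_loop", "stem"]
        stem = next(e for e in elements if e.kind == "stem")
        assert len(stem.positions) == 8

    def test_bulged_hairpin_by_hand(self):
        s = from_dot_bracket("GGAAGGAAACCCC", "((..((...))))")
        by_kind = {}
        for e in decompose(s):
            by_kind.setdefault(e.kind, []).append(e)
        assert len(by_kind["stem"]) == 2
        assert len(by_kind["bulge"]) == 1
        assert by_kind["bulge"][0].positions == (3, 4)
        assert len(by_kind["hairpin_loop"]) == 1

    def test_partition_property_and_brute_force_oracle(self, rng):
        """On 500 random nested structures the decomposition partitions all
        positions and agrees with an independent per-position scan."""
        for _ in range(500):
            s = random_nested_structure(rng, int(rng.integers(20, 70)))
            elements = decompose(s)
            seen = {}
            for e in elements:
                for p in e.positions:
                    assert p not in seen, "position in two elements"
                    seen[p] = e.kind
            assert set(seen) == set(range(1, len(s) + 1))
            assert seen == brute_force_element_kinds(s)


class TestLocateHit:
    def _hairpin(self, rng):
        mature = "".join(rng.choice(list("ACGU"), 21))
        return make_hairpin(mature, HairpinParams(), seed=1)

    def test_five_prime_arm(self, rng):
        _, s, truth = self._hairpin(rng)
        ctx = locate_hit(s, truth.mir_span)
        assert ctx.arm == "5p"
        assert ctx.terminal_structure_count == 1

    def test_loop_hit_fully_unpaired(self, rng):
        _, s, truth = self._hairpin(rng)
        ctx = locate_hit(s, truth.loop_span)
        assert ctx.arm == "loop"

    def test_crossing_hit_straddles_apex(self, rng):
        _, s, truth = self._hairpin(rng)
        span = (truth.mir_span[1] - 8, truth.star_span[0] + 8)
        ctx = locate_hit(s, span)
        assert ctx.arm == "crossing"

    def test_three_prime_arm(self, rng):
        mature = "".join(rng.choice(list("ACGU"), 21))
        _, s, truth = make_hairpin(mature, HairpinParams(arm="3p"), seed=2)
        ctx = locate_hit(s, truth.mir_span)
        assert ctx.arm == "3p"


class TestDisqualify:
    def test_clean_arm_hit_accepted(self, random_mature):
        _, s, truth = make_hairpin(random_mature(), HairpinParams(), seed=3)
        v = disqualify(s, locate_hit(s, truth.mir_span))
        assert v.accepted and v.violated == ()

    def test_unpaired_hit_violates_stem_rules(self, random_mature):
        _, s, truth = make_hairpin(random_mature(), HairpinParams(loop_size=8), seed=3)
        v = disqualify(s, locate_hit(s, truth.loop_span))
        assert not v.accepted
        assert "i" in v.violated and "ii" in v.violated

    def test_crossing_hit_violates_same_side_rule(self, random_mature):
        _, s, truth = make_hairpin(random_mature(), HairpinParams(), seed=3)
        span = (truth.mir_span[1] - 8, truth.star_span[0] + 8)
        v = disqualify(s, locate_hit(s, span))
        assert "vi" in v.violated

    def test_inner_branch_rule(self):
        # hit covers a stem AND a complete inner hairpin
        db = "((((..((...))..((((....))))..))))"
        seq = "G" * len(db)
        s = from_dot_bracket(seq, db)
        v = disqualify(s, locate_hit(s, (1, 13)))
        assert "iv" in v.violated

    # a mature-like span at 3..23 whose pairing straddles a foreign branch:
    # positions 3-12 close the outer helix, 14-23 an inner one, and an
    # unrelated hairpin (38-49) sits between the two complementary blocks
    BRANCHED = ".." + "(" * 10 + "." + "(" * 10 + "...." + ")" * 10 + "((((....))))" + ")" * 10 + "..."

    def test_unbranched_complement_not_flagged(self):
        db = "((((((((....((((....))))....))))))))"
        s = from_dot_bracket("G" * len(db), db)
        v = disqualify(s, locate_hit(s, (1, 8)))
        assert "v" not in v.violated

    def test_branched_complement_rule(self):
        s = from_dot_bracket("G" * len(self.BRANCHED), self.BRANCHED)
        v = disqualify(s, locate_hit(s, (3, 23)))
        assert "v" in v.violated
        assert "iv" not in v.violated  # no complete pair inside the hit itself

    def test_terminal_structure_budget(self):
        """At most 3 terminal structures are tolerated on the hit's branch."""

        def with_k_hairpins(k):
            inner = "." + "((((....))))" * k + "."
            db = "(((((((((" + inner + ")))))))))"
            s = from_dot_bracket("G" * len(db), db)
            return disqualify(s, locate_hit(s, (1, 9)))

        assert with_k_hairpins(1).accepted
        assert with_k_hairpins(3).accepted
        v = with_k_hairpins(4)
        assert not v.accepted
        assert "primary_terminal_structures" in v.violated
        assert v.stage == "primary_filter"

    def test_violation_accumulation_is_monotone(self, random_mature):
        """Degrading a fixture can only add violations, never rescue it."""
        _, s, truth = make_hairpin(random_mature(), HairpinParams(), seed=5)
        spans = [
            truth.mir_span,                                  # clean
            (truth.mir_span[1] - 8, truth.star_span[0] + 8),  # crossing
            truth.loop_span,                                  # unpaired
        ]
        n_violations = [len(disqualify(s, locate_hit(s, sp)).violated) for sp in spans]
        accepted = [disqualify(s, locate_hit(s, sp)).accepted for sp in spans]
        assert accepted[0] and not accepted[1] and not accepted[2]
        assert n_violations[0] == 0 and min(n_violations[1:]) >= 1


class TestInferStar:
    def test_involution_on_perfect_duplex(self, random_mature):
        _, s, truth = make_hairpin(random_mature(), HairpinParams(), seed=6)
        star = infer_star(s, truth.mir_span)
        assert star == truth.star_span
        assert infer_star(s, star) == truth.mir_span

    def test_recovers_planted_star_with_imperfections(self, random_mature):
        params = HairpinParams(
            mismatch_positions=(5, 12), bulges=((8, 1, "star"),), ext_stem=10
        )
        _, s, truth = make_hairpin(random_mature(), params, seed=7)
        assert infer_star(s, truth.mir_span) == truth.star_span

    def test_all_unpaired_mature_is_inference_error(self, random_mature):
        _, s, truth = make_hairpin(random_mature(), HairpinParams(loop_size=8), seed=6)
        with pytest.raises(StarInferenceError):
            infer_star(s, truth.loop_span)


class TestDuplexStats:
    def test_perfect_duplex(self, random_mature):
        _, s, truth = make_hairpin(random_mature(), HairpinParams(), seed=8)
        st = duplex_stats(s, truth.mir_span, truth.star_span)
        assert st.n_mismatch == 0 and st.n_asym == 0
        assert not st.secondary_stem
        assert (st.overhang_5p_side, st.overhang_3p_side) == (2, 2)

    def test_three_symmetric_loops(self, random_mature):
        params = HairpinParams(mismatch_positions=(5, 9, 14))
        _, s, truth = make_hairpin(random_mature(), params, seed=8)
        st = duplex_stats(s, truth.mir_span, truth.star_span)
        assert st.n_mismatch == 3 and st.n_asym == 0
        assert st.mismatch_positions == (5, 9, 14)

    def test_two_nt_star_bulge(self, random_mature):
        params = HairpinParams(bulges=((10, 2, "star"),))
        _, s, truth = make_hairpin(random_mature(), params, seed=8)
        st = duplex_stats(s, truth.mir_span, truth.star_span)
        assert st.n_asym == 2 and st.n_mismatch == 2

    def test_generator_truth_recovered_over_500_parameterizations(self, rng):
        """duplex_stats recovers the planted duplex parameters exactly."""
        checked = 0
        while checked < 500:
            mature = "".join(rng.choice(list("ACGU"), int(rng.integers(20, 25))))
            Lm = len(mature)
            o_mir = int(rng.integers(0, 4))
            hi = Lm - o_mir - 1
            n_mm = int(rng.integers(0, 4))
            interior = np.arange(2, hi)
            if len(interior) < n_mm + 2:
                continue
            mm = tuple(sorted(int(x) for x in rng.choice(interior, n_mm, replace=False)))
            bulges = ()
            free = [p for p in interior if p not in mm and p + 1 not in mm and p - 1 not in mm]
            if free and rng.random() < 0.6:
                pos = int(rng.choice(free))
                size = int(rng.integers(1, 4))
                side = "star" if rng.random() < 0.5 else "mir"
                if side == "mir" and pos + size > hi:
                    side = "star"
                if all(abs(pos + k - m) > 0 for k in range(size) for m in mm):
                    bulges = ((pos, size, side),)
            try:
                params = HairpinParams(
                    loop_size=int(rng.integers(3, 12)),
                    ext_stem=int(rng.integers(0, 12)),
                    mismatch_positions=mm,
                    bulges=bulges,
                    overhang_mir=o_mir,
                    overhang_star=int(rng.integers(0, 4)),
                    arm="5p" if rng.random() < 0.5 else "3p",
                )
                _, s, truth = make_hairpin(mature, params, seed=int(rng.integers(2**31)))
            except ValueError:
                continue
            st = duplex_stats(s, truth.mir_span, truth.star_span)
            assert st.n_mismatch == truth.n_mismatch
            assert st.n_asym == truth.n_asym
            assert st.largest_loop == truth.largest_loop
            assert st.overhang_5p_side == truth.overhang_5p_side
            assert st.overhang_3p_side == truth.overhang_3p_side
            assert st.mir_len == truth.mir_len
            assert st.star_len == truth.star_len
            assert st.precursor_len == truth.precursor_len
            assert not st.secondary_stem
            checked += 1


class TestApplyRules:
    def _stats(self, random_mature, params, seed=10):
        _, s, truth = make_hairpin(random_mature(), params, seed=seed)
        return duplex_stats(s, truth.mir_span, truth.star_span), s, truth

    def test_clean_duplex_accepted(self, random_mature):
        st, *_ = self._stats(random_mature, HairpinParams())
        assert apply_rules(st).accepted

    def test_seven_mismatches_rejected(self, random_mature):
        st, *_ = self._stats(
            random_mature, HairpinParams(mismatch_positions=(3, 5, 7, 9, 11, 13, 15))
        )
        v = apply_rules(st)
        assert v.violated == ("mismatch_limit",)

    def test_four_asymmetric_nucleotides_rejected(self, random_mature):
        st, *_ = self._stats(random_mature, HairpinParams(bulges=((9, 4, "star"),)))
        v = apply_rules(st)
        assert v.violated == ("asym_limit",)

    def test_precursor_over_300_rejected(self, random_mature):
        st, *_ = self._stats(random_mature, HairpinParams(loop_size=259))
        assert st.precursor_len == 301
        assert apply_rules(st).violated == ("precursor_length",)
        st300, *_ = self._stats(random_mature, HairpinParams(loop_size=258))
        assert st300.precursor_len == 300
        assert apply_rules(st300).accepted

    def test_mature_length_bounds(self, rng):
        for n, ok in ((19, False), (20, True), (24, True), (25, False)):
            mature = "".join(rng.choice(list("ACGU"), n))
            _, s, truth = make_hairpin(mature, HairpinParams(), seed=11)
            v = apply_rules(duplex_stats(s, truth.mir_span, truth.star_span))
            assert v.accepted == ok
            if not ok:
                assert v.violated == ("mature_length",)

    def test_blunt_duplex_rejected_on_overhang(self, random_mature):
        st, *_ = self._stats(
            random_mature, HairpinParams(overhang_mir=0, overhang_star=0)
        )
        assert apply_rules(st).violated == ("overhang",)

    def test_secondary_stem_rejected(self):
        """A declared duplex whose complementary region carries a foreign
        helix is flagged as containing secondary stems."""
        db = TestDisqualify.BRANCHED
        s = from_dot_bracket("G" * len(db), db)
        mir_span = (3, 23)
        star_span = infer_star(s, mir_span)
        st = duplex_stats(s, mir_span, star_span)
        assert st.secondary_stem
        assert "secondary_stem" in apply_rules(st).violated

    def test_banned_mismatch_positions(self, random_mature):
        st, *_ = self._stats(random_mature, HairpinParams(mismatch_positions=(10,)))
        cfg = RuleConfig(banned_mismatch_positions=(9, 10, 11))
        assert apply_rules(st, cfg).violated == ("banned_position",)
        assert apply_rules(st).accepted  # no ban by default
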