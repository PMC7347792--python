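"""The interpretation rules on the canonical worlds, plus cross-rule invariants."""

from fractions import Fraction

import pytest

from genalt.fixtures import parse_random_world_spec
from genalt.semantics import (
    GenericStatement,
    assertability,
    causal_verdict,
    homogeneity_check,
    informativity_check,
    majority_verdict,
    relative_verdict,
    restricted_majority_verdict,
)
from genalt.specio import parse_world_spec
from genalt.worldmodel import cond_prob, prob


def statement(worlds, name):
    ws = worlds[name]
    return ws.world, next(iter(ws.statements.values()))


class TestMajority:
    def test_rare_feature_generic_false_on_majority(self, worlds):
        w, s = statement(worlds, "mosquito")
        v = majority_verdict(w, s)
        assert v.truth is False
        assert v.quantities["P(f|G)"] == Fraction(1, 100)

    def test_common_feature_generic_true_on_majority(self, worlds):
        w, s = statement(worlds, "chicken")
        v = majority_verdict(w, s)
        assert v.truth is True
        assert v.quantities["P(f|G)"] == Fraction(4, 5)

    def test_exact_half_is_false_by_strictness(self):
        ws = parse_world_spec({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"]},
            "atoms": [
                {"assignment": {"g": "yes", "f": "yes"}, "weight": 1},
                {"assignment": {"g": "yes", "f": "no"}, "weight": 1},
                {"assignment": {"g": "no", "f": "no"}, "weight": 2},
            ],
            "events": {"G": {"g": "yes"}, "f": {"f": "yes"}},
            "statements": {"s": {"group": "G", "feature": "f"}},
        })
        assert majority_verdict(ws.world, ws.statements["s"]).truth is False

    def test_zero_probability_group_is_inapplicable(self):
        ws = parse_world_spec({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"]},
            "atoms": [{"assignment": {"g": "no", "f": "no"}, "weight": 1},
                      {"assignment": {"g": "yes", "f": "yes"}, "weight": 0}],
            "events": {"G": {"g": "yes"}, "f": {"f": "yes"}},
            "statements": {"s": {"group": "G", "feature": "f"}},
        })
        v = majority_verdict(ws.world, ws.statements["s"])
        assert not v.applicable and v.truth is None


class TestRestrictedMajority:
    def test_domain_restriction_rescues_below_half_generic(self, worlds):
        # below majority overall, 0.9 among animals with some reproduction mode
        w, s = statement(worlds, "ducks")
        assert majority_verdict(w, s).truth is False
        v = restricted_majority_verdict(w, s)
        assert v.truth is True
        assert v.quantities["P(f|G∩∪Alt(f))"] == Fraction(9, 10)

    def test_full_coverage_alternatives_reduce_to_majority(self, worlds):
        w, s = statement(worlds, "chicken")
        covering = GenericStatement(group=s.group, feature=s.feature,
                                    alt_features=(w.full_event(),))
        assert (restricted_majority_verdict(w, covering).truth
                == majority_verdict(w, s).truth)

    def test_majority_true_but_uninformative(self, worlds):
        # majority of books are paperbacks, yet the claim is infelicitous
        w, s = statement(worlds, "books")
        assert restricted_majority_verdict(w, s).truth is True
        assert informativity_check(w, s).truth is False


class TestRelative:
    def test_small_minority_can_still_be_distinctive(self, worlds):
        w, s = statement(worlds, "dutch_sailors")
        v = relative_verdict(w, s)
        assert v.truth is True
        assert v.quantities["P(f|G)"] == Fraction(1, 10) < Fraction(1, 2)

    def test_equal_conditionals_are_false(self):
        ws = parse_world_spec({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"]},
            "factored": {"group_var": "g",
                         "group_marginal": {"yes": "1/2", "no": "1/2"},
                         "feature_var": "f", "feature_value": "yes",
                         "feature_prob": {"yes": "3/10", "no": "3/10"}},
            "events": {"G": {"g": "yes"}, "altG": {"g": "no"}, "f": {"f": "yes"}},
            "statements": {"s": {"group": "G", "feature": "f",
                                 "alt_groups": ["altG"]}},
        })
        assert relative_verdict(ws.world, ws.statements["s"]).truth is False

    def test_no_alternatives_is_inapplicable(self, worlds):
        w, s = statement(worlds, "books")
        v = relative_verdict(w, s)
        assert not v.applicable

    def test_binary_alternative_agrees_with_marginal_comparison(self, rng):
        # with Alt(G) = not-G the relative verdict tracks sign(P(f|G) - P(f))
        checked = 0
        while checked < 100:
            ws = parse_random_world_spec(rng)
            w, s = ws.world, ws.statements["s"]
            if not (0 < prob(w, s.group) < 1):
                continue
            v = relative_verdict(w, s)
            marginal = cond_prob(w, s.feature, s.group) - prob(w, s.feature)
            assert v.truth == (marginal > 0)
            checked += 1

    def test_per_alternative_mode_requires_every_inequality(self):
        ws = parse_world_spec({
            "variables": {"g": ["a", "b", "c"], "f": ["yes", "no"]},
            "factored": {"group_var": "g",
                         "group_marginal": {"a": "1/3", "b": "1/3", "c": "1/3"},
                         "feature_var": "f", "feature_value": "yes",
                         "feature_prob": {"a": "1/2", "b": "1/4", "c": "3/4"}},
            "events": {"G": {"g": "a"}, "B": {"g": "b"}, "C": {"g": "c"},
                       "f": {"f": "yes"}},
            "statements": {"s": {"group": "G", "feature": "f",
                                 "alt_groups": ["B", "C"]}},
        })
        w, s = ws.world, ws.statements["s"]
        # pooled alternative: P(f|B or C) = 1/2 == P(f|G) -> false either way,
        # per-alternative fails on C (3/4 > 1/2)
        assert relative_verdict(w, s, mode="per_alternative").truth is False
        v = relative_verdict(w, s, mode="pooled")
        assert v.truth is False


class TestCausal:
    def test_confounded_generic_splits_evidential_and_causal(self, worlds):
        # strong evidential contrast, weak causal impact within background cells
        w, s = statement(worlds, "mandarin")
        assert relative_verdict(w, s).truth is True
        v = causal_verdict(w, s, tau=0.2)
        assert v.truth is False
        assert v.degree == pytest.approx(0.1, abs=1e-12)

    def test_single_background_cell_reduces_to_relative_comparison(self, rng):
        checked = 0
        while checked < 50:
            ws = parse_random_world_spec(rng, n_background=1)
            w, s = ws.world, ws.statements["s"]
            if not (0 < prob(w, s.group) < 1):
                continue
            v = causal_verdict(w, s, tau=0.0)
            if not v.applicable:
                continue
            rel_diff = (cond_prob(w, s.feature, s.group)
                        - cond_prob(w, s.feature, ~s.group))
            assert abs(v.degree - rel_diff) < 1e-12
            checked += 1

    def test_skyrms_condition_can_veto(self, worlds):
        # build a world where the average difference is large but one cell flips
        ws = parse_world_spec({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"], "b": ["b0", "b1"]},
            "atoms": [
                {"assignment": {"g": "yes", "f": "yes", "b": "b0"}, "weight": 9},
                {"assignment": {"g": "yes", "f": "no", "b": "b0"}, "weight": 1},
                {"assignment": {"g": "no", "f": "yes", "b": "b0"}, "weight": 1},
                {"assignment": {"g": "no", "f": "no", "b": "b0"}, "weight": 9},
                {"assignment": {"g": "yes", "f": "yes", "b": "b1"}, "weight": 1},
                {"assignment": {"g": "yes", "f": "no", "b": "b1"}, "weight": 9},
                {"assignment": {"g": "no", "f": "yes", "b": "b1"}, "weight": 2},
                {"assignment": {"g": "no", "f": "no", "b": "b1"}, "weight": 8},
            ],
            "events": {"G": {"g": "yes"}, "f": {"f": "yes"}},
            "statements": {"s": {"group": "G", "feature": "f",
                                 "background_var": "b"}},
        })
        w, s = ws.world, ws.statements["s"]
        assert causal_verdict(w, s, tau=0.2).truth is True
        assert causal_verdict(w, s, tau=0.2, require_skyrms=True).truth is False


class TestAssertability:
    def test_contrastive_stimulus_degree(self, rng):
        from genalt.experiment import build_stimulus, stimulus_to_world
        w = stimulus_to_world(build_stimulus(0.8, 25, "contrastive"))
        s = GenericStatement(group=w.event_eq("island", "target"),
                             feature=w.event_eq("feature", "yes"),
                             alt_groups=(w.event_eq("island", "alt"),))
        v = assertability(w, s)
        assert v.degree == Fraction(4, 5)
        assert v.quantities["mode"] == "contingency"

    def test_empty_alternatives_collapse_to_marginal(self):
        from genalt.experiment import build_stimulus, stimulus_to_world
        w = stimulus_to_world(build_stimulus(0.8, 25, "contrastive"))
        s = GenericStatement(group=w.event_eq("island", "target"),
                             feature=w.event_eq("feature", "yes"))
        v = assertability(w, s)
        assert v.degree == Fraction(4, 5)
        assert v.quantities["mode"] == "marginal"

    def test_antisymmetric_under_group_swap(self, rng):
        checked = 0
        while checked < 100:
            ws = parse_random_world_spec(rng)
            w, s = ws.world, ws.statements["s"]
            fwd = assertability(w, s)
            swapped = GenericStatement(group=s.alt_groups[0], feature=s.feature,
                                       alt_groups=(s.group,))
            bwd = assertability(w, swapped)
            if not (fwd.applicable and bwd.applicable):
                continue
            assert fwd.degree == pytest.approx(-bwd.degree, abs=1e-12)
            checked += 1

    def test_positive_degree_iff_relative_verdict(self, rng):
        checked = 0
        while checked < 100:
            ws = parse_random_world_spec(rng)
            w, s = ws.world, ws.statements["s"]
            v_rel = relative_verdict(w, s)
            v_ast = assertability(w, s)
            if not (v_rel.applicable and v_ast.applicable):
                continue
            assert v_rel.truth == (v_ast.degree > 0)
            checked += 1


class TestSideConditions:
    def test_feature_entailed_by_group_is_infelicitous(self, worlds):
        w, s = statement(worlds, "books")
        assert informativity_check(w, s).truth is False

    def test_feature_available_outside_group_is_felicitous(self, worlds):
        w, s = statement(worlds, "birds")
        # non-birds can fly in this world, so the claim is informative
        s2 = GenericStatement(group=s.group, feature=s.feature,
                              alt_features=(s.feature,))
        assert informativity_check(w, s2).truth is True

    def test_caste_partition_breaks_homogeneity(self, worlds):
        w, s = statement(worlds, "bees")
        assert majority_verdict(w, s).truth is True
        v = homogeneity_check(w, s, theta=0.5)
        assert v.truth is False
        assert v.quantities["workers"] > Fraction(1, 2)
        assert v.quantities["queens"] < Fraction(1, 2)

    def test_penguin_partition_breaks_homogeneity(self, worlds):
        w, s = statement(worlds, "birds")
        assert homogeneity_check(w, s).truth is False

    def test_uniform_partition_passes(self):
        ws = parse_world_spec({
            "variables": {"g": ["a", "b", "no"], "f": ["yes", "no"]},
            "atoms": [
                {"assignment": {"g": "a", "f": "yes"}, "weight": 1},
                {"assignment": {"g": "b", "f": "yes"}, "weight": 1},
                {"assignment": {"g": "no", "f": "no"}, "weight": 2},
            ],
            "events": {"G": {"g": ["a", "b"]}, "f": {"f": "yes"},
                       "Ga": {"g": "a"}, "Gb": {"g": "b"}},
            "statements": {"s": {"group": "G", "feature": "f",
                                 "group_partition": ["Ga", "Gb"]}},
        })
        v = homogeneity_check(ws.world, ws.statements["s"], theta=0.99)
        assert v.truth is True
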