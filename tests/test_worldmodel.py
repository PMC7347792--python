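"""World construction and the probability operators, checked against
exhaustive atom enumeration on small random worlds."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genalt.fixtures import random_world
from genalt.worldmodel import (
    UndefinedIntervention,
    WorldError,
    ZeroProbabilityCondition,
    cond_prob,
    contingency,
    do_prob,
    make_world,
    prob,
    total_probability_check,
)


def stimulus_world(p_target=Fraction(4, 5), p_alt=Fraction(0)):
    return make_world({
        "variables": {"island": ["target", "alt"], "feature": ["yes", "no"]},
        "atoms": [
            {"assignment": {"island": "target", "feature": "yes"},
             "weight": p_target * 25},
            {"assignment": {"island": "target", "feature": "no"},
             "weight": (1 - p_target) * 25},
            {"assignment": {"island": "alt", "feature": "yes"},
             "weight": p_alt * 25},
            {"assignment": {"island": "alt", "feature": "no"},
             "weight": (1 - p_alt) * 25},
        ],
    })


class TestMakeWorld:
    def test_contrastive_stimulus_probabilities_are_exact(self):
        w = stimulus_world()
        f = w.event_eq("feature", "yes")
        assert cond_prob(w, f, w.event_eq("island", "target")) == Fraction(4, 5)
        assert cond_prob(w, f, w.event_eq("island", "alt")) == 0

    def test_single_outcome_world_is_degenerate(self):
        w = make_world({
            "variables": {"x": ["a", "b"]},
            "atoms": [{"assignment": {"x": "a"}, "weight": 1}],
        })
        assert prob(w, w.event_eq("x", "a")) == 1
        assert prob(w, w.event_eq("x", "b")) == 0

    def test_factored_spec_equals_enumerated_atoms(self):
        factored = make_world({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"]},
            "factored": {
                "group_var": "g",
                "group_marginal": {"yes": "1/4", "no": "3/4"},
                "feature_var": "f", "feature_value": "yes",
                "feature_prob": {"yes": "4/5", "no": "1/10"},
            },
        })
        enumerated = make_world({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"]},
            "atoms": [
                {"assignment": {"g": "yes", "f": "yes"}, "weight": "1/5"},
                {"assignment": {"g": "yes", "f": "no"}, "weight": "1/20"},
                {"assignment": {"g": "no", "f": "yes"}, "weight": "3/40"},
                {"assignment": {"g": "no", "f": "no"}, "weight": "27/40"},
            ],
        })
        for g in ("yes", "no"):
            for f in ("yes", "no"):
                e1 = factored.event_eq("g", g) & factored.event_eq("f", f)
                e2 = enumerated.event_eq("g", g) & enumerated.event_eq("f", f)
                assert prob(factored, e1) == prob(enumerated, e2)

    @pytest.mark.parametrize("bad, match", [
        ({"variables": {"x": ["a"]},
          "atoms": [{"assignment": {"x": "a"}, "weight": 1},
                    {"assignment": {"x": "a"}, "weight": 1}]}, "same full assignment"),
        ({"variables": {"x": ["a"]},
          "atoms": [{"assignment": {"x": "a"}, "weight": -1}]}, "negative"),
        ({"variables": {"x": ["a"]},
          "atoms": [{"assignment": {"x": "a", "y": "b"}, "weight": 1}]}, "undeclared"),
        ({"variables": {"x": ["a"]},
          "atoms": [{"assignment": {"x": "a"}, "weight": 1}],
          "bogus": 1}, "unknown"),
    ])
    def test_malformed_specs_raise(self, bad, match):
        with pytest.raises(WorldError, match=match):
            make_world(bad)


class TestOperatorsAgainstEnumeration:
    def test_prob_and_cond_prob_match_atom_sums(self, rng):
        for _ in range(50):
            w = random_world(rng)
            g = w.event_eq("g", "yes")
            f = w.event_eq("f", "yes")
            total = sum(w.weights)
            brute_f = sum(w.weights[i] for i in f.indices) / total
            assert prob(w, f) == pytest.approx(brute_f, abs=1e-12)
            pg = sum(w.weights[i] for i in g.indices) / total
            if pg > 0:
                brute = sum(w.weights[i] for i in (f & g).indices) / total / pg
                assert cond_prob(w, f, g) == pytest.approx(brute, abs=1e-12)

    def test_full_and_empty_events(self, rng):
        w = random_world(rng)
        assert prob(w, w.full_event()) == pytest.approx(1.0, abs=1e-12)
        assert prob(w, w.empty_event()) == 0

    def test_conditioning_on_zero_event_raises_typed_error(self):
        w = stimulus_world()
        zero = w.event_eq("island", "alt") & w.event_eq("feature", "yes")
        with pytest.raises(ZeroProbabilityCondition):
            cond_prob(w, w.event_eq("feature", "yes"), zero)

    def test_self_conditioning_is_one(self, rng):
        w = random_world(rng, allow_zero_atoms=False)
        g = w.event_eq("g", "yes")
        assert cond_prob(w, g, g) == pytest.approx(1.0, abs=1e-12)


class TestContingency:
    def test_contrastive_stimulus_contingency(self):
        w = stimulus_world()
        c = contingency(w, w.event_eq("feature", "yes"),
                        w.event_eq("island", "target"), w.event_eq("island", "alt"))
        assert c == Fraction(4, 5)

    def test_non_contrastive_contingency_is_zero(self):
        w = stimulus_world(p_alt=Fraction(4, 5))
        c = contingency(w, w.event_eq("feature", "yes"),
                        w.event_eq("island", "target"), w.event_eq("island", "alt"))
        assert c == 0

    def test_prior_alternative_contingency(self):
        # target at 0.8 against an alternative sample at 0.15
        w = stimulus_world(p_alt=Fraction(3, 20))
        c = contingency(w, w.event_eq("feature", "yes"),
                        w.event_eq("island", "target"), w.event_eq("island", "alt"))
        assert c == Fraction(13, 20)


class TestDoProb:
    def test_single_cell_reduces_to_cond_prob(self):
        w = make_world({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"], "b": ["b0"]},
            "atoms": [
                {"assignment": {"g": g, "f": f, "b": "b0"}, "weight": wgt}
                for (g, f), wgt in zip(
                    [("yes", "yes"), ("yes", "no"), ("no", "yes"), ("no", "no")],
                    [3, 1, 1, 3])
            ],
        })
        g, f = w.event_eq("g", "yes"), w.event_eq("f", "yes")
        assert do_prob(w, f, g, "b") == cond_prob(w, f, g)

    def test_independent_background_collapses_to_cond_prob(self, rng):
        # product world: cause independent of the background cells
        pg, pb = 0.3, 0.6
        pf = {("yes", "b0"): 0.9, ("yes", "b1"): 0.4,
              ("no", "b0"): 0.2, ("no", "b1"): 0.7}
        atoms = []
        for g in ("yes", "no"):
            for b in ("b0", "b1"):
                for f in ("yes", "no"):
                    w0 = ((pg if g == "yes" else 1 - pg)
                          * (pb if b == "b0" else 1 - pb)
                          * (pf[(g, b)] if f == "yes" else 1 - pf[(g, b)]))
                    atoms.append({"assignment": {"g": g, "f": f, "b": b},
                                  "weight": w0})
        w = make_world({"variables": {"g": ["yes", "no"], "f": ["yes", "no"],
                                      "b": ["b0", "b1"]}, "atoms": atoms})
        g, f = w.event_eq("g", "yes"), w.event_eq("f", "yes")
        assert abs(do_prob(w, f, g, "b") - cond_prob(w, f, g)) < 1e-12

    def test_confounded_world_matches_hand_summation(self):
        # exact rational confounded world: the adjustment differs from
        # conditioning and equals the term-by-term sum
        spec = {"variables": {"g": ["yes", "no"], "f": ["yes", "no"],
                              "b": ["b0", "b1"]}, "atoms": []}
        weights = {  # (g, f, b) -> weight
            ("yes", "yes", "b0"): 9, ("yes", "no", "b0"): 1,
            ("yes", "yes", "b1"): 1, ("yes", "no", "b1"): 1,
            ("no", "yes", "b0"): 2, ("no", "no", "b0"): 2,
            ("no", "yes", "b1"): 1, ("no", "no", "b1"): 15,
        }
        for (g, f, b), wgt in weights.items():
            spec["atoms"].append({"assignment": {"g": g, "f": f, "b": b},
                                  "weight": wgt})
        w = make_world(spec)
        g, f = w.event_eq("g", "yes"), w.event_eq("f", "yes")
        # hand computation: P(b0)=14/32, P(b1)=18/32,
        # P(f|g,b0)=9/10, P(f|g,b1)=1/2
        expected = Fraction(9, 10) * Fraction(14, 32) + Fraction(1, 2) * Fraction(18, 32)
        assert do_prob(w, f, g, "b") == expected
        assert do_prob(w, f, g, "b") != cond_prob(w, f, g)

    def test_empty_cell_raises_unless_dropped(self):
        w = make_world({
            "variables": {"g": ["yes", "no"], "f": ["yes", "no"], "b": ["b0", "b1"]},
            "atoms": [
                {"assignment": {"g": "yes", "f": "yes", "b": "b0"}, "weight": 1},
                {"assignment": {"g": "no", "f": "no", "b": "b1"}, "weight": 1},
                {"assignment": {"g": "no", "f": "yes", "b": "b0"}, "weight": 1},
            ],
        })
        g, f = w.event_eq("g", "yes"), w.event_eq("f", "yes")
        with pytest.raises(UndefinedIntervention):
            do_prob(w, f, g, "b")
        assert do_prob(w, f, g, "b", drop_empty_cells=True) == 1


class TestInvariants:
    def test_normalization(self, rng):
        for _ in range(20):
            w = random_world(rng)
            assert abs(sum(w.atom_probability(i) for i in range(w.n_atoms)) - 1) < 1e-12

    def test_total_probability_for_all_partitions(self, rng):
        for _ in range(50):
            w = random_world(rng)
            f, g = w.event_eq("f", "yes"), w.event_eq("g", "yes")
            if prob(w, g) == 0:
                continue
            for var in ("b", "g", "f"):
                lhs, rhs = total_probability_check(w, f, g, var)
                assert abs(lhs - rhs) < 1e-12

    def test_relative_reading_equivalence_theorem(self, rng):
        # sign(P(f|G) - P(f)) == sign(P(f|G) - P(f|not G)) whenever 0<P(G)<1
        checked = 0
        while checked < 500:
            w = random_world(rng)
            g, f = w.event_eq("g", "yes"), w.event_eq("f", "yes")
            pg = prob(w, g)
            if not (0 < pg < 1):
                continue
            lhs = cond_prob(w, f, g) - prob(w, f)
            rhs = cond_prob(w, f, g) - cond_prob(w, f, ~g)
            assert np.sign(lhs) == np.sign(rhs)
            checked += 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=20), min_size=8,
                    max_size=8).filter(lambda ws: sum(ws) > 0))
    def test_total_probability_exact_on_rational_worlds(self, ws):
        spec = {"variables": {"g": ["yes", "no"], "f": ["yes", "no"],
                              "b": ["b0", "b1"]}, "atoms": []}
        i = 0
        for g in ("yes", "no"):
            for f in ("yes", "no"):
                for b in ("b0", "b1"):
                    spec["atoms"].append(
                        {"assignment": {"g": g, "f": f, "b": b}, "weight": ws[i]})
                    i += 1
        w = make_world(spec)
        g, f = w.event_eq("g", "yes"), w.event_eq("f", "yes")
        if prob(w, g) == 0:
            return
        lhs, rhs = total_probability_check(w, f, g, "b")
        assert lhs == rhs  # exact Fraction arithmetic
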