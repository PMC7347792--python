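"""Canonical worlds, environments and demo tables used across the suite.

The worlds encode the stock examples of the generics literature as small
exact joint distributions: the rare-but-true generic (mosquitoes carrying a
virus), the common-but-false one (chicken being female), the confounded one
(Chinese speaking Mandarin, confounded by living in China), the homogeneity
failures (sterile bees, flying birds vs. penguins), the informativity
failure (books being paperbacks) and the domain-restriction case (ducks
laying eggs).  Each builder returns a :class:`~genalt.specio.WorldSpec`
whose named statement is ready for the interpretation rules.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment import scale_from_contingency
from .specio import WorldSpec, parse_world_spec
from .worldmodel import World

__all__ = [
    "mosquito_world",
    "chicken_world",
    "mandarin_world",
    "bees_world",
    "birds_world",
    "books_world",
    "ducks_world",
    "dutch_sailors_world",
    "canonical_world_specs",
    "single_cue_environment_spec",
    "contingency_environment_spec",
    "alternative_sets_table",
    "random_world",
    "generate_fixtures",
]


def _two_group_feature_spec(group_var, groups, feature_var, feature_value,
                            other_value, marginal, feature_prob, statement):
    values = [feature_value, other_value]
    return {
        "variables": {group_var: list(groups), feature_var: values},
        "factored": {
            "group_var": group_var,
            "group_marginal": {g: str(marginal[g]) for g in groups},
            "feature_var": feature_var,
            "feature_value": feature_value,
            "feature_prob": {g: str(feature_prob[g]) for g in groups},
        },
        "events": {
            "G": {group_var: groups[0]},
            "altG": {group_var: groups[1]},
            "f": {feature_var: feature_value},
        },
        "statements": {
            statement: {"group": "G", "feature": "f", "alt_groups": ["altG"]},
        },
    }


def mosquito_world() -> WorldSpec:
    """Rare feature, strong contrast: P(carrier|mosquito)=0.01, others 0.0001."""
    return parse_world_spec(_two_group_feature_spec(
        "kind", ("mosquito", "other_insect"), "carrier", "yes", "no",
        {"mosquito": Fraction(1, 5), "other_insect": Fraction(4, 5)},
        {"mosquito": Fraction(1, 100), "other_insect": Fraction(1, 10000)},
        "mosquitoes_carry_virus"))


def chicken_world() -> WorldSpec:
    """High conditional probability, no contrast: P(female|chicken)=0.8."""
    return parse_world_spec(_two_group_feature_spec(
        "kind", ("chicken", "other_bird"), "sex", "female", "male",
        {"chicken": Fraction(1, 2), "other_bird": Fraction(1, 2)},
        {"chicken": Fraction(4, 5), "other_bird": Fraction(1, 2)},
        "chicken_are_female"))


def dutch_sailors_world() -> WorldSpec:
    """Relative reading: P(good sailor|Dutch)=0.1 vs 0.02 for the alternatives."""
    return parse_world_spec(_two_group_feature_spec(
        "nationality", ("dutch", "other"), "good_sailor", "yes", "no",
        {"dutch": Fraction(1, 10), "other": Fraction(9, 10)},
        {"dutch": Fraction(1, 10), "other": Fraction(1, 50)},
        "dutchmen_are_good_sailors"))


def mandarin_world() -> WorldSpec:
    """Confounded world: speaking Mandarin, confounded by living in China.

    Being Chinese is strongly evidentially relevant for speaking Mandarin
    (P(M|C) ≈ 0.91 vs P(M|¬C) ≈ 0.06) yet the cellwise differences within
    the causal background partition {lives in China, doesn't} are small
    (0.10), so the causal reading fails at any threshold above 0.1 while
    the relative reading holds.
    """
    p_c = Fraction(1, 5)
    p_b_given = {"yes": Fraction(19, 20), "no": Fraction(1, 100)}  # P(in_china|chinese)
    p_m = {  # P(mandarin | chinese, in_china)
        ("yes", "yes"): Fraction(19, 20),
        ("no", "yes"): Fraction(17, 20),
        ("yes", "no"): Fraction(3, 20),
        ("no", "no"): Fraction(1, 20),
    }
    atoms = []
    for c in ("yes", "no"):
        pc = p_c if c == "yes" else 1 - p_c
        for b in ("yes", "no"):
            pb = p_b_given[c] if b == "yes" else 1 - p_b_given[c]
            for m in ("yes", "no"):
                pm = p_m[(c, b)] if m == "yes" else 1 - p_m[(c, b)]
                atoms.append({"assignment": {"chinese": c, "in_china": b,
                                             "mandarin": m},
                              "weight": str(pc * pb * pm)})
    return parse_world_spec({
        "variables": {"chinese": ["yes", "no"], "in_china": ["yes", "no"],
                      "mandarin": ["yes", "no"]},
        "atoms": atoms,
        "events": {"G": {"chinese": "yes"}, "altG": {"chinese": "no"},
                   "f": {"mandarin": "yes"}},
        "statements": {
            "chinese_speak_mandarin": {
                "group": "G", "feature": "f", "alt_groups": ["altG"],
                "background_var": "in_china",
            },
        },
    })


def bees_world() -> WorldSpec:
    """Sterility among bees: true of workers only; homogeneity fails.

    Castes: 1% queens (fertile), 94% workers (sterile), 5% drones (fertile);
    overall P(sterile|bee) ≈ 0.93 but neither queens nor drones tend to be
    sterile.
    """
    caste = {"queen": Fraction(1, 100), "worker": Fraction(94, 100),
             "drone": Fraction(5, 100)}
    sterile = {"queen": Fraction(1, 100), "worker": Fraction(99, 100),
               "drone": Fraction(1, 100)}
    atoms = []
    for kind in ("bee", "other_insect"):
        pk = Fraction(1, 10) if kind == "bee" else Fraction(9, 10)
        for c, pc in caste.items():
            for s in ("yes", "no"):
                if kind == "other_insect":
                    ps = Fraction(1, 100) if s == "yes" else Fraction(99, 100)
                else:
                    ps = sterile[c] if s == "yes" else 1 - sterile[c]
                atoms.append({"assignment": {"kind": kind, "caste": c, "sterile": s},
                              "weight": str(pk * pc * ps)})
    return parse_world_spec({
        "variables": {"kind": ["bee", "other_insect"],
                      "caste": ["queen", "worker", "drone"],
                      "sterile": ["yes", "no"]},
        "atoms": atoms,
        "events": {
            "G": {"kind": "bee"}, "altG": {"kind": "other_insect"},
            "f": {"sterile": "yes"},
            "queens": {"kind": "bee", "caste": "queen"},
            "workers": {"kind": "bee", "caste": "worker"},
            "drones": {"kind": "bee", "caste": "drone"},
        },
        "statements": {
            "bees_are_sterile": {
                "group": "G", "feature": "f", "alt_groups": ["altG"],
                "group_partition": ["queens", "workers", "drones"],
            },
        },
    })


def birds_world() -> WorldSpec:
    """Birds fly; the {penguins, other birds} partition breaks homogeneity."""
    atoms = []
    spec = {  # (share within world, P(fly))
        "penguin": (Fraction(1, 50), Fraction(0)),
        "other_bird": (Fraction(39, 50), Fraction(19, 20)),
        "nonbird": (Fraction(10, 50), Fraction(1, 100)),  # bats, insects
    }
    for kind, (pk, pf) in spec.items():
        for f in ("yes", "no"):
            w = pk * (pf if f == "yes" else 1 - pf)
            atoms.append({"assignment": {"kind": kind, "flies": f},
                          "weight": str(w)})
    return parse_world_spec({
        "variables": {"kind": ["penguin", "other_bird", "nonbird"],
                      "flies": ["yes", "no"]},
        "atoms": atoms,
        "events": {
            "G": {"kind": ["penguin", "other_bird"]},
            "altG": {"kind": "nonbird"},
            "f": {"flies": "yes"},
            "penguins": {"kind": "penguin"},
            "other_birds": {"kind": "other_bird"},
        },
        "statements": {
            "birds_fly": {
                "group": "G", "feature": "f", "alt_groups": ["altG"],
                "group_partition": ["penguins", "other_birds"],
            },
        },
    })


def books_world() -> WorldSpec:
    """Books are paperbacks: majority true but uninformative (∪Alt(f) ⊆ G)."""
    atoms = [
        {"assignment": {"thing": "book", "format": "paperback"}, "weight": 60},
        {"assignment": {"thing": "book", "format": "hardcover"}, "weight": 40},
        {"assignment": {"thing": "other", "format": "none"}, "weight": 100},
    ]
    return parse_world_spec({
        "variables": {"thing": ["book", "other"],
                      "format": ["paperback", "hardcover", "none"]},
        "atoms": atoms,
        "events": {
            "G": {"thing": "book"},
            "f": {"format": "paperback"},
            "hardcovers": {"format": "hardcover"},
        },
        "statements": {
            "books_are_paperbacks": {
                "group": "G", "feature": "f",
                "alt_features": ["f", "hardcovers"],
            },
        },
    })


def ducks_world() -> WorldSpec:
    """Ducks lay eggs: below majority overall, high once restricted to ∪Alt(f).

    Only 45% of ducks lay eggs (roughly the females), but among animals
    exhibiting *some* mode of reproduction (laying eggs or giving live
    birth ≈ the females) the probability is 0.9.
    """
    duck = {"lays_eggs": Fraction(45, 100), "live_birth": Fraction(5, 100),
            "none": Fraction(50, 100)}
    mammal = {"lays_eggs": Fraction(0), "live_birth": Fraction(50, 100),
              "none": Fraction(50, 100)}
    atoms = []
    for species, dist in (("duck", duck), ("mammal", mammal)):
        for repro, p in dist.items():
            atoms.append({"assignment": {"species": species, "repro": repro},
                          "weight": str(p / 2)})
    return parse_world_spec({
        "variables": {"species": ["duck", "mammal"],
                      "repro": ["lays_eggs", "live_birth", "none"]},
        "atoms": atoms,
        "events": {
            "G": {"species": "duck"},
            "altG": {"species": "mammal"},
            "f": {"repro": "lays_eggs"},
            "live_birth": {"repro": "live_birth"},
        },
        "statements": {
            "ducks_lay_eggs": {
                "group": "G", "feature": "f",
                "alt_features": ["f", "live_birth"],
                "alt_groups": ["altG"],
            },
        },
    })


def canonical_world_specs() -> dict[str, WorldSpec]:
    return {
        "mosquito": mosquito_world(),
        "chicken": chicken_world(),
        "mandarin": mandarin_world(),
        "bees": bees_world(),
        "birds": birds_world(),
        "books": books_world(),
        "ducks": ducks_world(),
        "dutch_sailors": dutch_sailors_world(),
    }


# ---------------------------------------------------------------------------
# Learning environments
# ---------------------------------------------------------------------------

def single_cue_environment_spec(p_outcome: float = 0.7) -> dict:
    """One cue always present; RW converges to P(o|c)."""
    return {"configurations": [
        {"cues": ["target"], "probability": 1.0, "outcome_prob": p_outcome},
    ]}


def contingency_environment_spec(q_target: float = 0.5,
                                 p_both: float = 0.8,
                                 p_context: float = 0.3) -> dict:
    """Context cue always present, target on a fraction ``q_target`` of trials.

    Cue competition drives the target expectation to ΔP = p_both − p_context.
    """
    return {"configurations": [
        {"cues": ["context", "target"], "probability": q_target,
         "outcome_prob": p_both},
        {"cues": ["context"], "probability": 1.0 - q_target,
         "outcome_prob": p_context},
    ]}


# ---------------------------------------------------------------------------
# Alternative-sets demo
# ---------------------------------------------------------------------------

def alternative_sets_table(p_target: float = 0.8) -> pd.DataFrame:
    """Assertability of one generic under three candidate alternative sets.

    The same 80%-featured target sample is evaluated against: all animals
    (prior feature frequency 0.0001, essentially unmoved by the pictures),
    the broader kind (prior 0.2, lowered to 0.15 by the contrastive
    picture), and only the displayed alternative sample (0 in the
    contrastive condition, equal to the target frequency otherwise).  The
    table carries the contingency degree and its 0–5 scale value per
    alternative set and condition.
    """
    p_alt = {
        "all_animals": {"contrastive": 0.0001, "non_contrastive": 0.0001},
        "broader_kind": {"contrastive": 0.15, "non_contrastive": 0.2},
        "displayed_sample": {"contrastive": 0.0, "non_contrastive": p_target},
    }
    rows = []
    for alt, per_cond in p_alt.items():
        for cond, pa in per_cond.items():
            c = p_target - pa
            rows.append({
                "alternative_set": alt,
                "condition": cond,
                "p_f_given_G": p_target,
                "p_f_given_alt": pa,
                "assertability": c,
                "scale_score": float(scale_from_contingency(c)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Random worlds for property tests
# ---------------------------------------------------------------------------

def random_world(rng: np.random.Generator, n_background: int = 2,
                 allow_zero_atoms: bool = True) -> World:
    """Random small world over (g, f, b) for enumeration-oracle properties."""
    variables = {
        "g": ["yes", "no"],
        "f": ["yes", "no"],
        "b": [f"b{i}" for i in range(n_background)],
    }
    atoms = []
    for g in variables["g"]:
        for f in variables["f"]:
            for b in variables["b"]:
                w = float(rng.random())
                if allow_zero_atoms and rng.random() < 0.15:
                    w = 0.0
                atoms.append({"assignment": {"g": g, "f": f, "b": b}, "weight": w})
    if all(a["weight"] == 0 for a in atoms):
        atoms[0]["weight"] = 1.0
    return parse_world_spec({"variables": variables, "atoms": atoms}).world


def parse_random_world_spec(rng: np.random.Generator,
                            n_background: int = 2) -> WorldSpec:
    """Like :func:`random_world` but with G/f/altG events and a statement."""
    world = random_world(rng, n_background=n_background)
    # rebuild through the spec path to attach events
    data = {
        "variables": {n: list(v) for n, v in world.variables},
        "atoms": [{"assignment": dict(zip(world.variable_names, a)), "weight": w}
                  for a, w in zip(world.assignments, world.weights)],
        "events": {"G": {"g": "yes"}, "altG": {"g": "no"}, "f": {"f": "yes"}},
        "statements": {"s": {"group": "G", "feature": "f", "alt_groups": ["altG"],
                             "background_var": "b"}},
    }
    return parse_world_spec(data)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def generate_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the canonical world specs and environments as YAML files.

    The bundle is deterministic (byte-identical across runs at a fixed
    seed); returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    builders = {
        "mosquito": mosquito_world, "chicken": chicken_world,
        "mandarin": mandarin_world, "bees": bees_world, "birds": birds_world,
        "books": books_world, "ducks": ducks_world,
        "dutch_sailors": dutch_sailors_world,
    }
    # re-emit the *source* specs (not the compiled worlds) so files stay exact
    sources = {
        "mosquito": _two_group_feature_spec(
            "kind", ("mosquito", "other_insect"), "carrier", "yes", "no",
            {"mosquito": Fraction(1, 5), "other_insect": Fraction(4, 5)},
            {"mosquito": Fraction(1, 100), "other_insect": Fraction(1, 10000)},
            "mosquitoes_carry_virus"),
        "chicken": _two_group_feature_spec(
            "kind", ("chicken", "other_bird"), "sex", "female", "male",
            {"chicken": Fraction(1, 2), "other_bird": Fraction(1, 2)},
            {"chicken": Fraction(4, 5), "other_bird": Fraction(1, 2)},
            "chicken_are_female"),
    }
    for name in builders:
        spec = sources.get(name)
        if spec is None:
            # round-trip through the builder's own source dict is not kept;
            # serialise the compiled atoms exactly instead
            ws = builders[name]()
            w = ws.world
            spec = {
                "variables": {n: list(v) for n, v in w.variables},
                "atoms": [
                    {"assignment": dict(zip(w.variable_names, a)),
                     "weight": str(wt)}
                    for a, wt in zip(w.assignments, w.weights)
                ],
            }
        path = out / f"world_{name}.yaml"
        path.write_text(f"# genalt fixture world {name!r} (seed {seed})\n"
                        + yaml.safe_dump(spec, sort_keys=True))
        written.append(path)

    for name, env in (("single_cue", single_cue_environment_spec()),
                      ("context_target", contingency_environment_spec())):
        path = out / f"env_{name}.yaml"
        path.write_text(f"# genalt fixture environment {name!r} (seed {seed})\n"
                        + yaml.safe_dump(env, sort_keys=True))
        written.append(path)
    return written
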