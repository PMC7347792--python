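"""Stimulus construction and synthetic participants for the rating studies.

The studies show two samples of animals — a target group from one island and
a salient alternative group from another — and ask for the assertability of
a generic about the target group on a 0–5 slider.  Three stimulus conditions
exist: *contrastive* (none of the alternative sample carries the feature),
*non-contrastive* (equal feature proportions in both samples) and *filler*
(the queried feature appears on no animal at all; an attention check).

Synthetic participants respond by a strategy:

``con``
    rate the contingency P(f|G) − P(f|Alt(G)) through the anchored linear
    map (−1 → 0, 0 → 2.5, 1 → 5);
``nocon``
    ignore the alternative sample and rate the bare conditional probability
    P(f|G) through 5·p;
``prior_alt``
    rate the contingency against a held prior belief about P(f|Alt) (e.g.
    "frogs in general": alternative-set accounts);
``anti``
    mirror contingency, P(f|Alt(G)) − P(f|G): an extension giving the group
    of participants who rate the non-contrastive condition *higher* a
    generating strategy (the theoretical account itself provides none).

A score is the strategy's deterministic prediction plus Gaussian noise,
clamped to [0, 5].  By default the noise is a per-participant offset shared
across that participant's trials, modelling idiosyncratic scale use — the
dominant dispersion source the studies themselves point to; per-record
independent noise is available via ``noise_scope="record"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .worldmodel import World, make_world

__all__ = [
    "CONDITIONS",
    "STRATEGIES",
    "Stimulus",
    "ParticipantProfile",
    "StudyDesign",
    "STUDY_DESIGNS",
    "build_stimulus",
    "stimulus_to_world",
    "scale_from_contingency",
    "contingency_from_scale",
    "scale_from_probability",
    "predict_score",
    "simulate_study",
    "make_population",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("contrastive", "non_contrastive", "filler")
STRATEGIES = ("con", "nocon", "prior_alt", "anti")

#: The three fictive species used across the studies.
SPECIES = ("tree_frog", "hide_beetle", "jumping_spider")


@dataclass(frozen=True)
class Stimulus:
    """Two samples of animals plus the queried feature.

    ``queried_matches_displayed`` is False for fillers, whose sentence asks
    about a feature no displayed animal has.
    """

    species: str
    condition: str
    n_target: int
    k_target: int
    n_alt: int
    k_alt: int
    queried_matches_displayed: bool = True

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not (0 <= self.k_target <= self.n_target and 0 <= self.k_alt <= self.n_alt):
            raise ValueError("featured counts must lie within sample sizes")
        if self.condition == "contrastive" and self.k_alt != 0:
            raise ValueError("contrastive stimulus must have no featured alternatives")
        if self.condition == "non_contrastive" and (
                Fraction(self.k_target, self.n_target)
                != Fraction(self.k_alt, self.n_alt)):
            raise ValueError("non-contrastive stimulus needs equal featured proportions")
        if self.condition == "filler" and not self.queried_matches_displayed:
            pass  # fillers are exactly the mismatching case
        if self.condition == "filler" and self.queried_matches_displayed:
            raise ValueError("filler stimuli query a feature frequency of zero")

    @property
    def p_target(self) -> Fraction:
        """Queried-feature frequency in the target sample (0 for fillers)."""
        if not self.queried_matches_displayed:
            return Fraction(0)
        return Fraction(self.k_target, self.n_target)

    @property
    def p_alt(self) -> Fraction:
        """Queried-feature frequency in the alternative sample (0 for fillers)."""
        if not self.queried_matches_displayed:
            return Fraction(0)
        return Fraction(self.k_alt, self.n_alt)


def _round_half_up(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2))


def build_stimulus(proportion: float, n: int, condition: str,
                   species: str = "tree_frog", seed: Optional[int] = None) -> Stimulus:
    """Build a stimulus with ``round(proportion·n)`` featured target animals.

    The counts are the contract; the spatial layout of animals in a picture
    is cosmetic and ``seed`` is accepted only so callers randomising layouts
    stay reproducible.  Non-realisable proportions (54% of 25 is 13.5) are
    rounded half-up with a logged realised proportion.
    """
    del seed  # layout randomisation is cosmetic; counts carry the content
    if not (0 < proportion <= 1):
        raise ValueError(f"proportion {proportion} outside (0, 1]")
    if n < 1:
        raise ValueError("need at least one animal per sample")
    exact = Fraction(proportion).limit_denominator(10**6) * n
    k = _round_half_up(exact)
    if exact != k:
        logger.warning(
            "proportion %.4g not realisable with n=%d; rounded to %d/%d (%.4g)",
            proportion, n, k, n, k / n)
    if condition == "contrastive":
        return Stimulus(species, condition, n, k, n, 0)
    if condition == "non_contrastive":
        return Stimulus(species, condition, n, k, n, k)
    if condition == "filler":
        return Stimulus(species, condition, n, k, n, k,
                        queried_matches_displayed=False)
    raise ValueError(f"unknown condition {condition!r}")


def stimulus_to_world(stim: Stimulus) -> World:
    """Exact world over (island, feature) with one animal per unit weight.

    ``cond_prob(feature=yes, island=target)`` equals ``k_target/n_target``
    exactly — the bridge from stimulus counts to the probability operators.
    Fillers map the *queried* feature, which no animal carries.
    """
    kt = stim.k_target if stim.queried_matches_displayed else 0
    ka = stim.k_alt if stim.queried_matches_displayed else 0
    return make_world({
        "variables": {"island": ["target", "alt"], "feature": ["yes", "no"]},
        "atoms": [
            {"assignment": {"island": "target", "feature": "yes"}, "weight": kt},
            {"assignment": {"island": "target", "feature": "no"}, "weight": stim.n_target - kt},
            {"assignment": {"island": "alt", "feature": "yes"}, "weight": ka},
            {"assignment": {"island": "alt", "feature": "no"}, "weight": stim.n_alt - ka},
        ],
    })


# ---------------------------------------------------------------------------
# Scale maps
# ---------------------------------------------------------------------------

def scale_from_contingency(c):
    """Anchored affine map [−1, 1] → [0, 5]: −1 → 0, 0 → 2.5, 1 → 5."""
    if not (-1 <= c <= 1):
        raise ValueError(f"contingency {c} outside [-1, 1]")
    return 5 * (c + 1) / 2


def contingency_from_scale(s):
    """Exact inverse of :func:`scale_from_contingency`."""
    if not (0 <= s <= 5):
        raise ValueError(f"score {s} outside [0, 5]")
    return 2 * s / 5 - 1


def scale_from_probability(p):
    """Probability map [0, 1] → [0, 5]: p → 5·p (0.8 → 4)."""
    if not (0 <= p <= 1):
        raise ValueError(f"probability {p} outside [0, 1]")
    return 5 * p


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """One synthetic rater: a strategy plus a noise level.

    ``prior_alt_prob`` is required exactly for the ``prior_alt`` strategy:
    the held belief about how common the feature is among the alternatives
    the participant privately considers.
    """

    id: str
    strategy: str
    noise_sd: float = 0.0
    prior_alt_prob: Optional[float] = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if (self.prior_alt_prob is None) != (self.strategy != "prior_alt"):
            raise ValueError("prior_alt_prob required iff strategy is 'prior_alt'")
        if self.prior_alt_prob is not None and not (0 <= self.prior_alt_prob <= 1):
            raise ValueError("prior_alt_prob outside [0, 1]")


def predict_score(profile: ParticipantProfile, stim: Stimulus):
    """Noise-free score the profile's strategy assigns to the stimulus.

    Fillers ask about a feature no displayed animal has; a plainly false
    sentence is rated at the scale floor under every strategy (matching the
    near-zero filler means observed empirically), so fillers return 0
    rather than passing the zero contingency through the affine map.
    """
    if not stim.queried_matches_displayed:
        return Fraction(0)
    p_t, p_a = stim.p_target, stim.p_alt
    if profile.strategy == "nocon":
        return scale_from_probability(p_t)
    if profile.strategy == "con":
        c = p_t - p_a
    elif profile.strategy == "anti":
        c = p_a - p_t
    else:  # prior_alt
        c = p_t - Fraction(profile.prior_alt_prob).limit_denominator(10**9)
    return scale_from_contingency(c)


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Trial plan shared by the three studies.

    ``within=True``: every participant rates one contrastive, one
    non-contrastive and one filler stimulus (three species, filler last,
    experimental order randomised).  ``within=False``: one experimental
    condition plus a filler.  ``proportions`` are assigned between
    participants (round-robin over the seeded shuffle).
    """

    name: str
    proportions: tuple[float, ...]
    n_per_sample: int = 25
    within: bool = True

    def __post_init__(self):
        object.__setattr__(self, "proportions", tuple(self.proportions))
        if not self.proportions:
            raise ValueError("need at least one proportion")


STUDY_DESIGNS = {
    "study1": StudyDesign("study1", proportions=(0.8,), within=True),
    "study2": StudyDesign("study2", proportions=(0.8,), within=False),
    "study3": StudyDesign("study3", proportions=(0.54, 0.68, 0.8, 0.92), within=True),
}


def make_population(n: int, shares: dict[str, float], noise_sd: float,
                    seed: Optional[int] = None,
                    prior_alt_prob: float = 0.15) -> list[ParticipantProfile]:
    """Deterministically sized population with the given strategy mix.

    Counts are ``round(share·n)`` with the largest-share strategy absorbing
    the rounding remainder; the listing order is shuffled under ``seed``.
    """
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError("strategy shares must sum to 1")
    counts = {s: int(round(f * n)) for s, f in shares.items()}
    bulk = max(shares, key=lambda s: shares[s])
    counts[bulk] += n - sum(counts.values())
    profiles = []
    for strat, c in counts.items():
        for _ in range(c):
            profiles.append(ParticipantProfile(
                id=f"p{len(profiles):04d}", strategy=strat, noise_sd=noise_sd,
                prior_alt_prob=prior_alt_prob if strat == "prior_alt" else None))
    rng = np.random.default_rng(seed)
    rng.shuffle(profiles)
    return profiles


def simulate_study(design: StudyDesign | str,
                   population: Sequence[ParticipantProfile],
                   seed: Optional[int] = None,
                   noise_scope: str = "participant") -> pd.DataFrame:
    """Simulate one full study; returns one row per response.

    Columns: participant_id, study, condition, proportion, species, score
    (two decimals, matching the slider's resolution), trial_order.  Scores
    are ``clamp(prediction + noise, 0, 5)`` where the noise is a Gaussian
    draw shared across the participant's trials (``noise_scope=
    "participant"``, the default: an idiosyncratic scale-use offset) or
    independent per record (``"record"``).  Identical seeds give identical
    tables.
    """
    if isinstance(design, str):
        design = STUDY_DESIGNS[design]
    if not population:
        raise ValueError("empty population")
    if noise_scope not in ("participant", "record"):
        raise ValueError(f"unknown noise_scope {noise_scope!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for i, prof in enumerate(population):
        proportion = design.proportions[i % len(design.proportions)]
        if design.within:
            exp_conditions = ["contrastive", "non_contrastive"]
            rng.shuffle(exp_conditions)
        else:
            exp_conditions = ["contrastive" if i % 2 == 0 else "non_contrastive"]
        plan = exp_conditions + ["filler"]  # filler always last
        species = list(SPECIES[:len(plan)])
        rng.shuffle(species)
        offset = rng.normal(0.0, prof.noise_sd) if noise_scope == "participant" else None
        for order, (cond, spec) in enumerate(zip(plan, species), start=1):
            stim = build_stimulus(proportion, design.n_per_sample, cond, species=spec)
            pred = float(predict_score(prof, stim))
            eps = offset if offset is not None else rng.normal(0.0, prof.noise_sd)
            score = min(5.0, max(0.0, pred + eps))
            rows.append({
                "participant_id": prof.id,
                "study": design.name,
                "condition": cond,
                "proportion": float(stim.p_target),
                "species": spec,
                "score": round(score, 2),
                "trial_order": order,
            })
    return pd.DataFrame(rows)
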