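"""Interpretation rules for generic sentences ("Gs are f").

Five rules are implemented over a shared :class:`GenericStatement`:

majority
    true iff P(f|G) > 1/2 — the classical majority account.
restricted majority
    the same comparison with the probability domain restricted to the union
    of the salient feature alternatives, P(f | G ∩ ∪Alt(f)) > 1/2.
relative
    true iff f is more probable given G than given G's alternatives
    (pooled: against ∪Alt(G); or cell-by-cell against every alternative).
causal
    compares interventional probabilities P(f|do(G)) vs P(f|do(¬G)) via a
    partition of causally relevant background factors, with a threshold on
    the difference and an optional cellwise (Skyrms) dominance condition.
assertability
    graded: the contingency P(f|G) − P(f|∪Alt(G)); with no salient group
    alternatives it collapses to the bare conditional probability P(f|G)
    ("marginal mode").

Two side conditions are provided: an informativity (felicity) check that
fires when the feature alternatives can only apply to the group anyway, and
a homogeneity check requiring P(f|G_i) to be high on every cell of a salient
partition of G.

Zero-probability conditioning never raises out of this module: rules return
a :class:`Verdict` flagged inapplicable with a reason instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .worldmodel import (
    Event,
    World,
    ZeroProbabilityCondition,
    UndefinedIntervention,
    cond_prob,
    contingency,
    do_prob,
    prob,
    union_events,
)

__all__ = [
    "GenericStatement",
    "Verdict",
    "majority_verdict",
    "restricted_majority_verdict",
    "relative_verdict",
    "causal_verdict",
    "assertability",
    "informativity_check",
    "homogeneity_check",
    "DEFAULT_TAU",
    "DEFAULT_THETA",
]

logger = logging.getLogger(__name__)

#: Threshold standing in for "significantly above 0" in the causal rule.
#: The notion is inherently contextual; 0.2 is an arbitrary but documented
#: library default and every caller can override it.
DEFAULT_TAU = 0.2

#: Threshold standing in for "high" in the homogeneity condition; arbitrary
#: library default.
DEFAULT_THETA = 0.5


@dataclass(frozen=True)
class GenericStatement:
    """The semantic ingredients of one generic sentence.

    All events must be bound to one shared world.  ``alt_features`` (Alt(f))
    and ``alt_groups`` (Alt(G)) may be empty; ``background_var`` names the
    causal-background variable for the causal rule; ``group_partition``
    lists the cells {G_1..G_n} for the homogeneity condition.
    """

    group: Event
    feature: Event
    alt_features: tuple[Event, ...] = ()
    alt_groups: tuple[Event, ...] = ()
    background_var: Optional[str] = None
    group_partition: tuple[Event, ...] = ()
    name: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "alt_features", tuple(self.alt_features))
        object.__setattr__(self, "alt_groups", tuple(self.alt_groups))
        object.__setattr__(self, "group_partition", tuple(self.group_partition))
        w = self.group.world
        for e in (self.feature, *self.alt_features, *self.alt_groups,
                  *self.group_partition):
            if e.world is not w:
                raise ValueError("all statement events must share one world")
        if self.group_partition:
            seen = set()
            for cell in self.group_partition:
                if seen & cell.indices:
                    raise ValueError("group partition cells must be disjoint")
                seen |= cell.indices
            if seen != self.group.indices:
                raise ValueError("group partition must exactly cover the group")

    @property
    def world(self) -> World:
        return self.group.world

    def union_alt_features(self) -> Optional[Event]:
        return union_events(self.alt_features) if self.alt_features else None

    def union_alt_groups(self) -> Optional[Event]:
        return union_events(self.alt_groups) if self.alt_groups else None


@dataclass(frozen=True)
class Verdict:
    """Outcome of one rule applied to one statement.

    ``truth`` is the binary verdict where the rule is binary, ``degree`` the
    graded value where it is graded (assertability: in [−1, 1], or [0, 1] in
    marginal mode).  ``quantities`` carries the compared probabilities for
    reporting.  An inapplicable rule (zero-probability conditioning, missing
    alternatives/partition) sets ``reason`` and leaves truth/degree ``None``.
    """

    rule: str
    truth: Optional[bool] = None
    degree: Optional[float] = None
    quantities: dict = field(default_factory=dict)
    reason: Optional[str] = None

    @property
    def applicable(self) -> bool:
        return self.reason is None


def _inapplicable(rule: str, reason: str) -> Verdict:
    return Verdict(rule=rule, reason=reason)


def majority_verdict(world: World, s: GenericStatement) -> Verdict:
    """Simple majority rule: true iff P(f|G) > 1/2 (strict)."""
    try:
        p = cond_prob(world, s.feature, s.group)
    except ZeroProbabilityCondition:
        return _inapplicable("majority", "zero-probability group")
    return Verdict("majority", truth=bool(p > 0.5), quantities={"P(f|G)": p})


def restricted_majority_verdict(world: World, s: GenericStatement) -> Verdict:
    """Majority rule with the domain restricted to ∪Alt(f).

    True iff P(f | G ∩ ∪Alt(f)) > 1/2.  With no feature alternatives this
    falls back to the plain majority rule (logged).
    """
    ualt = s.union_alt_features()
    if ualt is None:
        logger.info("restricted majority: empty Alt(f); falling back to majority rule")
        v = majority_verdict(world, s)
        return Verdict("restricted_majority", truth=v.truth, quantities=v.quantities,
                       reason=v.reason)
    try:
        p = cond_prob(world, s.feature, s.group & ualt)
    except ZeroProbabilityCondition:
        return _inapplicable("restricted_majority",
                             "zero-probability restricted group G ∩ ∪Alt(f)")
    return Verdict("restricted_majority", truth=bool(p > 0.5),
                   quantities={"P(f|G∩∪Alt(f))": p})


def relative_verdict(world: World, s: GenericStatement,
                     mode: str = "pooled") -> Verdict:
    """Relative reading: f must be more probable given G than given G's alternatives.

    ``pooled`` compares against the union ∪Alt(G); ``per_alternative``
    requires the strict inequality against every alternative separately.
    Where the statement carries feature alternatives, all conditioning
    events are intersected with ∪Alt(f) first.
    """
    if mode not in ("pooled", "per_alternative"):
        raise ValueError(f"unknown mode {mode!r}")
    if not s.alt_groups:
        return _inapplicable("relative", "relative reading needs group alternatives")
    ualt_f = s.union_alt_features()

    def restrict(e: Event) -> Event:
        return e & ualt_f if ualt_f is not None else e

    try:
        p_g = cond_prob(world, s.feature, restrict(s.group))
    except ZeroProbabilityCondition:
        return _inapplicable("relative", "zero-probability (restricted) group")
    quantities = {"P(f|G)": p_g}
    if mode == "pooled":
        try:
            p_alt = cond_prob(world, s.feature, restrict(s.union_alt_groups()))
        except ZeroProbabilityCondition:
            return _inapplicable("relative", "zero-probability ∪Alt(G)")
        quantities["P(f|∪Alt(G))"] = p_alt
        return Verdict("relative", truth=bool(p_g > p_alt), quantities=quantities)
    truths = []
    for i, g_i in enumerate(s.alt_groups):
        try:
            p_i = cond_prob(world, s.feature, restrict(g_i))
        except ZeroProbabilityCondition:
            return _inapplicable("relative", f"zero-probability alternative #{i}")
        quantities[f"P(f|G_{i})"] = p_i
        truths.append(p_g > p_i)
    return Verdict("relative", truth=bool(all(truths)), quantities=quantities)


def causal_verdict(world: World, s: GenericStatement, tau: float = DEFAULT_TAU,
                   require_skyrms: bool = False) -> Verdict:
    """Causal reading: P(f|do(G)) must exceed P(f|do(¬G)) by more than ``tau``.

    Both interventional probabilities marginalise over the causal-background
    partition with *prior* cell weights.  With ``require_skyrms`` the
    cellwise dominance P(f|G ∧ B_i) ≥ P(f|¬G ∧ B_i) must additionally hold
    in every cell where both terms are defined.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if s.background_var is None:
        return _inapplicable("causal", "no causal-background variable set")
    not_g = ~s.group
    try:
        p_do_g = do_prob(world, s.feature, s.group, s.background_var)
        p_do_not_g = do_prob(world, s.feature, not_g, s.background_var)
    except (UndefinedIntervention, ZeroProbabilityCondition) as exc:
        return _inapplicable("causal", str(exc))
    d = p_do_g - p_do_not_g
    quantities = {"P(f|do(G))": p_do_g, "P(f|do(¬G))": p_do_not_g, "d": d}
    truth = d > tau
    if require_skyrms and truth:
        for b in world.partition(s.background_var):
            if prob(world, b) == 0:
                continue
            try:
                lo = cond_prob(world, s.feature, s.group & b)
                hi = cond_prob(world, s.feature, not_g & b)
            except ZeroProbabilityCondition:
                continue
            if lo < hi:
                truth = False
                quantities["skyrms_violated_cell"] = b.name
                break
    return Verdict("causal", truth=bool(truth), degree=float(d), quantities=quantities)


def assertability(world: World, s: GenericStatement,
                  restrict_to_alt_f: bool = False) -> Verdict:
    """Graded assertability: the contingency of f on G against ∪Alt(G).

    With group alternatives present the degree is
    ``P(f|G) − P(f|∪Alt(G)) ∈ [−1, 1]``; with none it collapses to the bare
    conditional probability ``P(f|G) ∈ [0, 1]`` and the verdict is flagged
    as ``marginal`` mode.  ``restrict_to_alt_f`` intersects every
    conditioning event with ∪Alt(f) first (off by default: the simplified
    measure ignores feature alternatives).
    """
    ualt_f = s.union_alt_features() if restrict_to_alt_f else None

    def restrict(e: Event) -> Event:
        return e & ualt_f if ualt_f is not None else e

    try:
        p_g = cond_prob(world, s.feature, restrict(s.group))
    except ZeroProbabilityCondition:
        return _inapplicable("assertability", "zero-probability (restricted) group")
    if not s.alt_groups:
        return Verdict("assertability", degree=p_g,
                       quantities={"P(f|G)": p_g, "mode": "marginal"})
    try:
        c = contingency(world, s.feature, restrict(s.group),
                        restrict(s.union_alt_groups()))
    except ZeroProbabilityCondition:
        return _inapplicable("assertability", "zero-probability ∪Alt(G)")
    return Verdict("assertability", degree=c,
                   quantities={"P(f|G)": p_g,
                               "P(f|∪Alt(G))": p_g - c,
                               "mode": "contingency"})


def informativity_check(world: World, s: GenericStatement) -> Verdict:
    """Felicity: infelicitous iff ∪Alt(f) ⊆ G.

    When the feature (and all its alternatives) can only apply to members of
    the group a priori, claiming the feature is distinctive of the group is
    uninformative.  With no declared feature alternatives the check is
    vacuously felicitous (logged).
    """
    ualt = s.union_alt_features()
    if ualt is None:
        logger.info("informativity: empty Alt(f); vacuously felicitous")
        return Verdict("informativity", truth=True,
                       quantities={"note": "vacuous (no Alt(f))"})
    infelicitous = ualt.issubset(s.group)
    return Verdict("informativity", truth=bool(not infelicitous),
                   quantities={"∪Alt(f)⊆G": infelicitous})


def homogeneity_check(world: World, s: GenericStatement,
                      theta: float = DEFAULT_THETA) -> Verdict:
    """Homogeneity: P(f|G_i) must exceed ``theta`` on every salient cell of G."""
    if not s.group_partition:
        return _inapplicable("homogeneity", "no group partition set")
    per_cell = {}
    for i, cell in enumerate(s.group_partition):
        try:
            per_cell[cell.name or f"G_{i}"] = cond_prob(world, s.feature, cell)
        except ZeroProbabilityCondition:
            return _inapplicable("homogeneity", f"zero-probability cell #{i}")
    truth = all(p > theta for p in per_cell.values())
    return Verdict("homogeneity", truth=bool(truth), quantities=per_cell)
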