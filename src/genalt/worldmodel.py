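"""Finite probability worlds and the operators the interpretation rules build on.

A :class:`World` is a finite joint distribution over a handful of labelled
discrete variables (a group membership variable, one or more feature
variables, optionally a causal-background variable).  Events are extensional:
a subset of the world's atoms.  All interpretation rules for generic
sentences reduce to comparisons between plain conditional probabilities
``P(f|G)``, contingencies ``P(f|G) - P(f|Alt(G))`` and interventional
probabilities ``P(f|do(G))`` computed on such worlds.

Worlds whose weights are integers or rationals are carried in exact
:class:`fractions.Fraction` arithmetic end to end, so stimulus worlds built
from animal counts yield exact probabilities (20/25 is 4/5, not 0.8000…01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "World",
    "Event",
    "WorldError",
    "ZeroProbabilityCondition",
    "UndefinedIntervention",
    "make_world",
    "prob",
    "cond_prob",
    "contingency",
    "do_prob",
    "total_probability_check",
]


class WorldError(ValueError):
    """Malformed world specification or ill-matched event/world pair."""


class ZeroProbabilityCondition(WorldError):
    """Conditioning on an event of probability zero.

    Semantic rules catch this and translate it into an "inapplicable"
    verdict rather than a crash.
    """


class UndefinedIntervention(WorldError):
    """A background cell with positive probability never co-occurs with the cause.

    The interventional sum then contains an undefined term ``P(f | cause, B_i)``;
    callers may opt in to dropping such cells and renormalising.
    """


def _as_weight(w):
    """Coerce a raw weight to Fraction when it is exactly representable."""
    if isinstance(w, bool):
        raise WorldError(f"weight must be a number, got {w!r}")
    if isinstance(w, Rational):
        return Fraction(w)
    if isinstance(w, float):
        return w
    if isinstance(w, str):
        return Fraction(w)  # "4/5" or "0.8" -> exact rational
    raise WorldError(f"weight must be a number, got {w!r}")


@dataclass(frozen=True)
class World:
    """Finite joint distribution over labelled discrete variables.

    Parameters
    ----------
    variables
        Ordered mapping-like sequence of ``(name, values)`` pairs; each value
        set is finite and ordered.
    assignments
        One tuple of values per atom, aligned with ``variables``.
    weights
        Nonnegative weight per atom; need not be normalised.  Atoms of weight
        zero are legal (events may select them; they contribute nothing).
    """

    variables: tuple[tuple[str, tuple], ...]
    assignments: tuple[tuple, ...]
    weights: tuple

    _total: object = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        names = [n for n, _ in self.variables]
        if len(set(names)) != len(names):
            raise WorldError("duplicate variable names")
        values = dict(self.variables)
        for a in self.assignments:
            if len(a) != len(self.variables):
                raise WorldError("atom does not assign every variable")
            for (name, vals), v in zip(self.variables, a):
                if v not in vals:
                    raise WorldError(f"value {v!r} undeclared for variable {name!r}")
        if len(set(self.assignments)) != len(self.assignments):
            raise WorldError("two atoms share the same full assignment")
        if len(self.weights) != len(self.assignments):
            raise WorldError("one weight per atom required")
        for w in self.weights:
            if w < 0:
                raise WorldError(f"negative weight {w!r}")
        total = sum(self.weights)
        if not total > 0:
            raise WorldError("weights must sum to a positive total")
        object.__setattr__(self, "_total", total)
        del values

    # -- introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.assignments)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.variables)

    def values_of(self, var: str) -> tuple:
        for n, vals in self.variables:
            if n == var:
                return tuple(vals)
        raise WorldError(f"variable {var!r} undeclared")

    def _var_index(self, var: str) -> int:
        for i, (n, _) in enumerate(self.variables):
            if n == var:
                return i
        raise WorldError(f"variable {var!r} undeclared")

    def atom_probability(self, i: int):
        return self.weights[i] / self._total

    # -- event constructors --------------------------------------------

    def event(self, predicate: Callable[[Mapping[str, object]], bool],
              name: str | None = None) -> "Event":
        """Event selecting the atoms whose assignment satisfies ``predicate``."""
        names = self.variable_names
        idx = frozenset(
            i for i, a in enumerate(self.assignments)
            if predicate(dict(zip(names, a)))
        )
        return Event(self, idx, name=name)

    def event_eq(self, var: str, value) -> "Event":
        """Event ``{var = value}``."""
        j = self._var_index(var)
        if value not in self.variables[j][1]:
            raise WorldError(f"value {value!r} undeclared for variable {var!r}")
        idx = frozenset(i for i, a in enumerate(self.assignments) if a[j] == value)
        return Event(self, idx, name=f"{var}={value}")

    def event_in(self, var: str, values: Iterable) -> "Event":
        """Event ``{var in values}``."""
        j = self._var_index(var)
        vals = set(values)
        undeclared = vals - set(self.variables[j][1])
        if undeclared:
            raise WorldError(f"values {undeclared!r} undeclared for variable {var!r}")
        idx = frozenset(i for i, a in enumerate(self.assignments) if a[j] in vals)
        return Event(self, idx, name=f"{var}in{sorted(map(str, vals))}")

    def full_event(self) -> "Event":
        return Event(self, frozenset(range(self.n_atoms)), name="Omega")

    def empty_event(self) -> "Event":
        return Event(self, frozenset(), name="empty")

    def partition(self, var: str) -> list["Event"]:
        """The family of events ``{var = v}``, one per declared value of ``var``."""
        return [self.event_eq(var, v) for v in self.values_of(var)]


@dataclass(frozen=True)
class Event:
    """Extensional event: a set of atom indices bound to one world."""

    world: World
    indices: frozenset
    name: str | None = None

    def __post_init__(self):
        if any(i < 0 or i >= self.world.n_atoms for i in self.indices):
            raise WorldError("event references atoms outside its world")

    def _check(self, other: "Event"):
        if other.world is not self.world:
            raise WorldError("events bound to different worlds")

    def __and__(self, other: "Event") -> "Event":
        self._check(other)
        return Event(self.world, self.indices & other.indices)

    def __or__(self, other: "Event") -> "Event":
        self._check(other)
        return Event(self.world, self.indices | other.indices)

    def __invert__(self) -> "Event":
        return Event(self.world, frozenset(range(self.world.n_atoms)) - self.indices)

    def issubset(self, other: "Event") -> bool:
        self._check(other)
        return self.indices <= other.indices

    def __contains__(self, atom_index: int) -> bool:
        return atom_index in self.indices


def union_events(events: Sequence[Event]) -> Event:
    """Union of a nonempty family of events over one world."""
    if not events:
        raise WorldError("cannot union an empty family of events")
    out = events[0]
    for e in events[1:]:
        out = out | e
    return out


# ---------------------------------------------------------------------------
# Spec compilation: factored or enumerated specs -> atoms
# ---------------------------------------------------------------------------

_WORLD_KEYS = {"variables", "atoms", "factored", "events", "statements"}


def make_world(spec: Mapping) -> World:
    """Compile a structured world description into a :class:`World`.

    The spec is a mapping with a ``variables`` key (variable name -> list of
    values) and either

    ``atoms``
        list of ``{"assignment": {var: value, ...}, "weight": w}`` entries
        (weights may be ints, "p/q" strings, or floats), or
    ``factored``
        a two-variable product form: a marginal over a group variable and,
        per group value, the probability that a binary feature variable takes
        its designated value.  Compiled to atoms so every operator runs on
        one representation.

    Unknown keys are errors (``events``/``statements`` are tolerated here and
    consumed by :mod:`genalt.specio`).
    """
    unknown = set(spec) - _WORLD_KEYS
    if unknown:
        raise WorldError(f"unknown world spec keys: {sorted(unknown)}")
    if "variables" not in spec:
        raise WorldError("world spec needs a 'variables' key")
    variables = tuple(
        (str(name), tuple(values)) for name, values in spec["variables"].items()
    )
    has_atoms = "atoms" in spec
    has_factored = "factored" in spec
    if has_atoms == has_factored:
        raise WorldError("world spec needs exactly one of 'atoms' or 'factored'")

    if has_atoms:
        names = [n for n, _ in variables]
        assignments, weights = [], []
        for entry in spec["atoms"]:
            extra = set(entry) - {"assignment", "weight"}
            if extra:
                raise WorldError(f"unknown atom keys: {sorted(extra)}")
            asg = entry["assignment"]
            missing = set(names) - set(asg)
            undeclared = set(asg) - set(names)
            if missing:
                raise WorldError(f"atom misses variables {sorted(missing)}")
            if undeclared:
                raise WorldError(f"atom references undeclared variables {sorted(undeclared)}")
            assignments.append(tuple(asg[n] for n in names))
            weights.append(_as_weight(entry["weight"]))
        return World(variables, tuple(assignments), tuple(weights))

    fac = spec["factored"]
    extra = set(fac) - {"group_var", "group_marginal", "feature_var",
                        "feature_value", "feature_prob"}
    if extra:
        raise WorldError(f"unknown factored spec keys: {sorted(extra)}")
    gvar, fvar = fac["group_var"], fac["feature_var"]
    decl = dict(variables)
    for v in (gvar, fvar):
        if v not in decl:
            raise WorldError(f"variable {v!r} referenced but undeclared")
    fvals = decl[fvar]
    if len(fvals) != 2:
        raise WorldError("factored feature variable must be binary")
    fyes = fac["feature_value"]
    if fyes not in fvals:
        raise WorldError(f"feature value {fyes!r} undeclared")
    fno = next(v for v in fvals if v != fyes)
    marginal = {k: _as_weight(v) for k, v in fac["group_marginal"].items()}
    featp = {k: _as_weight(v) for k, v in fac["feature_prob"].items()}
    if set(marginal) != set(decl[gvar]) or set(featp) != set(decl[gvar]):
        raise WorldError("factored spec must cover every group value exactly once")
    for g, p in featp.items():
        if not (0 <= p <= 1):
            raise WorldError(f"feature probability {p} for {g!r} outside [0,1]")

    names = [n for n, _ in variables]
    gi, fi = names.index(gvar), names.index(fvar)
    assignments, weights = [], []
    for g in decl[gvar]:
        for fv, w in ((fyes, marginal[g] * featp[g]),
                      (fno, marginal[g] * (1 - featp[g]))):
            a = [None] * len(names)
            a[gi], a[fi] = g, fv
            if any(x is None for x in a):
                raise WorldError("factored specs support exactly the group and feature variables")
            assignments.append(tuple(a))
            weights.append(w)
    return World(variables, tuple(assignments), tuple(weights))


# ---------------------------------------------------------------------------
# Probability operators
# ---------------------------------------------------------------------------

def prob(world: World, a: Event):
    """``P(a)`` — normalised weight of the atoms ``a`` selects."""
    if a.world is not world:
        raise WorldError("event bound to a different world")
    if not a.indices:
        return Fraction(0) if isinstance(world._total, Rational) else 0.0
    return sum(world.weights[i] for i in a.indices) / world._total


def cond_prob(world: World, target: Event, given: Event):
    """``P(target | given)``; raises :class:`ZeroProbabilityCondition` if P(given)=0."""
    pg = prob(world, given)
    if pg == 0:
        raise ZeroProbabilityCondition(
            f"conditioning on zero-probability event {given.name or given.indices}"
        )
    return prob(world, target & given) / pg


def contingency(world: World, f: Event, g: Event, alt_g: Event):
    """ΔP: ``P(f|g) − P(f|alt_g)``, the contingency of f on g against alt_g."""
    return cond_prob(world, f, g) - cond_prob(world, f, alt_g)


def do_prob(world: World, target: Event, cause: Event, background_var: str,
            drop_empty_cells: bool = False):
    """Interventional probability ``P(target | do(cause))``.

    Computed by the background-partition adjustment
    ``Σ_i P(target | cause ∧ B_i) · P(B_i)`` where the cells ``B_i`` are the
    values of ``background_var`` — the background factors keep their
    *marginal* weights instead of being updated by the observation of the
    cause, which is what distinguishes intervening from observing.

    A cell with ``P(B_i) > 0`` but ``P(cause ∧ B_i) = 0`` leaves the
    corresponding term undefined; by default this raises
    :class:`UndefinedIntervention`.  With ``drop_empty_cells=True`` such
    cells are dropped and the remaining cell weights renormalised.
    """
    cells = world.partition(background_var)
    terms, kept_mass = [], 0
    for b in cells:
        pb = prob(world, b)
        if pb == 0:
            continue
        overlap = prob(world, cause & b)
        if overlap == 0:
            if drop_empty_cells:
                continue
            raise UndefinedIntervention(
                f"background cell {b.name} (P={pb}) never co-occurs with the cause"
            )
        terms.append(cond_prob(world, target, cause & b) * pb)
        kept_mass += pb
    if not terms:
        raise UndefinedIntervention("no background cell overlaps the cause")
    return sum(terms) / kept_mass


def total_probability_check(world: World, target: Event, given: Event,
                            partition_var: str):
    """Return ``(P(target|given), Σ_i P(target|B_i ∧ given)·P(B_i|given))``.

    The two must agree for any partition (law of total probability); the
    property suite exercises this on randomly generated worlds.
    """
    lhs = cond_prob(world, target, given)
    rhs = 0
    for b in world.partition(partition_var):
        pb_given = cond_prob(world, b, given)
        if pb_given == 0:
            continue
        rhs += cond_prob(world, target, b & given) * pb_given
    return lhs, rhs
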