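"""Associative-learning rules: relative frequency (RF) and Rescorla–Wagner (RW).

RF tracks, per cue, the running mean of the outcome over the trials on which
the cue was present — it converges to the conditional probability P(o|c) and
admits an exact incremental form E ← E + (V − E)/n.

RW is the error-driven, competition-based update: on every trial, each
*present* cue's expectation moves by λ·(V − ΣE) where the prediction ΣE sums
the expectations of all cues present on that trial.  With a context cue
always present alongside a target cue, cue competition drives the target
expectation not to P(o|c) but to the contingency ΔP = P(o|c) − P(o|¬c) in
the long run — the fact that grounds using ΔP as the assertability measure
for generic sentences.

:func:`rw_equilibrium_analytic` solves the fixed-point system of the RW
expected update directly, giving the asymptote simulations are checked
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Trial",
    "AssociationState",
    "LearningConfig",
    "Environment",
    "Trajectory",
    "LearningError",
    "DegenerateDesignError",
    "rf_batch",
    "rf_step",
    "rw_step",
    "simulate_trials",
    "run_learning",
    "rw_equilibrium_analytic",
]


class LearningError(ValueError):
    pass


class DegenerateDesignError(LearningError):
    """The RW equilibrium system is singular for this cue design."""


@dataclass(frozen=True)
class Trial:
    """One learning episode: the cues present and the outcome magnitude V ∈ [0,1]."""

    index: int
    cues_present: frozenset
    outcome: float

    def __post_init__(self):
        object.__setattr__(self, "cues_present", frozenset(self.cues_present))
        if not self.cues_present:
            raise LearningError("a trial needs at least one cue")
        if not (0.0 <= self.outcome <= 1.0):
            raise LearningError(f"outcome {self.outcome} outside [0,1]")
        if self.index < 1:
            raise LearningError("trial index must be positive")


@dataclass(frozen=True)
class AssociationState:
    """Evolving expectations E(o|c_i), plus the number of updates applied."""

    expectations: Mapping[str, float]
    n: int = 0

    def __post_init__(self):
        object.__setattr__(self, "expectations", dict(self.expectations))

    def expectation(self, cue: str) -> float:
        return self.expectations[cue]


@dataclass(frozen=True)
class LearningConfig:
    """Which rule to run and with what parameters.

    ``lam`` is the RW learning rate (typically very small; demos use 0.05,
    convergence checks 0.005); ``initial`` the pre-exposure expectation.
    """

    rule: str = "rw"
    lam: float = 0.05
    initial: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.rule not in ("rf", "rw"):
            raise LearningError(f"unknown rule {self.rule!r}")
        if not (0.0 < self.lam <= 1.0):
            raise LearningError(f"learning rate {self.lam} outside (0,1]")


@dataclass(frozen=True)
class Environment:
    """Generative stand-in for a conditioning experiment.

    ``configurations`` maps each cue subset that can occur on a trial to its
    probability; ``outcome_probs`` maps the same subsets to P(outcome = 1 |
    that configuration).
    """

    configurations: Mapping[frozenset, float]
    outcome_probs: Mapping[frozenset, float]

    def __post_init__(self):
        cfg = {frozenset(k): float(v) for k, v in self.configurations.items()}
        out = {frozenset(k): float(v) for k, v in self.outcome_probs.items()}
        object.__setattr__(self, "configurations", cfg)
        object.__setattr__(self, "outcome_probs", out)
        if set(cfg) != set(out):
            raise LearningError("configurations and outcome_probs must share keys")
        if any(not k for k in cfg):
            raise LearningError("empty cue configuration")
        if any(v < 0 for v in cfg.values()) or abs(sum(cfg.values()) - 1.0) > 1e-9:
            raise LearningError("configuration probabilities must sum to 1")
        if any(not (0.0 <= v <= 1.0) for v in out.values()):
            raise LearningError("outcome probabilities must lie in [0,1]")

    @property
    def cues(self) -> tuple[str, ...]:
        return tuple(sorted(set().union(*self.configurations)))


# ---------------------------------------------------------------------------
# RF
# ---------------------------------------------------------------------------

def rf_batch(trials: Sequence[Trial], cue: str) -> float:
    """Mean outcome over the trials on which ``cue`` was present."""
    outcomes = [t.outcome for t in trials if cue in t.cues_present]
    if not outcomes:
        raise LearningError(f"cue {cue!r} never present")
    return float(sum(outcomes) / len(outcomes))


def rf_step(state: AssociationState, trial: Trial, cue: str) -> AssociationState:
    """One incremental RF update: E ← E + (V − E)/n.

    Exactly reproduces the batch mean after any trial sequence.  A trial on
    which the cue is absent leaves the state unchanged.
    """
    if cue not in trial.cues_present:
        return state
    n = state.n + 1
    e = state.expectations.get(cue, 0.0)
    new = dict(state.expectations)
    new[cue] = e + (trial.outcome - e) / n
    return AssociationState(expectations=new, n=n)


# ---------------------------------------------------------------------------
# RW
# ---------------------------------------------------------------------------

def rw_step(state: AssociationState, trial: Trial,
            config: LearningConfig) -> AssociationState:
    """One RW update: every present cue moves by λ·(V − Σ_{present} E_j)."""
    unknown = trial.cues_present - set(state.expectations)
    if unknown:
        raise LearningError(f"unknown cues {sorted(unknown)}")
    prediction = sum(state.expectations[c] for c in trial.cues_present)
    error = trial.outcome - prediction
    new = dict(state.expectations)
    for c in trial.cues_present:
        new[c] = new[c] + config.lam * error
    return AssociationState(expectations=new, n=state.n + 1)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_trials(env: Environment, n: int,
                    seed: int | np.random.Generator | None = None) -> list[Trial]:
    """Draw ``n`` i.i.d. trials: a cue configuration, then a Bernoulli outcome."""
    if n < 1:
        raise LearningError("need at least one trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    configs = sorted(env.configurations, key=lambda k: tuple(sorted(k)))
    probs = np.array([env.configurations[k] for k in configs], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(configs), size=n, p=probs)
    u = rng.random(n)
    return [
        Trial(index=i + 1, cues_present=configs[j],
              outcome=float(u[i] < env.outcome_probs[configs[j]]))
        for i, j in enumerate(idx)
    ]


@dataclass(frozen=True)
class Trajectory:
    """Per-trial expectation history for a learning run.

    ``history[k]`` holds the expectations *after* k updates (row 0 is the
    initial state), one column per cue in ``cues`` order.
    """

    cues: tuple[str, ...]
    history: np.ndarray
    rule: str

    @property
    def n_trials(self) -> int:
        return self.history.shape[0] - 1

    def state(self, k: int) -> AssociationState:
        return AssociationState(
            expectations=dict(zip(self.cues, self.history[k])), n=k)

    @property
    def final(self) -> AssociationState:
        return self.state(self.n_trials)

    def __iter__(self):
        return (self.state(k) for k in range(self.history.shape[0]))


def run_learning(trials: Sequence[Trial], config: LearningConfig,
                 cues: Iterable[str] | None = None) -> Trajectory:
    """Run RF or RW over a trial sequence, recording the whole trajectory.

    For RF, each cue's expectation is its running conditional mean (updated
    only on trials where the cue is present); for RW all present cues share
    the prediction error.  The inner loop is array-based so two-hundred-
    thousand-trial convergence runs stay cheap.
    """
    if cues is None:
        cues = sorted(set().union(*(t.cues_present for t in trials)))
    cues = tuple(cues)
    cue_index = {c: j for j, c in enumerate(cues)}
    n = len(trials)
    present = np.zeros((n, len(cues)), dtype=bool)
    outcomes = np.empty(n, dtype=float)
    for i, t in enumerate(trials):
        unknown = t.cues_present - set(cue_index)
        if unknown:
            raise LearningError(f"unknown cues {sorted(unknown)}")
        for c in t.cues_present:
            present[i, cue_index[c]] = True
        outcomes[i] = t.outcome

    history = np.empty((n + 1, len(cues)), dtype=float)
    e = np.full(len(cues), float(config.initial))
    history[0] = e
    if config.rule == "rw":
        lam = config.lam
        for i in range(n):
            mask = present[i]
            err = outcomes[i] - e[mask].sum()
            e[mask] += lam * err
            history[i + 1] = e
    else:  # rf
        counts = np.zeros(len(cues), dtype=float)
        for i in range(n):
            mask = present[i]
            counts[mask] += 1.0
            e[mask] += (outcomes[i] - e[mask]) / counts[mask]
            history[i + 1] = e
    return Trajectory(cues=cues, history=history, rule=config.rule)


def terminal_expectations(traj: Trajectory, tail_frac: float = 0.1) -> dict[str, float]:
    """Asymptote estimate: expectations averaged over the trajectory tail.

    A constant learning rate makes the expectations fluctuate around their
    equilibrium with stationary standard deviation of order √(λ/2); the
    time-average over the final ``tail_frac`` of trials is the standard
    low-variance estimate of the asymptote.
    """
    if not (0.0 < tail_frac <= 1.0):
        raise LearningError("tail_frac must lie in (0, 1]")
    start = int((1.0 - tail_frac) * traj.history.shape[0])
    tail = traj.history[start:]
    return dict(zip(traj.cues, tail.mean(axis=0).tolist()))


# ---------------------------------------------------------------------------
# RW equilibrium
# ---------------------------------------------------------------------------

def rw_equilibrium_analytic(env: Environment) -> dict[str, float]:
    """Solve the RW fixed point: expected update zero for every cue.

    For cue i the expected per-trial update is proportional to
    ``Σ_{K ∋ i} P(K) · (P(o|K) − Σ_{j ∈ K} E_j)``; setting all of these to
    zero is a linear system A·E = b with
    ``A[i,j] = Σ_{K ⊇ {i,j}} P(K)`` and ``b[i] = Σ_{K ∋ i} P(K)·P(o|K)``.
    In the canonical context+target design the target solves to
    ΔP = P(o | target) − P(o | context alone).
    """
    cues = env.cues
    k = len(cues)
    a = np.zeros((k, k))
    b = np.zeros(k)
    for cfg, p in env.configurations.items():
        members = [cues.index(c) for c in cfg]
        for i in members:
            b[i] += p * env.outcome_probs[cfg]
            for j in members:
                a[i, j] += p
    if np.linalg.matrix_rank(a) < k:
        raise DegenerateDesignError("RW equilibrium system is singular for this design")
    e = np.linalg.solve(a, b)
    return dict(zip(cues, e.tolist()))
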