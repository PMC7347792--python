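"""Cue competition: Rescorla–Wagner expectations converge to ΔP, not P(o|c).

A context cue is always present; a target cue accompanies it on half the
trials.  The outcome occurs with probability 0.8 when the target is present
and 0.3 otherwise, so P(o|target) = 0.8 while the contingency
ΔP = 0.8 − 0.3 = 0.5.  Plain relative-frequency learning tracks the former;
the error-driven competitive rule settles at the latter — the quantity the
assertability measure for generics is built on.
"""

import genalt as ga
from genalt.learning import Environment, terminal_expectations

env = Environment(
    configurations={frozenset({"context", "target"}): 0.5,
                    frozenset({"context"}): 0.5},
    outcome_probs={frozenset({"context", "target"}): 0.8,
                   frozenset({"context"}): 0.3})

trials = ga.simulate_trials(env, 100_000, seed=7)

rf = ga.run_learning(trials, ga.LearningConfig(rule="rf"))
rw = ga.run_learning(trials, ga.LearningConfig(rule="rw", lam=0.005))
eq = ga.rw_equilibrium_analytic(env)

print(f"relative frequency, target cue : {rf.final.expectations['target']:.3f}"
      "   (tracks P(o|target) = 0.8)")
print(f"Rescorla-Wagner,    target cue : {terminal_expectations(rw)['target']:.3f}"
      "   (tracks ΔP = 0.8 - 0.3 = 0.5)")
print(f"analytic RW equilibrium        : target {eq['target']:.3f}, "
      f"context {eq['context']:.3f}")
print("\nThe RW asymptote equals the contingency of the outcome on the target")
print("cue: learning the association is learning how *distinctive* the cue is.")
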