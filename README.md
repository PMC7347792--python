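# genalt — probabilistic semantics of generic sentences

`genalt` is a Python library for the probabilistic and causal semantics of
*generic sentences* — bare-plural generalizations of the form "*G*s are *f*"
("Birds fly", "Mosquitoes carry the West Nile virus") that are true or
assertable despite exceptions. It is aimed at researchers in formal
semantics and cognitive modeling who want the competing interpretation
rules for generics, and the learning theory behind them, as executable,
testable code.

## The model

All rules operate on a finite probability world: a joint distribution over
a group variable, feature variables and (optionally) a causal-background
variable. For a statement with group event *G*, feature event *f*, feature
alternatives Alt(*f*), group alternatives Alt(*G*) and background partition
{*B*ᵢ}, the library evaluates:

- **majority**: true iff P(*f*|*G*) > ½
- **restricted majority**: true iff P(*f* | *G* ∩ ∪Alt(*f*)) > ½
- **relative reading**: true iff P(*f* | *G* ∩ ∪Alt(*f*)) > P(*f* | ∪Alt(*G*) ∩ ∪Alt(*f*))
- **causal reading**: true iff Σᵢ P(*f*|*G*∧*B*ᵢ)·P(*B*ᵢ) exceeds
  Σᵢ P(*f*|¬*G*∧*B*ᵢ)·P(*B*ᵢ) by more than a threshold τ
  (interventional probabilities P(*f*|do(*G*)) via the background-partition
  adjustment), optionally with the cellwise dominance condition
  ∀*B*ᵢ: P(*f*|*G*∧*B*ᵢ) ≥ P(*f*|¬*G*∧*B*ᵢ)
- **graded assertability**: the contingency
  ΔP = P(*f*|*G*) − P(*f*|∪Alt(*G*)), collapsing to P(*f*|*G*) when no
  group alternatives are salient

plus two side conditions: **informativity** (infelicitous iff
∪Alt(*f*) ⊆ *G*) and **homogeneity** (P(*f*|*G*ᵢ) must be high on every
cell of a salient partition of *G*).

The assertability measure is grounded in associative learning: the
`learning` module implements relative-frequency and Rescorla–Wagner
updating (E ← E + λ(V − ΣE) for every cue present on a trial) and an
analytic equilibrium solver showing that under cue competition the RW
asymptote of a target cue is exactly ΔP — learning an association is
learning how *distinctive* a cue is for an outcome.

The `experiment` and `analysis` modules simulate and analyze slider-scale
rating studies built on this measure: two 25-animal samples with the target
sample 54/68/80/92% featured, a contrastive (alternative sample unfeatured)
vs. non-contrastive (equal proportions) manipulation, strategy-based
synthetic raters on a 0–5 scale with anchors 0 ↔ ΔP=−1, 2.5 ↔ ΔP=0,
5 ↔ ΔP=1, attention-check exclusions, a 0.5-point con/nocon/anti grouping
rule, and JZS Bayes-factor t-tests (Cauchy(0, √2/2) effect-size prior).

## Worked example

```python
import genalt as ga

stim = ga.build_stimulus(0.8, 25, "contrastive")   # 20/25 vs 0/25 featured
world = ga.stimulus_to_world(stim)                 # exact rational world
f = world.event_eq("feature", "yes")
G = world.event_eq("island", "target")
A = world.event_eq("island", "alt")

ga.contingency(world, f, G, A)                     # Fraction(4, 5)
ga.predict_score(ga.ParticipantProfile("p", "con"), stim)    # 9/2  -> 4.5
ga.predict_score(ga.ParticipantProfile("p", "nocon"), stim)  # 4    -> 4.0
```

The contingency of the contrastive stimulus is 0.8 − 0 = 0.8; a rater using
contingency maps it to 4.5 on the 0–5 slider, while a rater ignoring the
alternative sample rates the bare conditional probability 0.8 as 4.0 — the
half-point gap that separates the two strategies empirically. The
`examples/` directory contains four narrative scripts (interpretation
rules, ΔP convergence, a full simulated rating study, alternative-set
sensitivity); each prints the numbers it computes and what they mean. A
thin CLI mirrors the library:

```
genalt semantics eval WORLD.yaml --statement NAME --rules majority,relative,assertability
genalt learn simulate ENV.yaml --rule rw --lam 0.01 --n 100000 --seed 7 --out traj.csv
genalt experiment simulate --study study1 --population pop.yaml --seed 11 --out responses.csv
genalt experiment analyze responses.csv --design within --out report/
genalt demo alt-sets
genalt fixtures generate --out fixtures/
```

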