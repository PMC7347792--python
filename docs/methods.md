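# Methods

## Worlds and probability operators

Every semantic rule is evaluated on a finite probability world: labelled
discrete variables, one weight per joint assignment (atom). Events are
extensional (sets of atoms), so complement/union/intersection are set
operations and every probability is a ratio of weight sums. Factored specs
(group marginal × per-group feature probability) are compiled to atoms at
load time, keeping a single code path for all operators.

Worlds built from integer or rational weights — in particular every
stimulus world, where weights are animal counts — are carried in exact
`fractions.Fraction` arithmetic end to end; a 20-of-25 sample yields
exactly 4/5, and the law-of-total-probability identity holds exactly, not
to rounding. Float-weighted worlds use float arithmetic with a 1e-12 test
tolerance.

Conditioning on a zero-probability event raises a typed error
(`ZeroProbabilityCondition`); the rule layer catches it and returns an
*inapplicable* verdict with a reason instead of a number. The
interventional operator `do_prob(f, G, B)` = Σᵢ P(f|G∧Bᵢ)·P(Bᵢ) is
undefined when a positive-probability background cell never co-occurs with
the cause; the default is to raise, with an explicit opt-in flag that
drops such cells and renormalises. The underlying account never confronts
this degenerate case, so the conservative behaviour (refuse, don't guess)
is the default.

## Interpretation rules

All threshold comparisons are strict (`>`): the definitions are stated
with strict inequalities and no tie policy, so ties yield false. Two
thresholds are exposed as parameters because the account leaves them
qualitative: τ (default 0.2) stands in for "significantly above 0" in the
causal rule, and θ (default 0.5) for "high" in the homogeneity condition.
Both defaults are arbitrary and documented as such; every caller can
override them. The relative reading defaults to the pooled comparison
against ∪Alt(G), with the per-alternative variant (∀i: P(f|G) > P(f|Gᵢ))
available via `mode="per_alternative"`. The assertability measure ignores
feature alternatives by default (the simplified form of the account); the
composed rule is available through `restrict_to_alt_f=True`. Whether
homogeneity attaches to the absolute reading, the relative reading or both
is left open by the account; the package therefore exposes it as a free-
standing check rather than folding it into any verdict.

## Learning

RF (relative frequency) is the running conditional mean, with the exact
incremental form E ← E + (V − E)/n; the incremental/batch identity is an
algebraic fact and is tested to 1e-12 over random sequences. RW updates
every cue *present* on a trial by λ(V − Σⱼ Eⱼ), the sum ranging over the
present cues; absent cues are untouched. The account's notation indexes
"each primitive cue" ambiguously, but cue competition and ΔP convergence —
the behaviour the rule is invoked for — require the present-cues
convention, which is also the standard one. Initial expectations are 0
(the conventional pre-exposure value) and a single outcome variable is
assumed. λ defaults to 0.05 for demonstrations; convergence analyses use
0.005.

`rw_equilibrium_analytic` sets the *expected* update of every cue to zero
and solves the resulting linear system A·E = b with
A[i,j] = Σ_{K ⊇ {i,j}} P(K) and b[i] = Σ_{K ∋ i} P(K)·P(o|K). For the
canonical design (context always present, target on a fraction of trials)
the target's equilibrium is algebraically P(o|target) − P(o|context alone)
= ΔP, which bridges to `worldmodel.contingency` on the matching world.

With a constant learning rate the expectations fluctuate around the
equilibrium with stationary standard deviation of order √(λ/2), so a
single terminal sample is a noisy asymptote estimate. The package's
asymptote estimator, `terminal_expectations`, averages the final 10% of
the trajectory (≈ 100 independent stretches at λ = 0.005 over 2·10⁵
trials), reducing the estimator's SD to a few 10⁻³. Convergence analyses
use 2·10⁵ trials and five seeds; per-seed asymptotes are compared to the
target at 0.02 and the across-seed mean to the analytic equilibrium
at 0.01.

## Stimuli, raters and noise

A stimulus is two samples of n = 25 animals with k of them featured;
counts are the contract (the pictorial layout is cosmetic). Proportions
that are not realisable with 25 animals (54% → 13.5, 68% → 17) are rounded
half-up with a logged realised proportion, since how the original pictures
realised them is unrecorded. The stimulus→world bridge is exact rational
arithmetic.

Strategies map a stimulus to a deterministic score: `con` sends the
displayed contingency through the anchored affine map s = 2.5(ΔP + 1);
`nocon` sends the bare conditional probability through s = 5·P(f|G)
(anchored by the single fixed point P = 0.8 ↔ 4, and linear as the minimal
completion); `prior_alt` contrasts against a held prior belief about the
feature among privately assumed alternatives; `anti` is the mirror
contingency P(f|Alt) − P(f|G). The `anti` strategy is a package extension:
the theoretical account provides no generating mechanism for raters who
prefer the non-contrastive condition, but a designed strategy is needed to
simulate populations containing them at a known share. Fillers (a queried
feature no animal displays) score 0 under every strategy — a plainly false
sentence sits at the scale floor, matching the near-zero filler means
observed empirically — rather than passing ΔP = 0 through the affine map.

A response is clamp(prediction + ε, 0, 5) with Gaussian ε, rounded to the
slider's two decimals. The noise scope is a parameter: the default
(`noise_scope="participant"`) draws one offset per participant, shared
across that participant's trials, modelling idiosyncratic interpretation
of the scale — the dominant dispersion source the original studies
themselves point to, and the only noise structure under which the
0.5-point within-participant grouping rule can recover strategy shares
(per-record noise of SD 0.8 gives the within-participant difference an SD
of 1.13, misclassifying two-thirds of probability-strategy raters).
Independent per-record noise remains available via `noise_scope="record"`.
The generator emulates the studies' *structure* (conditions, proportions,
trial plans, slider resolution), not effects it has no mechanism for:
order effects, scale nonlinearity, sequential learning within a trial, or
participants switching strategies — so passing simulation-based tests
validates the pipeline's logic, not those aspects of real data.

## Analysis

Exclusions: participants with missing experimental responses, missing
fillers (unless a missing-slider-means-zero flag imputes 0), or a filler
score ≥ 1.5. The boundary is inclusive uniformly — the original exclusion
rule is worded both ways across studies, and the inclusive reading is the
conservative one. Group split: d = contrastive − non-contrastive score;
d ≥ 0.5 → con, d ≤ −0.5 → anti, otherwise nocon. Summaries report the
sample mean, SD (n−1 denominator) and a 95% normal-approximation CI
(z = 1.96, matching the normality assumption of the original analysis); a
t-interval is available behind a flag.

The JZS Bayes factor integrates the noncentral-t likelihood of the
observed statistic over a Cauchy(0, r) prior on the standardised effect
size (r = √2/2, the common "default prior" scale; the original analyses do
not print their r). One-sided tests place a half-Cauchy on the positive
direction. Numerics: the integral is split at the likelihood peak
δ = t/√N and truncated to the likelihood's support (the integrand is below
double precision outside it, and the underlying Boost density evaluation
overflows at extreme noncentrality — such points contribute zero). The
implementation is verified against an independent dense-trapezoid
quadrature and against pingouin's implementation at 1%. The Bayesian ANOVA
used for the multi-proportion study is out of scope; the pipeline emits
per-proportion summary tables instead.

The published means, SDs, CIs and BF₁₀ values of the original studies
(e.g. 3.51, 2.88, BF₁₀ = 104) depend on the deposited participant data and
the original prior settings; the pipeline accepts such data as an external
CSV input, but no test depends on it.

## Problem sizes

Default analyses use: 2·10⁵ trials × 5 seeds for convergence, 500 random
worlds for the equivalence property, 200 participants × 5 seeds for share
recovery, and a 15-point (t, n) grid for the Bayes-factor check — sizes at
which every stochastic tolerance above is comfortably met by the binomial
or CLT bound that motivates it.

## Known limitations

Finite outcome spaces only; no structure learning and no do-calculus
beyond the single background-partition adjustment; no natural-language
parsing into statements; no salience model for *which* alternative sets or
partitions are contextually relevant (they are inputs); the probability→
scale map for `nocon` raters is linear on the evidence of a single anchor;
the `anti` strategy is a simulation device, not a claim about mechanism.
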