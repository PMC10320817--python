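# Methods

## The reference game

A speaker sends a one-feature message; a listener must pick which of three
displayed objects it refers to. Objects combine one value from each of two
dimensions (three creatures × three accessories in the concrete stimuli,
three shapes × three colors in the abstract variant). Only a subset of
feature values is *expressible* as a message; the rest exist on screen but
cannot be named.

Four trial conditions are defined purely by geometry:

| condition | geometry | solvable by |
|---|---|---|
| unambiguous | only the target carries the message feature | anyone (attention check) |
| ambiguous | target and competitor are identical | nobody (chance baseline) |
| simple | target and competitor both match; the competitor has an unambiguous alternative message, the target's other feature is inexpressible | L1, L2 |
| complex | as simple, but the target's other feature is expressible yet shared with the distractor, so no unambiguous message for the target exists | L2 only |

A session holds 66 trials: 12 simple, 12 complex, 33 unambiguous, 9
ambiguous, in seeded-uniform order, with the three roles assigned uniformly
to screen slots (left/center/right) per trial. Message dimensions are
balanced within condition (6/6 in each critical condition). The concrete
item instantiations are sampled uniformly from all feature assignments
consistent with the condition geometry, since only the condition structure —
not the identity of particular creatures — enters any downstream analysis.

Four built-in designs: `exp1` (original expressibility: both monsters and
both hats expressible; robot and scarf not), `exp2_remapped` (expressible
and inexpressible values swapped within each dimension; constructed from
`exp1` by `remap_design`, which transports expressibility through the
bijection and is provably an isomorphism on trials), `exp3_all_messages`
(all six values expressible; trials are generated from the `exp1` template
and keep its condition labels, because relative to the full message set the
simple geometry is literally ambiguous), and `exp4_abstract` (structurally
identical to `exp1` with shape/color values).

## Listener hierarchy

All agents use a quantal-response (softmax) choice rule: an option with
utility `u` gets weight `exp(λ·u)`. The rationality parameter `λ > 0`
interpolates between uniform choice (λ→0) and strict maximization (λ→∞).

* `L0(o|m) ∝ exp(λ·U(o))`, where `U` is the uniform distribution over the
  referents the message is true of (`1/|truth set|`, 0 elsewhere).
* `S0(m|o) ∝ exp(λ·U(m))`, uniform over the referent's true expressible
  messages.
* Higher levels iterate the same rule with the previous level's choice
  probability in the utility slot: `L1(o|m) ∝ exp(λ·S0(m|o))`,
  `S1(m|o) ∝ exp(λ·L0(o|m))`, `L2(o|m) ∝ exp(λ·S1(m|o))`.

This "iterated quantal response" form reproduces every qualitative
prediction of the hierarchy: L0 at chance on both critical conditions; L1
solves simple (the competitor's S0 mass splits over two messages) but is
exactly symmetric on complex; L2 solves both, because S1 avoids the
ambiguous message for the competitor. Under the all-messages design the
simple asymmetry vanishes for every level while the complex asymmetry
survives for L2 only. An alternative recursion that exponentiates
log-probabilities (`utility="logprob"`, i.e. `p^λ` weighting) satisfies the
same qualitative predictions and is exposed as a config option; `prob` is
the default and is what all frozen test values use.

Degenerate inputs are defined rather than rejected: a message true of no
referent yields a uniform listener (all utilities zero), and a referent
with no true expressible message yields a uniform speaker. Softmax is
computed with max-subtraction, so large λ cannot overflow.

**Default λ = 5.** No fitted value is available to copy, so the default is
chosen to make predictions near-deterministic but non-degenerate: L1 at
λ = 5 gives ≈ (0.92, 0.07, 0.01) on a simple trial and L2 ≈ (0.71, 0.15,
0.14) on a complex one. Tests that need sharply separated reasoner types
use λ = 20 explicitly.

One consequence worth knowing: because utilities are probabilities in
[0, 1], the level-2 softmax compresses. At λ = 5 the L2 listener keeps
roughly 14% of its mass on the distractor of a complex trial. This is the
main reason the simulated overall distractor rate at defaults lands near
3–4% rather than exactly at the 2% lapse floor.

## Synthetic participants

Each simulated participant has one fixed strategy for the whole session
(the analyses operate at participant level, and elicited strategies are
near-consistent for reasoners):

* `rsa_L0`/`rsa_L1`/`rsa_L2` — sample the corresponding listener at the
  participant's λ.
* `guess` — uniform over message-matching referents.
* `visual_resemblance`, `odd_one_out`, `salience`, `preference` —
  stimulus-driven strategies, parameterized per design by
  `bias_alignment[strategy][condition]` = P(choice lands on the target).

Filler trials are handled structurally for everyone: unambiguous trials
are answered with the target (attention-check semantics — the message
names it uniquely), ambiguous trials split uniformly between the two
identical referents. Two nuisance processes overlay every strategy: a
lapse (probability `lapse_rate`, default 0.02, the trial is answered with
the distractor) and an additive log-odds position bias toward the center
and right slots (default (0.5, 0.5) at population level, matching
replication-scale estimates; the model-validation tests switch it off).

Bias-alignment defaults: `visual_resemblance` simple-condition alignment
is 0.87 on the original and all-messages stimuli and 0.25 on the remapped
stimuli — the one strategy with quantitative anchors (≈87% and ≈89% of
such responses landed on the target with the original stimuli, and the
remap points the same heuristic at a non-target). The other three
strategies have no quantitative anchors; they default to neutral-to-mild
values (salience 0.8 on the original stimuli where the odd-one-out target
is visually prominent, odd_one_out 0.30 with residual mass split toward
the distractor it tends to single out, preference 0.5) and all are
configurable. On the abstract design every alignment is 0.5. Residual
(non-target) mass goes to the competitor — stimulus-driven choices are
observed essentially only among the two message-matching referents —
except for `odd_one_out`, which splits it with the distractor.

The default population mixture (28% L2, 20% L1, 7% L0, 22% guess, 23%
bias strategies dominated by visual resemblance) emulates the annotated
strategy breakdown: about half correct reasoners, a quarter guessers, a
quarter stimulus-driven. It is a study-conditions default, not a fitted
quantity.

What the generator does *not* emulate: trial-level strategy switching,
learning across trials (none was observed in the data the simulator
emulates), free-text explanations and their annotation noise, and any
perceptual detail of the stimuli (visual resemblance is a probability, not
a similarity computation). Passing tests therefore show that the analysis
pipeline recovers structure a strategy-mixture world generates — not that
humans are such a world.

## Analysis pipeline

**Ambiguous baseline coding.** Correctness on ambiguous trials is
unobservable (two identical referents) and must be assigned: `coinflip`
codes each non-distractor response correct independently with probability
½; `forced_even` codes exactly ⌊k/2⌋ of the k non-distractor responses
correct (random subset). Distractor responses are incorrect under both.
The variance study re-codes a dataset n times per method and refits the
condition effects: forced-even pins the pooled ambiguous accuracy, so the
condition-only estimate is constant across recodings, while coin-flipping
adds Binomial(k, ½) dispersion — the SD ordering is a theorem, the test
merely exercises it.

**Condition effects.** ML logistic regression of correctness on
dummy-coded condition with complex as reference, distractor trials
excluded. With condition dummies only, the MLE is the closed-form logit
difference of pooled condition accuracies with Wald SE
`sqrt(Σ 1/successes + 1/failures)`; the implementation uses that identity
(cross-checked against an iterative GLM fit in the tests). Significance is
a 95% Wald interval excluding zero. This deliberately replaces a Bayesian
mixed-effects regression: the simulation pipeline needs a fast,
self-contained estimator, and the reproducible content here is the
dispersion/significance *ordering* across coding methods, not posterior
inference. Separation (a condition pooled at 0 or 1) yields an infinite
estimate plus a warning rather than an error.

**Contingency and agreement.** Pearson χ² without continuity correction
(scipy), dof = (r−1)(c−1). Cohen's κ with the large-sample CI
`κ ± 1.96·sqrt(p_o(1−p_o)/(n(1−p_e)²))`; the point estimate is
cross-checked against scikit-learn.

**Latent profile analysis.** Diagonal-covariance Gaussian mixture on
per-participant (simple, complex) accuracies, EM with 20 seeded restarts
per K, variance floor (reg_covar) 1e-4, K selected by BIC with the
AIC-selected K reported alongside (they can disagree). Ambiguous and
unambiguous accuracies never enter the profile space.

**Nearest-profile classification.** Canonical profiles L0 = (0.5, 0.5),
L1 = (1, 0.5), L2 = (1, 1); Euclidean distance; ties break toward the
lower level. Participants with simple accuracy below `0.5 − margin` form
the below-chance `other` class. Default margin 0.25: with 12 trials per
condition, a true chance-level responder falls below 0.4 (margin 0.1) with
probability 0.19 under Binomial(12, ½), which would mislabel a fifth of
genuine guessers; 0.25 places the boundary ≈2.8 binomial SDs below chance
while still catching the near-zero-accuracy participants the class exists
for.

**Recovery experiment.** Simulate → code (forced-even) → accuracies →
classify (nearest-profile and mixture-based, the latter mapping each
component to the class of its mean) → confusion of true strategy vs
assigned class. Under the bias-free abstract design with equal thirds of
L0/L1/L2 at λ = 20 and 2% lapse, nearest-profile recovery is ≈95%; under
the original design, visual-resemblance participants are mostly absorbed
into L1/L2 (the inflation phenomenon), and under the remapped design into
L0/other (deflation).

## Problem sizes and runtime choices

Simulated populations use 55–60 participants (one 66-trial session each),
matching the scale the design targets; the variance study uses 100
recodings per method; cluster-count recovery uses 50 replicates of n = 60
with four planted clusters (means (0.5, 0.5), (0.92, 0.5), (0.92, 0.92),
(0.2, 0.35), SD 0.04 — kept off the [0, 1] boundary so clipping does not
create spurious point masses). Monte-Carlo agreement tests use a few
hundred to a few thousand trials with 3-standard-error tolerances. The
coin-flip false-significance bound is checked as the average rate over
five replicate guesser populations, because a single dataset's rate is
confounded with its own sampling deviation from chance — the average
measures the coding method, which is the claim of interest.

## Known limitations

* Strategy is fixed per participant; humans switch.
* `bias_alignment` values other than visual resemblance are conventions,
  not estimates.
* The effect estimator ignores participant- and item-level random
  variation; its SEs are anticonservative for clustered data. It exists to
  compare coding schemes and designs within the simulation, not to analyze
  human data.
* The iterated-QR recursion is one of several defensible level-k
  formulations; the `logprob` variant is provided but only the qualitative
  predictions (shared by both) should be relied on across variants.
* No salience priors or message costs: listener levels above 2 are
  rejected rather than extrapolated.
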