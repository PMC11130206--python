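# Methods

`pongocog` implements the statistical analysis of two touchscreen
experiments with zoo-housed Bornean orang-utans — a dot-probe task measuring
immediate attention to male facial characteristics (enlarged flanges;
symmetrised faces) and a two-alternative preference task measuring choice
bias for flanged-male pictures — together with seeded generators that
reproduce both task designs, so the whole pipeline is testable without any
animal data.

## Task designs and the synthetic generators

**Dot-probe.** A subject sees two versions of the same face side by side for
300 ms; a probe then replaces one of them and the reaction time (RT) to
touch it is recorded. A trial is *congruent* when the probe replaces the
hypothesised attention-grabbing version (large flange, or symmetrised face).
The flange variant uses 72 stimulus pairs across 6 sessions of 24 trials;
the symmetry variant 80 pairs across 8 sessions of 20 trials. Every pair is
probed exactly twice — once congruently, once incongruently — in seeded
random order, with probe sides balanced within a session up to rounding (the
original design does not state how sides were balanced; balanced-to-rounding
is this package's assumption).

The RT generator mirrors the analysis model: RT = intercept + b_congruent·c
+ b_left·l + session effect + Student-t(ν) noise, with c and l sum-coded ±1
so the condition-level gap is twice the coefficient. Defaults: intercept
700 ms, null condition effects, session SD 30 ms, residual scale 80 ms,
ν = 5 — a realistic regime for great-ape touchscreen RTs, matching the null
result and the heavy-tailed residuals the robust model anticipates. Two
contamination processes are added for the filtering stage to remove, since
the filtering rules need something to act on: anticipatory taps (RT replaced
by Uniform(50, 199) ms) and distracted slow responses (+1500 ms), each at
probability 0.05 by default. Simulated RTs below 50 ms are clipped there and
flagged.

**Preference.** Each of six subjects completes six sessions in two
contiguous three-session blocks; the flanged-male category is coded red in
one block and green in the other, with block order counterbalanced 3/3
across subjects. A session opens with 8 forced trials (4 per colour) that
teach the colour→category mapping, followed by 16 free choices between a
red and a green dot placed at opposite ends of a random diameter around the
screen centre. The vertical position of the flanged dot is therefore
R·cos(φ) with φ ~ Uniform(0, 2π), scaled to ±0.35 of screen height
(positive = lower). Choices are Bernoulli draws from a logistic model with
colour, order and height fixed effects plus subject, session-within-subject
and subject-colour-slope random effects. Defaults encode the observed
regime: no net category preference, a red bias (b_green = −0.40, odds ratio
0.67), a weak order effect (−0.128) and a strong energy-saving height effect
(+4.05 per screen unit — the lower dot needs less arm lifting). Random
effect SDs default to 0.25 / 0.25 / 0.15 on the logit scale, modest
individual differences of the size small-N primate studies typically show.

What the generators deliberately do **not** emulate: stimulus identity
effects (the analysis ignores which picture appears), learning or
trial-order drift, motor noise beyond the RT value, and reward dynamics.
Passing recovery tests therefore show that the estimators are correct for
data satisfying the models' assumptions, not that real orang-utan data
satisfy them.

## Reaction-time filtering

Two exclusion rules are applied per subject and task: RTs above
median + 2.5 × MAD (slow outliers) and RTs below 200 ms (anticipatory).
The MAD is scaled by the normal-consistency constant 1.4826 following the
usual robust-estimation convention; a raw-MAD option is exposed because the
bare term "MAD" is ambiguous. The threshold is computed on the full
submitted batch before the 200 ms floor is applied (the conservative
reading; an option computes it after removing sub-floor trials first).
A subject×task group with fewer than two trials cannot support a MAD
threshold; it is passed through unfiltered and flagged `unfilterable`
rather than silently dropped.

Excluded trials are re-run once in subject-specific repetition sessions and
filtered by the same rules; the final dataset is the union of the two
retained sets, so a trial excluded in both rounds is lost. With the
published counts this arithmetic reproduces the study's accounting exactly:
(423−96) + (105−28) = 404 flange trials, (474−102) + (108−32) = 448
symmetry trials, and exclusion percentages 22.69% / 26.67%. (The published
21.61% for the symmetry primary round does not match 102/474 = 21.52%; the
counts, which are self-consistent, are taken as authoritative.)

## Inference engine

Both models expose a differentiable log posterior on an unconstrained
vector (positive parameters log-transformed, the random-effect correlation
tanh-transformed, Jacobians included) and are sampled with the package's
Hamiltonian Monte Carlo engine: dual-averaging step-size adaptation toward
80% acceptance, a diagonal mass matrix estimated midway through warmup, and
a per-iteration leapfrog count drawn uniformly from 1–32 to decorrelate
draws. Chains are seeded independently via `SeedSequence(seed, chain)`, so
runs are bit-reproducible for a fixed seed and NumPy version. A proposal
with energy error above 500 is counted as a divergence and rejected —
because rejection is exactly the Metropolis step with acceptance
probability 0, divergences leave the chain valid (unlike in dynamic
trajectory samplers) and merely signal reduced efficiency. Gradients are
analytic and verified against finite differences in the test suite;
convergence is monitored with split R-hat and bulk ESS (via `arviz`) plus a
worst-case lag-1 autocorrelation. Default run length follows the analysis
convention of 4 chains × 6000 iterations with 1000 warmup each (20 000
retained draws); tests and calibration loops use shorter, seeded runs since
the posteriors involved are low-dimensional and fast-mixing.

Effects are reported as: posterior median, scaled MAD of the draws, an 89%
highest-density interval (89% rather than 95% so the interval reads as a
posterior description, not a hypothesis test), and the probability of
direction pd = max(P(θ>0), P(θ<0)) ∈ [0.5, 1]. The HDI is the shortest
window of ⌈0.89·n⌉ consecutive order statistics; for a multimodal posterior
this still returns one interval, which may bridge modes (noted rather than
split). Exact-zero draws are excluded from pd and the shares renormalised —
a measure-zero event for continuous posteriors. Summaries on transformed
scales (odds ratios, probabilities) always transform the draws first and
summarise after.

## Dot-probe model

Per subject: centred RT ~ Student-t(ν, μ, σ) with
μ = α + b_congruent·c + b_left·l + u_session, c and l sum-coded ±1,
u_session ~ Normal(0, σ_session) non-centred. Priors: α ~ Normal(0, 5),
coefficients ~ Normal(0, 10), ν ~ Gamma(shape 2, rate 0.1), scales ~
half-Student-t(3, max(2.5, sd(y))).

Two prior readings deserve note. The Gamma prior for ν is parameterised as
shape 2 / *rate* 0.1 (prior mean 20): a scale-0.1 reading would put the
prior mean at 0.2, untenable for a degrees-of-freedom parameter, and
shape-2/rate-0.1 is the standard weakly-informative choice for ν. The
half-t(3) scale prior uses max(2.5, sd(response)): a fixed 2.5 on a
millisecond-scale response would be absurdly informative, and scaling by
the response spread reproduces the documented default behaviour of standard
Bayesian regression interfaces. Centring uses the subject's final filtered
dataset (after the repetition merge); repetition sessions enter as their own
session levels; sessions are unordered identifiers. With a single session
the group term is dropped and logged. Fits with any split R-hat above 1.05
are flagged non-converged.

The optional moderator extension adds the pair's absolute flange-width
difference (mean-centred) and its interaction with congruence, probing
whether a congruence effect is confined to the most discriminable pairs.

## Preference model

All subjects' choice-phase trials (forced trials are not choices and are
excluded from the likelihood) enter one Bernoulli model with logit
P(choice = flanged) = α + b_green·g + b_order·o [+ b_height·h] + a_subject +
s_session(subject) + c_subject·g, where g = +1 when flanged is green-coded,
o = +1 for red-block-first subjects, and h is the flanged dot's vertical
position in screen fractions. The subject intercept and colour slope are
correlated bivariate normal (non-centred Cholesky parameterisation; uniform
prior on the correlation); priors are Normal(0, 0.5) on the logit scale for
all fixed terms and half-t(3, 2.5) for the random-effect SDs. Because h
spans only 0.7 units, a height odds ratio is "per full screen unit" and
observable contrasts span 0.7 of it — large printed ORs for height are
expected and correctly interpreted this way. Per-subject odds ratios and
choice probabilities combine the fixed intercept with the subject deviation
draw-wise before transforming.

## Switch test

For each 16-trial session the statistic T counts adjacent choice switches.
Under independence with choice probability θ ~ Beta(10, 10) (a deliberately
strong 50/50 expectation), the conjugate posterior after a session with k
flanged choices is Beta(10+k, 10+n−k); the null distribution of T is built
from 10 000 simulated series, each drawing θ* from that posterior and n
independent Bernoulli(θ*) trials. The observed T is compared against the
null's 95% highest-density set, built by greedy accumulation of the
highest-probability bins (ties broken toward the shorter span — a
convention this package fixes, since an HDI on a discrete empirical
distribution is not otherwise unique): below it → temporal clustering,
above → dispersion. Both tail shares include equality, so p_ge + p_le ≥ 1.

For n ≤ 12 an exact oracle enumerates all 2ⁿ sequences with marginal weight
B(a+k, b+n−k)/B(a, b) and is used to validate the Monte-Carlo null bin by
bin; the closed-form null mean (n−1)·2ab/((a+b)(a+b+1)) provides an
independent moment check. Because T is discrete, the greedy 95% set
overshoots its mass, making the test conservative: on genuinely independent
series about 3% of sessions are flagged rather than the nominal 5%.
Sessions are analysed independently, as in the original procedure.

## Calibration experiments

The acceptance checks verify frequentist calibration of the Bayesian
machinery at the study's own sample sizes (~140 retained dot-probe trials
per subject; 6 subjects × 96 choices). In each replicate the focal
coefficient's true value is drawn from its exact model prior (congruence ~
Normal(0, 10) ms; colour ~ Normal(0, 0.5) logits, along with the other
fixed effects), data are simulated, the model is fitted, and coverage of
the 89% HDI is recorded; by construction the long-run coverage for a
prior-drawn parameter is 89%, so the observed rate tests the sampler and
model code rather than a particular effect size. Nuisance generator
parameters (random-effect SDs, residual scale, ν) are fixed at study-scale
values instead of prior draws: the residual-scale prior is data-dependent
(max(2.5, sd(y))) and hence non-generative, and half-t(3, 2.5) draws for a
millisecond-scale SD would be physically meaningless. This makes the check
approximate for the focal parameter only through second-order nuisance
effects, which the ±8-percentage-point acceptance band absorbs. Replicate
counts (50 in the tests; 40/30 in the acceptance script) and shortened
chain lengths were chosen so one replicate's Monte-Carlo error is small
against that band.

## Numerical choices and limitations

- Unconstrained log-scale parameters beyond ±30 (and |atanh ρ| > 6) are
  rejected before exponentials overflow; such excursions only occur on
  already-unstable trajectories.
- The filtering invariant "fast exclusions = injected anticipatory trials"
  holds exactly only when genuine RTs cannot fall below 200 ms; the test
  uses tight residuals to guarantee this.
- `FilterReport.from_totals` books unknown slow/fast splits as slow;
  retained counts and percentages are unaffected.
- The per-subject dot-probe model deliberately has no pooled variant, and
  the preference model has no stimulus-identity or learning terms,
  mirroring the analysis it implements.
- Deposited-data ingestion is by declared column rename maps only; no
  external column convention is hard-coded.
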