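# pongocog

Bayesian analysis pipeline for two touchscreen cognition experiments with
Bornean orang-utans (*Pongo pygmaeus*): a **dot-probe task** measuring
immediate attention to male secondary sexual characteristics (enlarged
cheek flanges; symmetrised faces) and a **two-alternative preference task**
measuring choice bias for pictures of flanged over unflanged males. The
package is aimed at comparative-cognition researchers who want to re-run,
stress-test or extend this style of small-N animal analysis: every stage —
design-faithful data simulation, reaction-time filtering, model fitting,
temporal-structure testing — is a tested library function with a thin CLI
on top, and every stochastic step is bit-reproducible from a seed.

## What it computes

**RT filtering.** Per subject and task, trials are excluded when
RT > median + 2.5 × MAD (MAD scaled by 1.4826) or RT < 200 ms; excluded
trials are re-run once in repetition sessions and the same rules applied
again. With the published counts this reproduces the study's accounting:
(423−96) + (105−28) = 404 flange trials and (474−102) + (108−32) = 448
symmetry trials retained.

**Dot-probe model.** Per subject, a robust Student-t regression of centred
RT on congruence and probe side (both sum-coded ±1) with session-varying
intercepts:

  rt_c ~ Student-t(ν, α + b_cong·c + b_left·l + u_session, σ),
  α ~ N(0,5), b ~ N(0,10), ν ~ Gamma(2, 0.1), scales ~ half-t(3).

**Preference model.** One Bernoulli mixed model over all subjects' free
choices (1 = flanged picture):

  logit P = α + b_green·g + b_order·o + b_height·h
            + a_subj + s_sess(subj) + c_subj·g,

with Normal(0, 0.5) priors on the logit scale, half-t(3, 2.5) on random
effect SDs, and a correlated subject intercept/colour-slope pair. Effects
are reported as odds ratios (draws exponentiated before summarising).

**Switch test.** Each session's switch count T (adjacent choice changes) is
compared with its null under independence: θ ~ Beta(10, 10) updated by the
session's choices, 10 000 independent series simulated from the posterior,
verdict from the null's 95% highest-density set. An exact 2ⁿ enumeration
oracle validates the Monte-Carlo null for short series.

All posteriors are sampled with the package's Hamiltonian Monte Carlo
engine (analytic gradients, adaptive step size and mass matrix; 4 chains ×
6000 iterations, 1000 warmup by default) and summarised the same way:
posterior median, MAD, 89% highest-density interval, probability of
direction. See `docs/methods.md` for the full model notes.

## Worked example

```bash
pongocog full --seed 11 --out-dir demo_out
```

simulates both experiments at the study's size (3 subjects × 6×24 and 8×20
dot-probe trials; 6 subjects × 6 sessions of 8 forced + 16 choice trials),
filters, fits and tests, writing CSVs plus a summary. A run prints:

```
pongocog pipeline run (mode=full, seed=11)
simulated 912 dot-probe trials, 864 preference trials
flange: 473 collected, 424 retained after repetition merge
  flange/Kawan: b_congruent -0.37 [5.78], pd 0.52
  flange/Samboja: b_congruent 12.82 [6.97], pd 0.96
  flange/Sandy: b_congruent 4.17 [5.82], pd 0.76
symmetry: 535 collected, 471 retained after repetition merge
  symmetry/Kawan: b_congruent -4.90 [6.18], pd 0.78
  symmetry/Samboja: b_congruent -3.92 [5.89], pd 0.75
  symmetry/Sandy: b_congruent -0.42 [6.03], pd 0.53
preference: OR_intercept 1.01, OR_green 0.70, OR_height 9.97
switch test: 1/36 sessions outside the 95% null HDI
total wall time 239.9s
```

Reading the output: "collected" counts primary plus repetition-session
trials, of which 424 survive both filtering rounds. `b_congruent` is the
congruence coefficient in ms on the ±1 coding (condition gap = 2×b) with
its posterior MAD in brackets and the probability of direction — under the
generator's null defaults most subjects sit near pd 0.5–0.8, with an
occasional pd ≈ 0.95 false alarm, exactly the regime such studies report.
`OR_green` below 1 means flanged pictures were chosen less when coded
green (a red bias); `OR_height` far above 1 means the lower-positioned dot
was strongly preferred (its covariate spans only 0.7 screen units, so
large ORs are expected). The switch test flagging 1 of 36 independent
sessions is within its nominal false-alarm rate.

The same stages are available as `simulate`, `analyse`, `filter`,
`fit-dotprobe`, `fit-preference`, `switch-test` and `report` subcommands,
and as
plain library calls (`pongocog.fit_subject`, `pongocog.fit_preference`,
`pongocog.switch_test`, ...). External trial tables with different column
names are ingested via a `rename_map` in the YAML config.

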