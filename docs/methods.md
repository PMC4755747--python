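# Methods

## The model

`gengrad` implements a trial-by-trial model of similarity-based stimulus
generalization for intradimensional discrimination tasks on a circularly
unwrapped orientation axis (degrees). Every orientation *k* carries two
non-negative association strengths, excitatory *E_k* and inhibitory *I_k*.
The net value of the presented stimulus pools the associations of all
previously experienced orientations, weighted by similarity kernels:

    V_k = Σ_j [ E_j · eS(|x_j − x_k|; s_e) − I_j · iS(|x_j − x_k|; s_i) ]

with a Gaussian kernel `exp(−d² / 2s²)` or an exponential kernel
`exp(−d / 2s²)`. The exponential form divides the *first* power of distance
by `2s²`; this non-standard scaling is retained deliberately, so the two
families share the parameterization used when they are compared. A practical
consequence is that exponential widths are not commensurable with Gaussian
widths: an exponential kernel with s ≈ 20° decays over ~800° and is nearly
flat across the task range, whereas s ≈ 3–4° decays over a perceptually
realistic 20–30°. Synthetic cohorts generated under the exponential family
therefore use widths of that order.

Learning is a ratchet: the reward prediction error δ = R − V increments
*E_k* by α·δ when positive and *I_k* by α·|δ| when negative; nothing ever
decays, and only the presented orientation is updated. Associations start at
zero (the unique choice making pre-training V = 0) and are stored sparsely
at presented orientations only. δ = 0 triggers no update. Choice is a biased
logistic read-out, `P(+) = 1 / (1 + exp(−β (V − a)))`, with slope β and
offset a in value units. Separate learning rates apply during reinforced
training (α_train) and the extinction test (α_test); test outcomes are
always R = 0, so test-phase prediction errors equal −V and the model keeps
extinguishing during the test at rate α_test.

## Likelihood and fitting

The pooled log-likelihood sums `log P(response_t)` over all *valid
extinction-test trials* of all subjects under one shared parameter set; the
training phase is run through the same trial loop (it determines the
associative state carried into the test) but contributes no likelihood
terms. This scope matches the definition of the fitted likelihood as the
probability of responses *during test*; a toggle
(`LikelihoodOptions.include_training`) adds training terms. Three-way
responses (+ / − / ×) enter the likelihood as binary "+" versus not-"+"
(P(not +) = 1 − P(+)); `exclude_unsure` drops "×" trials instead. Trials
without a valid response contribute no term but still drive learning — the
stimulus and outcome were experienced (`update_invalid` toggles this).

Fitting is two-stage: α_train is estimated on the combined cohort with all
six parameters free, then fixed at that value while
(s_i, s_e, β, a, α_test) are estimated per group. Optimization is bounded
Nelder–Mead from multiple seeded starts (default 20; kernel widths in
[1, 100]° and learning rates in [10⁻⁴, 1] drawn log-uniformly, β in
[0.1, 20] and a in [−1, 2] uniformly), objective tolerance 10⁻⁶ — below
per-trial likelihood resolution; the best objective across starts wins, ties
going to the earliest start. AIC = 2k − 2·LLE and BIC = k·ln(n) − 2·LLE use
n = number of likelihood-contributing trials. The kernel families are
compared on the combined cohort with all six parameters free per family
(k = 6), by AIC/BIC and by pairing per-subject logistic-regression slopes of
observed responses on modelled P(+) (statsmodels MLE with intercept; perfect
separation is flagged non-finite, a constant predictor NaN).

The likelihood loop is compiled with numba on a packed array layout; a
readable pure-Python reference implementation (`core_model.run_trials`)
computes identical quantities and the test suite asserts agreement to 1e-10,
alongside an independently coded naive trace oracle.

## Gradients and inference

Generalization gradients are per-orientation proportions of "+" responses
among valid test trials, pooled on the mirror-normalized axis (counter-
balanced subjects reflected about the CS midpoint so the CS+ is always on
the low side). The peak-shift statistic is a paired t across subjects of
mean responding on the CS+ side away from the CS− minus the side toward it,
tested one-tailed.

Gradient shape is summarized by the kurtosis of an amplitude-scaled Pearson
type VII curve, `A·(1 + ((x − μ)/σ)²)^(−m)`, fitted to the group-mean
gradient by least squares (the gradient is a mean curve, not a sample, so a
density MLE is not applicable). Kurtosis is the 4th standardized moment of
the fitted density, computed by numerical quadrature on the standard form;
the family is a scaled Student-t with ν = 2m − 1, so quadrature is checked
against the closed form 3(ν − 2)/(ν − 4) and against Monte-Carlo sampling.
For m ≤ 2.5 the 4th moment diverges and the kurtosis is flagged infinite —
this genuinely occurs for narrow-generalization groups whose gradients
combine a sharp peak with elevated far tails.

Permutation tests reshuffle subjects into groups of the original sizes and
recompute the statistic on every relabeling: the kurtosis difference
(per-subject gradient rows are label-invariant, so rows are computed once
and each permutation re-averages a subset and refits the curve — identical
to a full recomputation), or the vector of group-wise fitted-parameter
differences, with α_train held at the full-sample estimate throughout (a
flag refits it per permutation). p = (#{null beyond observed} + 1)/(n_perm
+ 1), one-tailed by default. Permutations whose curve or model fit fails are
re-drawn and counted.

Leave-one-out scores turn the pooled fits into individual-difference
measures: within each group, score = full-group estimate minus the estimate
with that subject excluded, so a subject carrying a large latent parameter
receives a positive score; groups are compared per parameter by one-tailed
two-sample t-tests on the scores. Sub-fit failures leave NaN scores.

## The synthetic cohort generator

No behavioural data are distributed with the study this design follows, so
the generator *is* the data source, and its defaults are the study
conditions: two counterbalanced CS orientations (39°/51°, alternating across
subjects), 100 training repetitions of each CS with exactly half of CS+
trials rewarded (an exact-count schedule, guaranteeing the 50% contingency
in every realization; an i.i.d. Bernoulli mode exists behind a flag), a
15-orientation test ladder (17°–73°, 4° steps, 14 repetitions each, in
extinction), 25 drug-group (PA) and 21 placebo-group (PP) subjects, and
group-level generating parameters

| group | s_i | s_e | β | a | α_test |
|---|---|---|---|---|---|
| PA | 20.121 | 17.599 | 3.093 | 0.370 | 0.002 |
| PP | 30.587 | 24.584 | 3.124 | 0.361 | 0.006 |

α_train is not identified by those group estimates; the default 0.1 was
chosen because generated cohorts then reproduce the known empirical
phenomena — bell-shaped gradients peaking around 0.55–0.6, a peak shift
away from the CS−, and a drug group with a higher, narrower peak, lower
flanks, elevated far tail and larger fitted kurtosis. Faster rates (≥ 0.2)
over-accumulate both association pools across 200 training trials and
invert the peak-height ordering. Trial order is an unconstrained seeded
shuffle; per-subject seeds derive from the master seed by a fixed counter
scheme, so cohorts are bit-reproducible and extensible.

What the generator does *not* emulate: perceptual noise (similarity acts on
the true orientation), response-time structure, lapses/"too slow" trials
(all generated responses are valid), "×" responses (the model defines no
uncertainty report; generative mode emits only +/−), and session effects.
Passing recovery tests therefore show that the estimation machinery is
consistent for data generated by the model itself — not that the model is
identified under misspecification of real behaviour.

## Problem sizes and numerical choices

Validation runs use sizes chosen to keep the full suite fast while leaving
each check statistically meaningful: parameter recovery uses 20 replicate
cohorts at the full study design with 6 optimizer starts per fit (the
default 20 starts change recovered medians negligibly but triple the cost);
kernel-comparison self-consistency uses 10 replicates per generating family
at 6+6 subjects; permutation-calibration meta-simulations use ≥200
meta-replicates at n_perm = 200 with homogeneous cohorts — miniature
model-generated cohorts with single-start capped-iteration fits for the
parameter statistic (permutation validity only requires the statistic to be
a deterministic function of the data, which capped fits are), and
responders whose P(+) profile is itself an interior-shape Pearson VII curve
for the kurtosis statistic (profiles at either shape extreme make the
fitted kurtosis degenerate — ties at the shape ceiling or ±∞ atoms — so
exact uniformity of p-values cannot be observed even though the test stays
valid). Inside permutation loops the Pearson fit is warm-started from the
label-invariant pooled-gradient fit, which leaves the statistic unchanged.
The acceptance script runs one full-size cohort end to end with a reduced
parameter-permutation count (n_perm = 99).

Degenerate inputs are rejected explicitly: flat gradients (unidentifiable
Pearson shape), non-integer exact reinforcement counts, empty orientation
lists, single-class logistic responses, permutation tests with n_perm < 1
or overlapping groups. Runaway association dynamics under pathological
parameter proposals (|V| > 10¹²) short-circuit to a very poor likelihood
rather than overflowing.

## Known limitations

* The pooled MLE treats subjects as exchangeable within group; there is no
  hierarchical structure, so between-subject variance inflates α_test and β
  estimates slightly (visible as mild bias in recovery summaries).
* β and α_train trade off partially when only test responses are scored;
  the two-stage procedure (α_train fixed from the combined fit) mitigates
  but does not remove this.
* The Pearson VII kurtosis is a property of the *fitted* curve; for groups
  whose fitted shape lands near the m = 2.5 boundary, tiny gradient changes
  move the kurtosis from large-finite to infinite. Group comparisons by
  permutation are insensitive to this (only the ordering matters), but the
  point estimate itself is unstable in that regime.
* The exponential similarity family, with the scaling used here, cannot be
  given widths that simultaneously match Gaussian widths numerically and
  behave comparably; comparisons across families should rely on AIC/BIC and
  regression slopes, never on raw width values.
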