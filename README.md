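# gengrad

Similarity-based stimulus-generalization modelling for intradimensional
discrimination experiments: trial-by-trial excitatory/inhibitory association
learning with Gaussian or exponential similarity kernels, pooled
maximum-likelihood fitting, kernel comparison, permutation inference on
group parameters and gradient kurtosis, leave-one-out individual estimates,
and a synthetic-cohort generator that reproduces the study design end to
end.

## The problem

In intradimensional discrimination, one stimulus orientation (the CS+) is
probabilistically rewarded and a nearby orientation (the CS−) never is.
When novel orientations are then probed in extinction, responding traces a
bell-shaped *generalization gradient* around the CS+, typically with a
*peak shift* away from the CS−. The scientific questions are how wide
generalization is, and what changes it — e.g. a pharmacological manipulation
administered only at test.

`gengrad` is for researchers who want to fit and compare computational
accounts of such gradients. The model assigns every experienced orientation
*k* excitatory and inhibitory associations *E_k*, *I_k*; the value of the
presented stimulus pools all of them, weighted by similarity:

    V_k = Σ_j  E_j · exp(−(x_j−x_k)² / 2s_e²) − I_j · exp(−(x_j−x_k)² / 2s_i²)

(or exponential kernels `exp(−|x_j−x_k| / 2s²)`). The widths **s_e** and
**s_i** are the model's measures of generalization breadth. Prediction
errors δ = R − V ratchet the associations (δ>0 feeds *E*, δ<0 feeds *I*)
with separate learning rates for training (α_train) and the extinction test
(α_test), and choice is logistic in value:
P(+) = 1 / (1 + exp(−β(V − a))).

Parameters are estimated by pooled maximum likelihood over all valid test
responses of a group, in two stages (α_train estimated on everyone, then
fixed for group-wise fits). Inference uses group-size-preserving permutation
tests, Pearson type VII kurtosis of the mean gradient, and leave-one-out
jackknife scores. Because behavioural data for this design are not publicly
deposited, the package ships a generator that simulates full cohorts from
group-level parameters, making every stage verifiable by parameter
recovery. See `docs/methods.md` for the full model and design choices.

## Worked example

```python
from gengrad import (
    CohortSpec, FitConfig, simulate_cohort,
    fit_alpha_train, fit_group, behavioral_gradient, peak_shift_statistic,
)

# 25 + 21 subjects at the default group parameters, full study design
cohort, manifest = simulate_cohort(CohortSpec(master_seed=5))

config = FitConfig(n_starts=6, seed=42)
a_train = fit_alpha_train(cohort, "gaussian", config)
pa = fit_group([s for s in cohort if s.group == "PA"], a_train, "gaussian", config)
pp = fit_group([s for s in cohort if s.group == "PP"], a_train, "gaussian", config)
print(f"alpha_train = {a_train:.4f}")
print(f"PA: s_e = {pa.params.s_e:.2f}  s_i = {pa.params.s_i:.2f}")
print(f"PP: s_e = {pp.params.s_e:.2f}  s_i = {pp.params.s_i:.2f}")
shift = peak_shift_statistic(cohort)
print(f"peak shift: t = {shift.statistic:.2f}, one-tailed p = {shift.p_value:.2g}")
```

Output:

```
alpha_train = 0.0833
PA: s_e = 16.83  s_i = 19.47
PP: s_e = 21.56  s_i = 25.87
peak shift: t = 23.82, one-tailed p = 1.9e-27
```

The fitted widths recover the generating values (PA: s_e 17.6, s_i 20.1;
PP: s_e 24.6, s_i 30.6) to within sampling error of one cohort, the drug
group comes out narrower on both kernels (s_e and s_i smaller for PA), and
the strongly positive paired t confirms the peak shift: subjects respond
more on the side of the CS+ that faces away from the CS−.

The same stages are scriptable from the shell:

```sh
gengrad fit --seed 5                  # simulate + two-stage MLE
gengrad kurtosis --n-perm 2000        # gradient kurtosis + permutation test
gengrad recovery --replicates 20      # parameter-recovery experiment
```

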