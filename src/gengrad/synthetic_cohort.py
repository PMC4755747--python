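"""Synthetic subjects and cohorts generated from the model itself.

The generator reproduces the study design end to end: two counterbalanced CS
orientations (39 and 51 degrees), 100 training repetitions of each CS with
exact 50% reinforcement of the CS+, and a 15-orientation extinction test
(17-73 degrees, 4-degree steps) with 14 repetitions each.  Behaviour is
produced by running the generalization model generatively with group-level
parameters; the published group estimates serve as the default generating
truth for the drug (PA) and placebo (PP) groups, so the whole fitting and
inference pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import Kernel, ModelParams, run_trials
from .fitting import FitConfig, SubjectData, fit_alpha_train, fit_group
from .task_design import (
    StimulusSpec,
    make_test_schedule,
    make_training_schedule,
)

__all__ = [
    "PA_PARAMS",
    "PP_PARAMS",
    "DEFAULT_GROUP_SIZES",
    "CohortSpec",
    "simulate_subject",
    "simulate_cohort",
    "recovery_experiment",
    "RecoveryReport",
]

#: Default training learning rate for generated agents.  The group estimates
#: below come from test-phase behaviour and do not pin down training speed.
#: 0.1 is the rate at which agents acquire the discrimination over the first
#: quarter of training and the two generated groups reproduce the known
#: gradient differences (higher/narrower drug-group peak, lower flanks,
#: elevated far tail, larger fitted kurtosis); faster rates over-accumulate
#: associations and invert the peak-height ordering.
DEFAULT_ALPHA_TRAIN = 0.1

#: Group-level parameter estimates used as the default generating truth.
PA_PARAMS = ModelParams(
    s_i=20.121, s_e=17.599, beta=3.093, offset_a=0.370,
    alpha_train=DEFAULT_ALPHA_TRAIN, alpha_test=0.002, kernel="gaussian",
)
PP_PARAMS = ModelParams(
    s_i=30.587, s_e=24.584, beta=3.124, offset_a=0.361,
    alpha_train=DEFAULT_ALPHA_TRAIN, alpha_test=0.006, kernel="gaussian",
)

DEFAULT_GROUP_SIZES: dict[str, int] = {"PA": 25, "PP": 21}


def _child_seeds(seed_key: Sequence[int], n: int) -> list[int]:
    """Deterministic 31-bit child seeds from a counter-keyed seed sequence."""
    state = np.random.SeedSequence(list(seed_key)).generate_state(n, dtype=np.uint32)
    return [int(x & 0x7FFFFFFF) for x in state]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated cohort.

    Defaults mirror the study exactly: 25 PA + 21 PP subjects, 100 training
    repetitions per CS at 50% exact-count reinforcement, 14 repetitions of
    each of 15 test orientations, CS-role counterbalancing alternating across
    subjects within each group.
    """

    group_params: Mapping[str, ModelParams] = field(
        default_factory=lambda: {"PA": PA_PARAMS, "PP": PP_PARAMS}
    )
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_reps: int = 100
    p_reward: float = 0.5
    n_reps_test: int = 14
    exact_reinforcement: bool = True
    counterbalance: bool = True
    base_spec: StimulusSpec = field(default_factory=StimulusSpec)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group_params) != set(self.group_sizes):
            raise ValueError("group_params and group_sizes must name the same groups")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least one subject")


def simulate_subject(
    params: ModelParams,
    spec: StimulusSpec,
    n_reps: int = 100,
    p_reward: float = 0.5,
    n_reps_test: int = 14,
    seed: int = 0,
    subject_id: str = "S00",
    group: str = "NA",
    exact_reinforcement: bool = True,
) -> SubjectData:
    """Simulate one agent: build seeded schedules, run the model generatively
    through training and (with carried associative state) through test."""
    s_train, s_test, b_train, b_test = _child_seeds([int(seed)], 4)
    training = make_training_schedule(
        spec, n_reps=n_reps, p_reward=p_reward, seed=s_train, exact=exact_reinforcement
    )
    test = make_test_schedule(spec, n_reps_test=n_reps_test, seed=s_test)
    run_tr = run_trials(params, training, mode="generative", seed=b_train)
    run_te = run_trials(
        params, test, mode="generative", seed=b_test, initial_state=run_tr.final_state
    )
    return SubjectData(
        subject_id=subject_id,
        group=group,
        spec=spec,
        training=run_tr.schedule,
        test=run_te.schedule,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[SubjectData], pd.DataFrame]:
    """Simulate a full cohort; returns the subjects and a manifest table
    (subject_id, group, cs_plus_deg) describing counterbalance assignment."""
    subjects: list[SubjectData] = []
    rows = []
    global_index = 0
    for group in sorted(spec.group_sizes):
        params = spec.group_params[group]
        for i in range(spec.group_sizes[group]):
            stim = spec.base_spec
            if spec.counterbalance and i % 2 == 1:
                stim = stim.swapped()
            (subject_seed,) = _child_seeds([spec.master_seed, global_index], 1)
            sid = f"{group}{i + 1:02d}"
            subjects.append(
                simulate_subject(
                    params,
                    stim,
                    n_reps=spec.n_reps,
                    p_reward=spec.p_reward,
                    n_reps_test=spec.n_reps_test,
                    seed=subject_seed,
                    subject_id=sid,
                    group=group,
                    exact_reinforcement=spec.exact_reinforcement,
                )
            )
            rows.append({"subject_id": sid, "group": group, "cs_plus_deg": stim.cs_plus})
            global_index += 1
    return subjects, pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryReport:
    """Replicate-level parameter-recovery records with summary helpers."""

    records: pd.DataFrame  # replicate, group, parameter, true, recovered
    alpha_train_estimates: pd.DataFrame  # replicate, estimate
    failures: tuple[int, ...]

    def summary(self) -> pd.DataFrame:
        """Per group x parameter: median recovered value, bias, median
        relative error (|recovered - true| / |true|)."""
        rec = self.records.copy()
        rec["rel_error"] = (rec["recovered"] - rec["true"]).abs() / rec["true"].abs()
        out = (
            rec.groupby(["group", "parameter"])
            .agg(
                true=("true", "first"),
                median_recovered=("recovered", "median"),
                bias=("recovered", lambda v: v.mean()),
                median_rel_error=("rel_error", "median"),
            )
            .reset_index()
        )
        out["bias"] -= out["true"]
        return out

    def sign_rate(self, parameter: str, group_a: str, group_b: str) -> float:
        """Fraction of replicates in which recovered ``parameter`` differs
        between groups in the same direction as the generating truth."""
        rec = self.records[self.records["parameter"] == parameter]
        piv = rec.pivot_table(
            index="replicate", columns="group", values=["recovered", "true"]
        )
        diff = piv[("recovered", group_a)] - piv[("recovered", group_b)]
        true_diff = piv[("true", group_a)] - piv[("true", group_b)]
        return float(np.mean(np.sign(diff) == np.sign(true_diff)))


_RECOVERED = ("s_i", "s_e", "beta", "offset_a", "alpha_test")


def recovery_experiment(
    cohort_spec: CohortSpec = CohortSpec(),
    replicates: int = 20,
    seed: int = 0,
    fit_config: FitConfig = FitConfig(n_starts=6),
    kernel: Kernel = "gaussian",
) -> RecoveryReport:
    """Simulate -> two-stage fit -> compare recovered vs generating parameters.

    Each replicate draws a fresh cohort (replicate-keyed seeds), estimates
    alpha_train on the combined cohort, then fits each group separately with
    alpha_train fixed.  Fit failures are recorded and the replicate skipped.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows, alphas, failures = [], [], []
    for r in range(replicates):
        m_seed, f_seed = _child_seeds([seed, r], 2)
        spec_r = replace(cohort_spec, master_seed=m_seed)
        cohort, _ = simulate_cohort(spec_r)
        config_r = replace(fit_config, seed=f_seed)
        try:
            a_train = fit_alpha_train(cohort, kernel, config_r)
            for group in sorted(spec_r.group_sizes):
                members = [s for s in cohort if s.group == group]
                fit = fit_group(members, a_train, kernel, config_r)
                truth = spec_r.group_params[group]
                for name in _RECOVERED:
                    rows.append(
                        {
                            "replicate": r,
                            "group": group,
                            "parameter": name,
                            "true": getattr(truth, name),
                            "recovered": getattr(fit.params, name),
                        }
                    )
            alphas.append({"replicate": r, "alpha_train": a_train})
        except Exception:  # noqa: BLE001 - fit failures are data, not bugs
            failures.append(r)
    return RecoveryReport(
        records=pd.DataFrame(rows),
        alpha_train_estimates=pd.DataFrame(alphas),
        failures=tuple(failures),
    )
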