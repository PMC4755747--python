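import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gengrad.core_model import ModelParams
from gengrad.fitting import SubjectData
from gengrad.task_design import (
    Schedule,
    StimulusSpec,
    TrialRecord,
    make_test_schedule,
    make_training_schedule,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_spec() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture(scope="session")
def pa_like_params() -> ModelParams:
    return ModelParams(
        s_i=20.121, s_e=17.599, beta=3.093, offset_a=0.370,
        alpha_train=0.1, alpha_test=0.002,
    )


def random_trials(rng: np.random.Generator, n_train: int = 10, n_test: int = 10) -> list[dict]:
    """Random mixed-phase trial dicts for oracle comparisons."""
    trials = []
    for i in range(n_train):
        trials.append(
            {
                "phase": "training",
                "orientation": float(rng.integers(10, 80)),
                "outcome": int(rng.integers(0, 2)),
                "response": str(rng.choice(["plus", "minus", "unsure"])),
                "valid": bool(rng.random() > 0.1),
            }
        )
    for i in range(n_test):
        trials.append(
            {
                "phase": "test",
                "orientation": float(rng.integers(10, 80)),
                "outcome": 0,
                "response": str(rng.choice(["plus", "minus", "unsure"])),
                "valid": bool(rng.random() > 0.1),
            }
        )
    for tr in trials:
        if not tr["valid"]:
            tr["response"] = "missing"
    return trials


def trials_to_schedules(trials: list[dict], spec: StimulusSpec) -> tuple[Schedule, Schedule]:
    """Pack oracle-style trial dicts into package Schedule objects."""
    by_phase: dict[str, list[TrialRecord]] = {"training": [], "test": []}
    for tr in trials:
        phase = tr["phase"]
        by_phase[phase].append(
            TrialRecord(
                phase=phase,
                index=len(by_phase[phase]),
                orientation=tr["orientation"],
                outcome=tr["outcome"],
                response=tr["response"],
                valid=tr["valid"],
            )
        )
    return (
        Schedule(tuple(by_phase["training"]), spec, seed=-1),
        Schedule(tuple(by_phase["test"]), spec, seed=-1),
    )


def random_params(rng: np.random.Generator, kernel: str = "gaussian") -> ModelParams:
    return ModelParams(
        s_i=float(rng.uniform(3, 40)),
        s_e=float(rng.uniform(3, 40)),
        beta=float(rng.uniform(0.5, 8)),
        offset_a=float(rng.uniform(-0.5, 1.0)),
        alpha_train=float(rng.uniform(0.01, 0.6)),
        alpha_test=float(rng.uniform(0.001, 0.2)),
        kernel=kernel,
    )


def quick_subject(
    rng: np.random.Generator,
    params: ModelParams,
    spec: StimulusSpec,
    subject_id: str = "S01",
    group: str = "G",
    n_reps: int = 10,
    n_reps_test: int = 3,
) -> SubjectData:
    """Small generatively-responded subject for fitting tests."""
    from gengrad.core_model import run_trials

    training = make_training_schedule(spec, n_reps=n_reps, seed=int(rng.integers(2**31)))
    test = make_test_schedule(spec, n_reps_test=n_reps_test, seed=int(rng.integers(2**31)))
    r1 = run_trials(params, training, mode="generative", seed=int(rng.integers(2**31)))
    r2 = run_trials(
        params, test, mode="generative", seed=int(rng.integers(2**31)),
        initial_state=r1.final_state,
    )
    return SubjectData(subject_id, group, spec, r1.schedule, r2.schedule)
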