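"""Similarity-based generalization model of trial-by-trial learning.

Every orientation ``k`` carries separate excitatory and inhibitory association
strengths ``E_k`` and ``I_k``.  The net value of the presented stimulus pools
the associations of *all* previously experienced orientations, weighted by
similarity kernels whose widths ``s_e`` and ``s_i`` set the breadth of
excitatory and inhibitory generalization::

    V_k = sum_j  E_j * eS(|x_j - x_k|; s_e)  -  I_j * iS(|x_j - x_k|; s_i)

The kernels are Gaussian, ``exp(-d^2 / (2 s^2))``, or exponential,
``exp(-d / (2 s^2))``.  A reward prediction error ``delta = R - V`` updates
only the presented orientation: positive errors add to its excitatory
association, negative errors to its inhibitory association (rates are
ratchets; neither strength ever decreases).  Choice is a biased logistic read-out
of value, ``P(+) = 1 / (1 + exp(-beta * (V - a)))``.

Separate learning rates apply during reinforced training (``alpha_train``) and
the extinction test (``alpha_test``); during test R = 0 on every trial, so
prediction errors equal ``-V`` and reflect pure generalized expectation.

The trial runner operates in two modes that share every state computation:
*generative* (sample responses from P(+)) and *likelihood* (score observed
responses, accumulating ``log P(response)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .task_design import Schedule, TrialRecord

__all__ = [
    "ModelParams",
    "AssociativeState",
    "TrialEvaluation",
    "RunResult",
    "generalization_coefficient",
    "net_value",
    "prediction_error",
    "apply_update",
    "response_probability",
    "run_trials",
]

Kernel = Literal["gaussian", "exponential"]


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the generalization model.

    s_i, s_e : widths (degrees) of the inhibitory / excitatory similarity
        kernels — the model's measures of generalization breadth.
    beta, offset_a : slope and offset of the logistic response rule.
    alpha_train, alpha_test : learning rates during training / extinction test.
    kernel : similarity-function family, ``gaussian`` or ``exponential``.
    """

    s_i: float
    s_e: float
    beta: float
    offset_a: float
    alpha_train: float
    alpha_test: float
    kernel: Kernel = "gaussian"

    def __post_init__(self) -> None:
        if self.s_i <= 0 or self.s_e <= 0:
            raise ValueError("kernel widths s_i, s_e must be positive")
        if self.beta <= 0:
            raise ValueError("softmax slope beta must be positive")
        if not (0.0 <= self.alpha_train <= 1.0 and 0.0 <= self.alpha_test <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.kernel not in ("gaussian", "exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    def alpha_for(self, phase: str) -> float:
        return self.alpha_train if phase == "training" else self.alpha_test


class AssociativeState:
    """Sparse map orientation -> (E, I) association strengths.

    Entries exist only for orientations presented so far; absent orientations
    hold zero associations (the update rule only ever touches the presented
    stimulus).  Both strengths are non-negative and non-decreasing in time.
    """

    __slots__ = ("_assoc",)

    def __init__(self, assoc: Optional[dict[float, tuple[float, float]]] = None):
        self._assoc: dict[float, tuple[float, float]] = dict(assoc or {})
        for x, (e, i) in self._assoc.items():
            if e < 0 or i < 0:
                raise ValueError(f"negative association strength at {x}")

    def excitatory(self, x: float) -> float:
        return self._assoc.get(float(x), (0.0, 0.0))[0]

    def inhibitory(self, x: float) -> float:
        return self._assoc.get(float(x), (0.0, 0.0))[1]

    @property
    def orientations(self) -> list[float]:
        return sorted(self._assoc)

    def as_dict(self) -> dict[float, tuple[float, float]]:
        return dict(self._assoc)

    def copy(self) -> "AssociativeState":
        return AssociativeState(self._assoc)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AssociativeState) and self._assoc == other._assoc

    def __repr__(self) -> str:
        return f"AssociativeState({self._assoc!r})"


def generalization_coefficient(
    distance: Union[float, np.ndarray], width: float, kernel: Kernel = "gaussian"
) -> Union[float, np.ndarray]:
    """Similarity weight in (0, 1] between two stimuli ``distance`` degrees apart.

    Gaussian: ``exp(-d^2 / (2 w^2))``; exponential: ``exp(-d / (2 w^2))``.
    Equals 1 at zero distance and decreases strictly with distance.
    """
    if width <= 0:
        raise ValueError("kernel width must be positive")
    d = np.abs(np.asarray(distance, dtype=float))
    if kernel == "gaussian":
        out = np.exp(-(d**2) / (2.0 * width**2))
    elif kernel == "exponential":
        out = np.exp(-d / (2.0 * width**2))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return float(out) if np.isscalar(distance) else out


def net_value(state: AssociativeState, params: ModelParams, x_k: float) -> float:
    """Net associative strength V of orientation ``x_k`` under ``state``."""
    v = 0.0
    for x_j, (e_j, i_j) in state.as_dict().items():
        d = abs(x_j - float(x_k))
        v += e_j * generalization_coefficient(d, params.s_e, params.kernel)
        v -= i_j * generalization_coefficient(d, params.s_i, params.kernel)
    return v


def prediction_error(outcome: float, value: float) -> float:
    """Reward prediction error ``delta = R - V`` (exactly)."""
    return float(outcome) - float(value)


def apply_update(
    state: AssociativeState, k: float, delta: float, alpha: float
) -> AssociativeState:
    """Return the state after learning from ``delta`` at orientation ``k``.

    ``delta > 0`` increments E_k by ``alpha * delta``; ``delta < 0`` increments
    I_k by ``alpha * |delta|``; ``delta == 0`` leaves the state untouched.  No
    other orientation changes.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if delta == 0.0:
        return state.copy()
    assoc = state.as_dict()
    k = float(k)
    e, i = assoc.get(k, (0.0, 0.0))
    if delta > 0:
        e += alpha * delta
    else:
        i -= alpha * delta
    assoc[k] = (e, i)
    return AssociativeState(assoc)


def response_probability(value: float, beta: float, offset_a: float) -> float:
    """Probability of an approach ("+") response: logistic in V with slope
    ``beta``, crossing 0.5 exactly at ``V = offset_a``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = beta * (float(value) - float(offset_a))
    # evaluate as exp of the stable log to keep p in the open interval
    return math.exp(_log_sigmoid(z))


def _log_sigmoid(z: float) -> float:
    """log(1 / (1 + exp(-z))), numerically stable for any finite z."""
    if z >= 0:
        return -math.log1p(math.exp(-z))
    return z - math.log1p(math.exp(z))


@dataclass(frozen=True)
class TrialEvaluation:
    """Per-trial model quantities: value, choice probability, prediction
    error, and (likelihood mode, scored trials only) the log-probability of
    the observed response."""

    trial: TrialRecord
    V: float
    p_plus: float
    delta: float
    loglik_term: Optional[float] = None


@dataclass(frozen=True)
class RunResult:
    evaluations: tuple[TrialEvaluation, ...]
    final_state: AssociativeState
    loglik: Optional[float]
    schedule: Schedule


def run_trials(
    params: ModelParams,
    schedule: Schedule,
    mode: Literal["likelihood", "generative"] = "likelihood",
    seed: Optional[Union[int, np.random.Generator]] = None,
    initial_state: Optional[AssociativeState] = None,
    exclude_unsure: bool = False,
    update_invalid: bool = True,
) -> RunResult:
    """Run the model through a schedule in order.

    Each trial computes ``V`` -> ``P(+)`` -> response -> ``delta = R - V`` ->
    association update with the phase-appropriate learning rate.  In
    *likelihood* mode the observed responses stored on the schedule are
    scored: ``log P(+)`` for "+" responses and ``log(1 - P(+))`` otherwise,
    on valid trials only (set ``exclude_unsure`` to drop "x" responses from
    the likelihood instead of scoring them as non-"+").  Invalid trials
    contribute no term but still drive value computation and learning (the
    stimulus and outcome were experienced); set ``update_invalid=False`` to
    skip their updates.  In *generative* mode responses are sampled
    ("+" with probability P(+), else "-"), seeded-deterministically.
    """
    if mode not in ("likelihood", "generative"):
        raise ValueError(f"unknown mode {mode!r}")
    rng: Optional[np.random.Generator] = None
    if mode == "generative":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    state = (initial_state or AssociativeState()).copy()
    evaluations: list[TrialEvaluation] = []
    responses: list[Optional[str]] = []
    total_ll = 0.0

    for trial in schedule.trials:
        v = net_value(state, params, trial.orientation)
        z = params.beta * (v - params.offset_a)
        p = math.exp(_log_sigmoid(z))

        ll_term: Optional[float] = None
        if mode == "generative":
            resp = "plus" if rng.random() < p else "minus"
            responses.append(resp)
        else:
            resp = trial.response
            if trial.valid and resp in (None, "missing"):
                raise ValueError(
                    f"likelihood mode requires an observed response on valid "
                    f"trial {trial.index} ({trial.phase})"
                )
            if trial.valid and not (exclude_unsure and resp == "unsure"):
                if resp == "plus":
                    ll_term = _log_sigmoid(z)
                else:
                    ll_term = _log_sigmoid(-z)
                total_ll += ll_term

        delta = prediction_error(trial.outcome, v)
        evaluations.append(TrialEvaluation(trial, v, p, delta, ll_term))
        if trial.valid or update_invalid:
            state = apply_update(
                state, trial.orientation, delta, params.alpha_for(trial.phase)
            )

    if mode == "generative":
        out_schedule = schedule.with_responses(responses)
        loglik = None
    else:
        out_schedule = schedule
        loglik = total_ll
    return RunResult(tuple(evaluations), state, loglik, out_schedule)
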