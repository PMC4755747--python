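"""Trial schedules for an intradimensional orientation-discrimination task.

Two Gabor orientations serve as conditioned stimuli: the CS+ is rewarded
probabilistically during training, the CS- never is.  Generalization is then
probed in extinction with a ladder of novel orientations bracketing both CSs.
This module builds and validates those schedules and provides the mirror
normalization used to pool counterbalanced subjects onto one canonical axis
(CS+ on the low-orientation side).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_TEST_ORIENTATIONS",
    "StimulusSpec",
    "TrialRecord",
    "Schedule",
    "make_training_schedule",
    "make_test_schedule",
    "mirror_normalize",
]

#: Test ladder used throughout: 17..73 degrees in 4-degree steps (15 values),
#: bracketing the 39/51-degree conditioned stimuli, which are never retested.
DEFAULT_TEST_ORIENTATIONS: tuple[float, ...] = tuple(float(x) for x in range(17, 74, 4))

Phase = Literal["training", "test"]

RESPONSES = ("plus", "minus", "unsure", "missing")


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus geometry of one subject's task.

    ``cs_plus``/``cs_minus`` are the trained orientations in degrees;
    ``test_orientations`` is the strictly increasing extinction-test ladder,
    which must not contain either CS.
    """

    cs_plus: float = 39.0
    cs_minus: float = 51.0
    test_orientations: tuple[float, ...] = DEFAULT_TEST_ORIENTATIONS

    def __post_init__(self) -> None:
        if self.cs_plus == self.cs_minus:
            raise ValueError("cs_plus and cs_minus must differ")
        orients = tuple(float(x) for x in self.test_orientations)
        if len(orients) == 0:
            raise ValueError("test_orientations must not be empty")
        if any(b <= a for a, b in zip(orients, orients[1:])):
            raise ValueError("test_orientations must be strictly increasing")
        if float(self.cs_plus) in orients or float(self.cs_minus) in orients:
            raise ValueError("CS orientations must not appear among test orientations")
        object.__setattr__(self, "cs_plus", float(self.cs_plus))
        object.__setattr__(self, "cs_minus", float(self.cs_minus))
        object.__setattr__(self, "test_orientations", orients)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.cs_plus + self.cs_minus)

    def swapped(self) -> "StimulusSpec":
        """Same geometry with the CS roles exchanged (counterbalancing)."""
        return replace(self, cs_plus=self.cs_minus, cs_minus=self.cs_plus)


@dataclass(frozen=True)
class TrialRecord:
    """One trial: phase, ordinal index, stimulus, scheduled outcome, response.

    ``outcome`` is the scheduled reinforcer R (1 = reward, 0 = nothing); test
    trials are in extinction and always carry R = 0.  ``response`` is one of
    ``plus``/``minus``/``unsure``/``missing`` or ``None`` when not yet made;
    a ``missing`` response forces ``valid=False``.
    """

    phase: Phase
    index: int
    orientation: float
    outcome: int
    response: Optional[str] = None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.phase not in ("training", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")
        if self.phase == "test" and self.outcome != 0:
            raise ValueError("test trials are in extinction: outcome must be 0")
        if self.response is not None and self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.response == "missing" and self.valid:
            raise ValueError("missing responses must be marked invalid")


@dataclass(frozen=True)
class Schedule:
    """An ordered, seeded-deterministic sequence of trials."""

    trials: tuple[TrialRecord, ...]
    stimulus_spec: StimulusSpec
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def orientations(self) -> np.ndarray:
        return np.array([t.orientation for t in self.trials], dtype=float)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials], dtype=float)

    @property
    def responses(self) -> list[Optional[str]]:
        return [t.response for t in self.trials]

    @property
    def valid(self) -> np.ndarray:
        return np.array([t.valid for t in self.trials], dtype=bool)

    def with_responses(
        self, responses: Sequence[Optional[str]], valid: Optional[Sequence[bool]] = None
    ) -> "Schedule":
        """Copy of the schedule with responses (and optionally validity) filled in."""
        if len(responses) != len(self.trials):
            raise ValueError("one response per trial required")
        if valid is None:
            valid = [r != "missing" for r in responses]
        new = tuple(
            replace(t, response=r, valid=bool(v))
            for t, r, v in zip(self.trials, responses, valid)
        )
        return replace(self, trials=new)


def make_training_schedule(
    spec: StimulusSpec,
    n_reps: int = 100,
    p_reward: float = 0.5,
    seed: int = 0,
    exact: bool = True,
) -> Schedule:
    """Training schedule: ``n_reps`` CS+ and ``n_reps`` CS- trials, shuffled.

    With ``exact=True`` (default) exactly ``p_reward * n_reps`` CS+ trials are
    rewarded — the contingency is guaranteed in every realization, so
    ``p_reward * n_reps`` must be an integer.  With ``exact=False`` each CS+
    trial is rewarded independently with probability ``p_reward``.  CS- trials
    are never rewarded.  The trial order is a seeded unconstrained shuffle.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError("p_reward must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if exact:
        n_rewarded_f = p_reward * n_reps
        n_rewarded = int(round(n_rewarded_f))
        if abs(n_rewarded_f - n_rewarded) > 1e-9:
            raise ValueError(
                f"exact-count reinforcement requires p_reward*n_reps to be an "
                f"integer; got {p_reward} * {n_reps} = {n_rewarded_f}"
            )
        plus_outcomes = np.zeros(n_reps, dtype=int)
        plus_outcomes[:n_rewarded] = 1
    else:
        plus_outcomes = (rng.random(n_reps) < p_reward).astype(int)
    pairs = [(spec.cs_plus, int(r)) for r in plus_outcomes]
    pairs += [(spec.cs_minus, 0)] * n_reps
    order = rng.permutation(len(pairs))
    trials = tuple(
        TrialRecord("training", i, pairs[j][0], pairs[j][1])
        for i, j in enumerate(order)
    )
    return Schedule(trials, spec, int(seed))


def make_test_schedule(
    spec: StimulusSpec, n_reps_test: int = 14, seed: int = 0
) -> Schedule:
    """Extinction-test schedule: each test orientation ``n_reps_test`` times,
    shuffled, all outcomes 0."""
    if n_reps_test < 1:
        raise ValueError("n_reps_test must be >= 1")
    rng = np.random.default_rng(seed)
    orients = np.repeat(np.asarray(spec.test_orientations, dtype=float), n_reps_test)
    order = rng.permutation(orients.size)
    trials = tuple(
        TrialRecord("test", i, float(orients[j]), 0) for i, j in enumerate(order)
    )
    return Schedule(trials, spec, int(seed))


def mirror_normalize(orientations: Iterable[float], spec: StimulusSpec) -> np.ndarray:
    """Reflect orientations about the CS midpoint when the CS+ is on the high
    side, so the CS+ always lies on the canonical low side.

    Applying the transform twice with the CS roles swapped recovers the input
    (involution on the mirrored branch); subjects counterbalanced in either
    direction can therefore be pooled on one axis.
    """
    arr = np.asarray(list(orientations) if not isinstance(orientations, np.ndarray) else orientations, dtype=float)
    if spec.cs_plus > spec.cs_minus:
        return 2.0 * spec.midpoint - arr
    return arr.copy()
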