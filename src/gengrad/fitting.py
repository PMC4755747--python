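"""Pooled maximum-likelihood estimation and kernel comparison.

Parameters are estimated by maximizing the summed log-likelihood of all
subjects' valid extinction-test responses under one shared parameter set
(pooled MLE).  Fitting is two-stage: the training learning rate is first
estimated on the combined cohort with all six parameters free, then fixed
while the remaining five parameters are estimated per group.  Kernel families
(Gaussian vs exponential similarity) are compared on the combined cohort via
AIC/BIC and via per-subject logistic regressions of observed responses on the
modelled choice probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _engine
from .core_model import Kernel, ModelParams
from .task_design import Schedule, StimulusSpec

__all__ = [
    "SubjectData",
    "LikelihoodOptions",
    "FitConfig",
    "FitResult",
    "FitFailure",
    "KernelComparison",
    "compile_cohort",
    "pooled_negative_loglik",
    "fit_group",
    "fit_all_subjects",
    "fit_alpha_train",
    "information_criteria",
    "per_subject_logistic",
    "subject_p_plus",
    "compare_kernels",
]


@dataclass(frozen=True)
class SubjectData:
    """One subject's complete data: spec (with their counterbalanced CS+),
    responded training schedule, and responded extinction-test schedule."""

    subject_id: str
    group: str
    spec: StimulusSpec
    training: Schedule
    test: Schedule


@dataclass(frozen=True)
class LikelihoodOptions:
    """Toggles for how observed responses enter the likelihood.

    include_training : score training-phase responses too (default: the
        likelihood covers extinction-test responses only; training still
        drives learning).
    exclude_unsure : drop "x" responses from the likelihood instead of
        scoring them as non-"+".
    update_invalid : whether trials without a valid response still trigger
        learning (the stimulus and outcome were experienced).
    """

    include_training: bool = False
    exclude_unsure: bool = False
    update_invalid: bool = True


@dataclass(frozen=True)
class CompiledCohort:
    """Cohort packed into flat arrays for the compiled trial loop."""

    orientations: np.ndarray  # unique orientation grid (degrees)
    dist: np.ndarray  # pairwise |difference| on the grid
    stim_idx: np.ndarray
    outcome: np.ndarray
    resp_plus: np.ndarray
    use_ll: np.ndarray
    is_train: np.ndarray
    do_update: np.ndarray
    ptr: np.ndarray  # subject boundaries into the stacked arrays
    test_mask: np.ndarray  # test-phase trials (for per-subject extraction)
    subject_ids: tuple[str, ...]
    n_obs: int  # number of likelihood-contributing trials

    def subject_slice(self, i: int) -> slice:
        return slice(int(self.ptr[i]), int(self.ptr[i + 1]))


def compile_cohort(
    cohort: Sequence[SubjectData], options: LikelihoodOptions = LikelihoodOptions()
) -> CompiledCohort:
    """Pack a cohort into the stacked-array layout of the compiled engine."""
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one subject")
    grid = sorted(
        {t.orientation for s in cohort for t in (*s.training.trials, *s.test.trials)}
    )
    orient = np.asarray(grid, dtype=float)
    index = {x: i for i, x in enumerate(grid)}
    dist = np.abs(orient[:, None] - orient[None, :])

    stim, outc, resp, usell, istr, updt = [], [], [], [], [], []
    ptr = [0]
    for s in cohort:
        for sched, training in ((s.training, True), (s.test, False)):
            for t in sched.trials:
                stim.append(index[t.orientation])
                outc.append(float(t.outcome))
                resp.append(1 if t.response == "plus" else 0)
                scored = t.valid and (training is False or options.include_training)
                if options.exclude_unsure and t.response == "unsure":
                    scored = False
                if scored and t.response in (None, "missing"):
                    raise ValueError(
                        f"subject {s.subject_id}: valid trial without observed response"
                    )
                usell.append(scored)
                istr.append(training)
                updt.append(t.valid or options.update_invalid)
        ptr.append(len(stim))

    return CompiledCohort(
        orientations=orient,
        dist=dist,
        stim_idx=np.asarray(stim, dtype=np.int64),
        outcome=np.asarray(outc, dtype=float),
        resp_plus=np.asarray(resp, dtype=np.int8),
        use_ll=np.asarray(usell, dtype=np.bool_),
        is_train=np.asarray(istr, dtype=np.bool_),
        do_update=np.asarray(updt, dtype=np.bool_),
        ptr=np.asarray(ptr, dtype=np.int64),
        test_mask=~np.asarray(istr, dtype=np.bool_),
        subject_ids=tuple(s.subject_id for s in cohort),
        n_obs=int(np.sum(usell)),
    )


def _engine_loglik(params: ModelParams, compiled: CompiledCohort) -> float:
    return _engine.loglik_stacked(
        compiled.dist,
        params.kernel == "gaussian",
        params.s_i,
        params.s_e,
        params.beta,
        params.offset_a,
        params.alpha_train,
        params.alpha_test,
        compiled.stim_idx,
        compiled.outcome,
        compiled.resp_plus,
        compiled.use_ll,
        compiled.is_train,
        compiled.do_update,
        compiled.ptr,
    )


def pooled_negative_loglik(
    params: ModelParams,
    cohort: Sequence[SubjectData] | CompiledCohort,
    options: LikelihoodOptions = LikelihoodOptions(),
) -> float:
    """Negative pooled log-likelihood of a cohort under ``params``.

    Each subject starts from zero associations; their state evolves through
    training into test.  The objective is additive over subjects.
    """
    compiled = cohort if isinstance(cohort, CompiledCohort) else compile_cohort(cohort, options)
    return -_engine_loglik(params, compiled)


# ---------------------------------------------------------------------------
# Optimization


#: Parameter boxes for the bounded multi-start search.  Kernel widths and
#: learning rates are drawn log-uniformly from their boxes; slope and offset
#: uniformly.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "s_i": (1.0, 100.0),
    "s_e": (1.0, 100.0),
    "beta": (0.1, 20.0),
    "offset_a": (-1.0, 2.0),
    "alpha_test": (1e-4, 1.0),
    "alpha_train": (1e-4, 1.0),
}

_LOG_SCALE = {"s_i", "s_e", "alpha_test", "alpha_train"}


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration for the pooled MLE.

    Bounded Nelder–Mead from ``n_starts`` seeded random starting points; the
    best objective across starts wins (ties broken by first start index).
    """

    n_starts: int = 20
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fatol: float = 1e-6
    xatol: float = 1e-4
    maxfev: Optional[int] = None
    extra_starts: tuple[tuple[float, ...], ...] = ()  # appended verbatim
    options: LikelihoodOptions = LikelihoodOptions()


@dataclass(frozen=True)
class StartDiagnostic:
    start_index: int
    x0: tuple[float, ...]
    objective: float
    n_evaluations: int
    converged: bool


@dataclass(frozen=True)
class FitResult:
    """Best-of-starts pooled MLE with information criteria.

    ``aic = 2 k - 2 LLE`` and ``bic = k ln(n) - 2 LLE`` where ``k`` is the
    number of free parameters and ``n`` the number of likelihood trials.
    """

    params: ModelParams
    pooled_lle: float
    n_obs: int
    n_free: int
    aic: float
    bic: float
    free_names: tuple[str, ...]
    diagnostics: tuple[StartDiagnostic, ...]

    def as_dict(self) -> dict:
        return {
            "params": {
                "s_i": self.params.s_i,
                "s_e": self.params.s_e,
                "beta": self.params.beta,
                "offset_a": self.params.offset_a,
                "alpha_train": self.params.alpha_train,
                "alpha_test": self.params.alpha_test,
                "kernel": self.params.kernel,
            },
            "pooled_lle": self.pooled_lle,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "aic": self.aic,
            "bic": self.bic,
        }


class FitFailure(RuntimeError):
    """Raised when no optimizer start produces a finite objective."""


def information_criteria(pooled_lle: float, n_free: int, n_obs: int) -> tuple[float, float]:
    """AIC and BIC from a pooled log-likelihood."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = 2.0 * n_free - 2.0 * pooled_lle
    bic = n_free * np.log(n_obs) - 2.0 * pooled_lle
    return float(aic), float(bic)


def _draw_starts(names: Sequence[str], config: FitConfig) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    starts = np.empty((config.n_starts, len(names)))
    for j, name in enumerate(names):
        lo, hi = config.bounds[name]
        if name in _LOG_SCALE:
            starts[:, j] = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_starts))
        else:
            starts[:, j] = rng.uniform(lo, hi, config.n_starts)
    return starts


def _fit(
    compiled: CompiledCohort,
    free_names: tuple[str, ...],
    fixed: dict[str, float],
    kernel: Kernel,
    config: FitConfig,
) -> FitResult:
    bounds = optimize.Bounds(
        np.array([config.bounds[n][0] for n in free_names]),
        np.array([config.bounds[n][1] for n in free_names]),
    )

    def build(x: np.ndarray) -> ModelParams:
        kw = dict(fixed)
        kw.update({n: float(v) for n, v in zip(free_names, x)})
        return ModelParams(kernel=kernel, **kw)

    def objective(x: np.ndarray) -> float:
        nll = -_engine_loglik(build(x), compiled)
        return nll if np.isfinite(nll) else 1e15

    starts = _draw_starts(free_names, config)
    if config.extra_starts:
        extra = np.asarray(config.extra_starts, dtype=float)
        if extra.shape[1] != len(free_names):
            raise ValueError(
                f"extra_starts must have {len(free_names)} components {free_names}"
            )
        starts = np.vstack([starts, extra])
    maxfev = config.maxfev or 400 * len(free_names)
    diagnostics = []
    best_x, best_f, best_i = None, np.inf, -1
    for i, x0 in enumerate(starts):
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "fatol": config.fatol,
                "xatol": config.xatol,
                "maxfev": maxfev,
                "adaptive": True,
            },
        )
        diagnostics.append(
            StartDiagnostic(i, tuple(x0), float(res.fun), int(res.nfev), bool(res.success))
        )
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f, best_i = res.x, float(res.fun), i
    if best_x is None or best_f >= 1e14:
        raise FitFailure(
            f"no optimizer start converged to a finite objective "
            f"({config.n_starts} starts; see diagnostics)"
        )
    params = build(best_x)
    lle = -best_f
    aic, bic = information_criteria(lle, len(free_names), compiled.n_obs)
    return FitResult(
        params=params,
        pooled_lle=lle,
        n_obs=compiled.n_obs,
        n_free=len(free_names),
        aic=aic,
        bic=bic,
        free_names=free_names,
        diagnostics=tuple(diagnostics),
    )


def fit_group(
    cohort: Sequence[SubjectData] | CompiledCohort,
    fixed_alpha_train: float,
    kernel: Kernel = "gaussian",
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Pooled MLE of (s_i, s_e, beta, a, alpha_test) with alpha_train fixed."""
    if not 0.0 <= fixed_alpha_train <= 1.0:
        raise ValueError("fixed_alpha_train must lie in [0, 1]")
    compiled = cohort if isinstance(cohort, CompiledCohort) else compile_cohort(cohort, config.options)
    return _fit(
        compiled,
        ("s_i", "s_e", "beta", "offset_a", "alpha_test"),
        {"alpha_train": float(fixed_alpha_train)},
        kernel,
        config,
    )


def fit_all_subjects(
    cohort: Sequence[SubjectData] | CompiledCohort,
    kernel: Kernel = "gaussian",
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Pooled MLE of all six parameters on the combined cohort."""
    compiled = cohort if isinstance(cohort, CompiledCohort) else compile_cohort(cohort, config.options)
    return _fit(
        compiled,
        ("s_i", "s_e", "beta", "offset_a", "alpha_test", "alpha_train"),
        {},
        kernel,
        config,
    )


def fit_alpha_train(
    cohort: Sequence[SubjectData],
    kernel: Kernel = "gaussian",
    config: FitConfig = FitConfig(),
) -> float:
    """Stage-one estimate of the training learning rate on the full cohort
    (all six parameters free; the alpha_train component is returned and is
    then held fixed during group-wise fitting)."""
    return fit_all_subjects(cohort, kernel, config).params.alpha_train


# ---------------------------------------------------------------------------
# Goodness of fit per subject


def subject_p_plus(
    params: ModelParams,
    cohort: Sequence[SubjectData],
    options: LikelihoodOptions = LikelihoodOptions(),
) -> list[pd.DataFrame]:
    """Modelled P(+) for every likelihood-scored trial of each subject.

    Returns one frame per subject with columns ``p_plus`` (model) and
    ``response_plus`` (observed, 1 = "+").
    """
    compiled = compile_cohort(cohort, options)
    V, P = _engine.trace_stacked(
        compiled.dist,
        params.kernel == "gaussian",
        params.s_i,
        params.s_e,
        params.beta,
        params.offset_a,
        params.alpha_train,
        params.alpha_test,
        compiled.stim_idx,
        compiled.outcome,
        compiled.is_train,
        compiled.do_update,
        compiled.ptr,
    )
    frames = []
    for i in range(len(cohort)):
        sl = compiled.subject_slice(i)
        keep = compiled.use_ll[sl]
        frames.append(
            pd.DataFrame(
                {
                    "p_plus": P[sl][keep],
                    "response_plus": compiled.resp_plus[sl][keep].astype(int),
                }
            )
        )
    return frames


def per_subject_logistic(responses: Sequence[int], p_plus: Sequence[float]) -> float:
    """Slope of a maximum-likelihood logistic regression of observed binary
    responses on modelled P(+) (with intercept).

    Returns ``inf`` (with a warning) under perfect separation and ``nan``
    when the predictor is constant (unidentifiable slope).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(responses, dtype=float)
    p = np.asarray(p_plus, dtype=float)
    if y.shape != p.shape:
        raise ValueError("responses and p_plus must be aligned")
    if np.unique(y).size < 2:
        raise ValueError("at least one response of each class is required")
    if np.ptp(p) < 1e-12:
        warnings.warn("constant p_plus: logistic slope unidentifiable", stacklevel=2)
        return np.nan
    X = sm.add_constant(p)
    separated = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        coef = float(fit.params[1])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        warnings.warn("perfect separation: logistic slope is not finite", stacklevel=2)
        return np.inf
    if separated or abs(coef) > 1e6:
        warnings.warn("perfect separation: logistic slope is not finite", stacklevel=2)
        return np.inf if coef > 0 else -np.inf
    return coef


@dataclass(frozen=True)
class KernelComparison:
    """Combined-cohort comparison of the two similarity families."""

    gaussian: FitResult
    exponential: FitResult
    coefficients: pd.DataFrame  # per-subject logistic slopes for each kernel
    t_statistic: float  # paired t on the slopes (gaussian - exponential)
    p_value: float

    @property
    def delta_aic(self) -> float:
        """AIC(gaussian) - AIC(exponential); negative favours Gaussian."""
        return self.gaussian.aic - self.exponential.aic


def compare_kernels(
    cohort: Sequence[SubjectData], config: FitConfig = FitConfig()
) -> KernelComparison:
    """Fit both kernel families to the combined cohort (all six parameters
    free), compare them by AIC/BIC, and pair per-subject logistic slopes."""
    fits = {k: fit_all_subjects(cohort, k, config) for k in ("gaussian", "exponential")}
    slopes: dict[str, list[float]] = {}
    for k, fit in fits.items():
        frames = subject_p_plus(fit.params, cohort, config.options)
        slopes[k] = [
            per_subject_logistic(f["response_plus"], f["p_plus"]) for f in frames
        ]
    coef = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "gaussian": slopes["gaussian"],
            "exponential": slopes["exponential"],
        }
    )
    finite = coef[["gaussian", "exponential"]].apply(np.isfinite).all(axis=1)
    if not finite.all():
        warnings.warn(
            f"{int((~finite).sum())} subject(s) with non-finite logistic slopes "
            "excluded from the paired comparison",
            stacklevel=2,
        )
    paired = coef[finite]
    t, p = stats.ttest_rel(paired["gaussian"], paired["exponential"])
    return KernelComparison(
        gaussian=fits["gaussian"],
        exponential=fits["exponential"],
        coefficients=coef,
        t_statistic=float(t),
        p_value=float(p),
    )
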