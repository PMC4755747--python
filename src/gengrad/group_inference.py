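"""Gradient construction and group-level inference.

Behavioural generalization gradients are the per-orientation proportions of
"+" responses during the extinction test, pooled on the mirror-normalized
axis (CS+ canonically on the low side).  Group comparisons use:

* a peak-shift statistic — paired contrast of responding on the side of the
  CS+ away from the CS- versus the side toward it;
* the kurtosis of a Pearson type VII curve fitted to the group-mean gradient
  (the gradient is bounded and off-centre, so the fourth moment is read off a
  fitted symmetric heavy-tailed family rather than estimated directly);
* permutation tests that reshuffle subjects into groups of the original
  sizes, recomputing the statistic (kurtosis difference, or group-wise fitted
  parameter differences) on every relabeling;
* leave-one-out (jackknife) scores that turn pooled fits into per-subject
  individual-difference measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .fitting import FitConfig, SubjectData, compile_cohort, fit_group
from .task_design import mirror_normalize

__all__ = [
    "GradientSummary",
    "behavioral_gradient",
    "PeakShiftResult",
    "peak_shift_statistic",
    "PearsonVIIFit",
    "fit_pearson7",
    "kurtosis_of_fit",
    "PermutationResult",
    "permutation_test_kurtosis",
    "permutation_test_parameters",
    "LOOEstimates",
    "loo_parameter_scores",
]

Tail = Literal["greater", "less", "two-sided"]


# ---------------------------------------------------------------------------
# Gradients


@dataclass(frozen=True)
class GradientSummary:
    """Per-subject and group-mean P(+) per canonical test orientation."""

    orientations: np.ndarray  # canonical (mirror-normalized) degrees, ascending
    per_subject: pd.DataFrame  # index subject_id, columns orientations
    groups: pd.Series  # subject_id -> group label
    mean: pd.DataFrame  # index group, columns orientations
    sem: pd.DataFrame

    def group_mean(self, group: str) -> np.ndarray:
        return self.mean.loc[group].to_numpy()


def behavioral_gradient(cohort: Sequence[SubjectData]) -> GradientSummary:
    """Proportion of "+" among valid test trials at each mirror-normalized
    orientation, per subject, with group mean and SEM across subjects.

    A subject with zero valid trials at an orientation gets NaN there and is
    excluded from that orientation's group mean (with a warning).
    """
    rows = {}
    groups = {}
    for s in cohort:
        canon = mirror_normalize([t.orientation for t in s.test.trials], s.spec)
        plus = np.array([t.response == "plus" for t in s.test.trials], dtype=float)
        valid = s.test.valid
        frame = pd.DataFrame({"orientation": canon, "plus": plus, "valid": valid})
        frame = frame[frame["valid"]]
        prop = frame.groupby("orientation")["plus"].mean()
        all_orients = np.unique(canon)
        prop = prop.reindex(all_orients)
        if prop.isna().any():
            warnings.warn(
                f"subject {s.subject_id}: no valid trials at "
                f"{[float(o) for o in prop.index[prop.isna()]]}; excluded from "
                "those orientations' group means",
                stacklevel=2,
            )
        rows[s.subject_id] = prop
        groups[s.subject_id] = s.group
    per_subject = pd.DataFrame(rows).T
    per_subject = per_subject[sorted(per_subject.columns)]
    group_ser = pd.Series(groups, name="group")
    mean = per_subject.groupby(group_ser).mean()
    count = per_subject.groupby(group_ser).count()
    sem = per_subject.groupby(group_ser).std(ddof=1) / np.sqrt(count)
    return GradientSummary(
        orientations=np.asarray(per_subject.columns, dtype=float),
        per_subject=per_subject,
        groups=group_ser,
        mean=mean,
        sem=sem,
    )


@dataclass(frozen=True)
class PeakShiftResult:
    statistic: float  # paired t across subjects
    p_value: float
    per_subject: pd.DataFrame  # far-side and near-side mean P(+) per subject


def peak_shift_statistic(
    cohort: Sequence[SubjectData], alternative: Tail = "greater"
) -> PeakShiftResult:
    """Paired test of responding on the CS+ side away from the CS- versus
    the side toward it (a positive statistic is a peak shift).

    Per subject: mean P(+) over canonical orientations below the canonical
    CS+ (farther from the CS-) minus the mean over orientations above it.
    """
    if len(cohort) < 2:
        raise ValueError("peak-shift statistic requires at least 2 subjects")
    gradient = behavioral_gradient(cohort)
    far_rows, near_rows = [], []
    for sid in gradient.per_subject.index:
        subject = next(s for s in cohort if s.subject_id == sid)
        cs_plus_c = float(
            mirror_normalize([subject.spec.cs_plus], subject.spec)[0]
        )
        row = gradient.per_subject.loc[sid]
        orients = np.asarray(row.index, dtype=float)
        far_rows.append(row[orients < cs_plus_c].mean())
        near_rows.append(row[orients > cs_plus_c].mean())
    per_subject = pd.DataFrame(
        {"far_side": far_rows, "near_side": near_rows},
        index=gradient.per_subject.index,
    )
    t, p = stats.ttest_rel(
        per_subject["far_side"], per_subject["near_side"], alternative=alternative
    )
    return PeakShiftResult(statistic=float(t), p_value=float(p), per_subject=per_subject)


# ---------------------------------------------------------------------------
# Pearson type VII gradient shape


@dataclass(frozen=True)
class PearsonVIIFit:
    """Amplitude-scaled Pearson type VII curve fitted to a mean gradient:
    ``A * (1 + ((x - mu)/scale)^2)^(-shape)``."""

    location: float
    scale: float
    shape: float
    amplitude: float
    residual_norm: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.location) / self.scale
        return self.amplitude * (1.0 + z**2) ** (-self.shape)


def _pearson7(x, mu, scale, shape, amp):
    return amp * (1.0 + ((x - mu) / scale) ** 2) ** (-shape)


def fit_pearson7(
    orientations: Sequence[float],
    values: Sequence[float],
    p0: Optional[tuple[float, float, float, float]] = None,
) -> PearsonVIIFit:
    """Least-squares fit of the Pearson VII curve to a mean gradient.

    Deterministic given the starting point (default: peak location/height of
    the data, scale 10 degrees, shape 3).  Raises on degenerate (flat) input
    or non-convergence.
    """
    x = np.asarray(orientations, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValueError("orientations and values must be aligned")
    if x.size < 5:
        raise ValueError("at least 5 gradient points are required")
    if np.ptp(y) < 1e-9:
        raise ValueError("degenerate (flat) gradient: shape is unidentifiable")
    if p0 is None:
        p0 = (float(x[np.argmax(y)]), 10.0, 3.0, float(max(y.max(), 1e-3)))
    lo = [x.min() - 2 * np.ptp(x), 1e-2, 0.51, 1e-6]
    hi = [x.max() + 2 * np.ptp(x), 1e3, 1e3, 10.0]
    p0 = tuple(np.clip(p0, lo, hi))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _pearson7, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except RuntimeError as err:
        raise RuntimeError(f"Pearson VII fit did not converge: {err}") from err
    resid = float(np.linalg.norm(_pearson7(x, *popt) - y))
    return PearsonVIIFit(
        location=float(popt[0]),
        scale=float(popt[1]),
        shape=float(popt[2]),
        amplitude=float(popt[3]),
        residual_norm=resid,
    )


def kurtosis_of_fit(fit: PearsonVIIFit) -> float:
    """Fourth standardized moment of the fitted Pearson VII density, by
    numerical quadrature.

    The density ``(1 + z^2)^(-m)`` has a finite fourth moment only for
    ``m > 2.5``; below that the kurtosis is flagged infinite.  Kurtosis is
    location/scale invariant, so the quadrature runs on the standard form.
    """
    m = fit.shape
    if m <= 2.5:
        return np.inf

    def moment(k: int) -> float:
        # z = tan(theta) maps the half-line to (0, pi/2) with a smooth,
        # bounded integrand: z^k (1+z^2)^(-m) dz = sin^k cos^(2m-k-2) dtheta
        with warnings.catch_warnings():
            # near the m = 2.5 divergence boundary the tail integral is
            # best-effort; the flag above already marks the divergent case
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(
                lambda th: np.sin(th) ** k * np.cos(th) ** (2.0 * m - k - 2.0),
                0.0,
                np.pi / 2.0,
                limit=200,
            )
        return 2.0 * val

    m0 = moment(0)
    m2 = moment(2) / m0
    m4 = moment(4) / m0
    return float(m4 / m2**2)


# ---------------------------------------------------------------------------
# Permutation inference


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic(s), permutation null, and directed p-value(s).

    ``p = (#{null >= observed} + 1) / (n_perm + 1)`` for the ``greater``
    tail (counts flipped for ``less``; absolute values for ``two-sided``),
    so p always lies in (0, 1].
    """

    observed: pd.Series
    null: pd.DataFrame  # one column per statistic, n_perm rows
    p_values: pd.Series
    n_perm: int
    seed: int
    tail: Tail
    n_redrawn: int = 0


def _perm_pvalues(observed: pd.Series, null: pd.DataFrame, tail: Tail) -> pd.Series:
    n_perm = len(null)
    p = {}
    for name, obs in observed.items():
        draws = null[name].to_numpy()
        if tail == "greater":
            count = int(np.sum(draws >= obs))
        elif tail == "less":
            count = int(np.sum(draws <= obs))
        elif tail == "two-sided":
            count = int(np.sum(np.abs(draws) >= abs(obs)))
        else:
            raise ValueError(f"unknown tail {tail!r}")
        p[name] = (count + 1) / (n_perm + 1)
    return pd.Series(p)


def _check_disjoint(cohort_a: Sequence[SubjectData], cohort_b: Sequence[SubjectData]) -> None:
    ids_a = {s.subject_id for s in cohort_a}
    ids_b = {s.subject_id for s in cohort_b}
    if ids_a & ids_b:
        raise ValueError(f"groups share subjects: {sorted(ids_a & ids_b)}")


def _group_kurtosis(subjects: Sequence[SubjectData]) -> float:
    gradient = behavioral_gradient(subjects)
    mean = gradient.per_subject.mean(axis=0)  # single pooled mean over subjects
    fit = fit_pearson7(np.asarray(mean.index, dtype=float), mean.to_numpy())
    return kurtosis_of_fit(fit)


def _fit_pearson7_fast(
    x: np.ndarray, y: np.ndarray, p0: tuple[float, float, float, float]
) -> PearsonVIIFit:
    """Warm-started unbounded least squares with fallback to the bounded fit.

    Used inside permutation loops, where thousands of refits share one
    label-invariant starting point; results are validated against the same
    parameter box as :func:`fit_pearson7` and fall back to it otherwise.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(_pearson7, x, y, p0=p0, method="lm", maxfev=5000)
        mu, sc, sh, amp = popt
        sc = abs(sc)  # the curve is even in the scale
        if (
            np.all(np.isfinite(popt))
            and 1e-2 <= sc <= 1e3
            and 0.51 <= sh <= 1e3
            and 1e-6 <= amp <= 10.0
        ):
            resid = float(np.linalg.norm(_pearson7(x, mu, sc, sh, amp) - y))
            return PearsonVIIFit(float(mu), float(sc), float(sh), float(amp), resid)
    except RuntimeError:
        pass
    return fit_pearson7(x, y, p0=p0)


def _rows_kurtosis(
    rows: np.ndarray,
    orientations: np.ndarray,
    p0: Optional[tuple[float, float, float, float]] = None,
) -> float:
    # mean over subjects (NaN-aware, matching behavioral_gradient), then fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rows, axis=0)
    if p0 is None:
        fit = fit_pearson7(orientations, mean)
    else:
        fit = _fit_pearson7_fast(orientations, mean, p0)
    return kurtosis_of_fit(fit)


def _kurtosis_diff(
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    orients: np.ndarray,
    p0: Optional[tuple[float, float, float, float]] = None,
) -> float:
    diff = _rows_kurtosis(rows_a, orients, p0) - _rows_kurtosis(rows_b, orients, p0)
    if np.isnan(diff):  # inf - inf: both tails too heavy for a 4th moment
        raise RuntimeError("kurtosis difference undefined: both groups infinite")
    return diff


def permutation_test_kurtosis(
    cohort_a: Sequence[SubjectData],
    cohort_b: Sequence[SubjectData],
    n_perm: int = 10000,
    seed: int = 0,
    tail: Tail = "greater",
    max_redraws: int = 1000,
) -> PermutationResult:
    """Permutation test on the difference in fitted-gradient kurtosis
    (group A minus group B), relabeling subjects into groups of the original
    sizes.  Permutations whose curve fit fails are re-drawn (and counted)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_disjoint(cohort_a, cohort_b)
    # Per-subject gradient rows do not depend on group labels, so they are
    # computed once; every permutation re-averages a row subset and refits
    # the Pearson VII curve from scratch (identical to refitting per group).
    pool = list(cohort_a) + list(cohort_b)
    gradient = behavioral_gradient(pool)
    rows = gradient.per_subject.loc[[s.subject_id for s in pool]].to_numpy()
    orients = gradient.orientations
    n_a = len(cohort_a)
    # shared warm start from the pooled (label-invariant) mean gradient
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled_mean = np.nanmean(rows, axis=0)
    pooled = fit_pearson7(orients, pooled_mean)
    p0 = (pooled.location, pooled.scale, pooled.shape, pooled.amplitude)
    observed = _kurtosis_diff(rows[:n_a], rows[n_a:], orients, p0)
    rng = np.random.default_rng(seed)
    draws: list[float] = []
    redrawn = 0
    while len(draws) < n_perm:
        order = rng.permutation(len(pool))
        try:
            draws.append(
                _kurtosis_diff(rows[order[:n_a]], rows[order[n_a:]], orients, p0)
            )
        except (RuntimeError, ValueError):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraws} permutations failed to fit"
                )
    observed_s = pd.Series({"kurtosis_diff": observed})
    null = pd.DataFrame({"kurtosis_diff": draws})
    return PermutationResult(
        observed=observed_s,
        null=null,
        p_values=_perm_pvalues(observed_s, null, tail),
        n_perm=n_perm,
        seed=seed,
        tail=tail,
        n_redrawn=redrawn,
    )


_PARAM_NAMES = ("s_i", "s_e", "beta", "offset_a", "alpha_test")


def _param_diff(
    cohort_a: Sequence[SubjectData],
    cohort_b: Sequence[SubjectData],
    fixed_alpha_train: float,
    kernel: str,
    config: FitConfig,
) -> pd.Series:
    fit_a = fit_group(cohort_a, fixed_alpha_train, kernel, config)
    fit_b = fit_group(cohort_b, fixed_alpha_train, kernel, config)
    return pd.Series(
        {n: getattr(fit_a.params, n) - getattr(fit_b.params, n) for n in _PARAM_NAMES}
    )


def permutation_test_parameters(
    cohort_a: Sequence[SubjectData],
    cohort_b: Sequence[SubjectData],
    fixed_alpha_train: float,
    n_perm: int = 10000,
    seed: int = 0,
    kernel: str = "gaussian",
    config: FitConfig = FitConfig(),
    tail: Tail = "less",
    max_redraws: int = 1000,
) -> PermutationResult:
    """Permutation test on group-wise fitted-parameter differences (A - B).

    Subjects are reshuffled into groups of the original sizes and both groups
    refitted on every relabeling; alpha_train stays fixed at the full-sample
    estimate throughout (the two-stage convention).  The default ``less``
    tail tests for smaller parameters in group A.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_disjoint(cohort_a, cohort_b)
    observed = _param_diff(cohort_a, cohort_b, fixed_alpha_train, kernel, config)
    pool = list(cohort_a) + list(cohort_b)
    n_a = len(cohort_a)
    rng = np.random.default_rng(seed)
    draws: list[pd.Series] = []
    redrawn = 0
    while len(draws) < n_perm:
        order = rng.permutation(len(pool))
        perm_a = [pool[i] for i in order[:n_a]]
        perm_b = [pool[i] for i in order[n_a:]]
        try:
            draws.append(
                _param_diff(perm_a, perm_b, fixed_alpha_train, kernel, config)
            )
        except Exception:  # noqa: BLE001 - refit failures are re-drawn
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraws} permutation refits failed"
                )
    null = pd.DataFrame(draws).reset_index(drop=True)
    return PermutationResult(
        observed=observed,
        null=null,
        p_values=_perm_pvalues(observed, null, tail),
        n_perm=n_perm,
        seed=seed,
        tail=tail,
        n_redrawn=redrawn,
    )


# ---------------------------------------------------------------------------
# Leave-one-out individual estimates


@dataclass(frozen=True)
class LOOEstimates:
    """Per-subject jackknife scores per parameter, with group tests.

    A subject's score is the full-group estimate minus the estimate with that
    subject left out, so a subject carrying a large latent parameter receives
    a positive score.
    """

    scores: pd.DataFrame  # index subject_id; columns parameters + "group"
    tests: pd.DataFrame  # per parameter: t statistic and one-tailed p


def loo_parameter_scores(
    cohort: Sequence[SubjectData],
    fixed_alpha_train: float,
    kernel: str = "gaussian",
    config: FitConfig = FitConfig(),
    alternative: Tail = "less",
) -> LOOEstimates:
    """Leave-one-out individual-difference scores within each group.

    For each group: fit all members, then refit leaving each subject out;
    score = full fit minus leave-one-out fit, per parameter.  Groups are then
    compared per parameter with a two-sample t-test on the scores (default
    tail: first group label in sorted order smaller).  Sub-fit failures leave
    that subject's scores missing (NaN).
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-out requires at least 3 subjects")
    groups = sorted({s.group for s in cohort})
    rows = {}
    for group in groups:
        members = [s for s in cohort if s.group == group]
        full = fit_group(members, fixed_alpha_train, kernel, config)
        for left_out in members:
            rest = [s for s in members if s.subject_id != left_out.subject_id]
            try:
                reduced = fit_group(rest, fixed_alpha_train, kernel, config)
                score = {
                    n: getattr(full.params, n) - getattr(reduced.params, n)
                    for n in _PARAM_NAMES
                }
            except Exception:  # noqa: BLE001
                warnings.warn(
                    f"leave-one-out refit failed for {left_out.subject_id}; "
                    "scores set to NaN",
                    stacklevel=2,
                )
                score = {n: np.nan for n in _PARAM_NAMES}
            score["group"] = group
            rows[left_out.subject_id] = score
    scores = pd.DataFrame(rows).T
    scores[list(_PARAM_NAMES)] = scores[list(_PARAM_NAMES)].astype(float)

    test_rows = []
    if len(groups) == 2:
        a, b = groups
        for n in _PARAM_NAMES:
            va = scores.loc[scores["group"] == a, n].dropna()
            vb = scores.loc[scores["group"] == b, n].dropna()
            t, p = stats.ttest_ind(va, vb, alternative=alternative)
            test_rows.append({"parameter": n, "t": float(t), "p": float(p)})
    tests = pd.DataFrame(test_rows)
    return LOOEstimates(scores=scores, tests=tests)
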