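import numpy as np
import pytest

from gengrad.core_model import ModelParams
from gengrad.fitting import FitConfig, SubjectData
from gengrad.group_inference import (
    PearsonVIIFit,
    behavioral_gradient,
    fit_pearson7,
    kurtosis_of_fit,
    loo_parameter_scores,
    peak_shift_statistic,
    permutation_test_kurtosis,
    permutation_test_parameters,
)
from gengrad.task_design import StimulusSpec, make_test_schedule

from conftest import quick_subject, trials_to_schedules


def _responded_subject(spec, responses, sid="S01", group="G", seed=0):
    """Subject with a fixed test-response sequence (training left empty)."""
    test = make_test_schedule(spec, n_reps_test=len(responses) // 15, seed=seed)
    test = test.with_responses(
        [responses[i] for i in range(len(test))]
        if callable(responses)
        else responses[: len(test)]
    )
    train, _ = trials_to_schedules([], spec)
    return SubjectData(sid, group, spec, train, test)


def _subject_with_rule(spec, rule, sid="S01", group="G", n_reps_test=4, seed=0):
    test = make_test_schedule(spec, n_reps_test=n_reps_test, seed=seed)
    resp = [rule(t.orientation) for t in test.trials]
    train, _ = trials_to_schedules([], spec)
    return SubjectData(sid, group, spec, train, test.with_responses(resp))


class TestBehavioralGradient:
    def test_all_plus_responder_flat_at_one(self, default_spec):
        s = _subject_with_rule(default_spec, lambda x: "plus")
        g = behavioral_gradient([s])
        assert np.allclose(g.per_subject.loc["S01"].to_numpy(), 1.0)

    def test_step_profile_for_deterministic_responder(self, default_spec):
        # responds "+" exactly when the orientation is below 40 degrees
        s = _subject_with_rule(
            default_spec, lambda x: "plus" if x < 40 else "minus"
        )
        g = behavioral_gradient([s])
        row = g.per_subject.loc["S01"]
        expected = (np.asarray(row.index, float) < 40).astype(float)
        assert np.allclose(row.to_numpy(), expected)

    def test_trial_order_invariance(self, default_spec):
        a = _subject_with_rule(
            default_spec, lambda x: "plus" if x < 45 else "minus", seed=1
        )
        b = _subject_with_rule(
            default_spec, lambda x: "plus" if x < 45 else "minus", seed=99
        )
        ga = behavioral_gradient([a]).per_subject.loc["S01"]
        gb = behavioral_gradient([b]).per_subject.loc["S01"]
        assert np.allclose(ga.to_numpy(), gb.to_numpy())

    def test_counterbalance_invariance(self, default_spec):
        """A mirrored-role subject with mirrored responses lands on the same
        canonical row."""
        rule = lambda x: "plus" if x < 40 else "minus"
        a = _subject_with_rule(default_spec, rule, sid="A")
        swapped = default_spec.swapped()
        b = _subject_with_rule(swapped, lambda x: rule(90 - x), sid="B")
        g = behavioral_gradient([a, b])
        assert np.allclose(
            g.per_subject.loc["A"].to_numpy(), g.per_subject.loc["B"].to_numpy()
        )

    def test_zero_valid_orientation_warns_and_nan(self, default_spec):
        test = make_test_schedule(default_spec, n_reps_test=1, seed=0)
        responses = ["plus"] * len(test)
        valid = [t.orientation != 45.0 for t in test.trials]
        responses = [
            "missing" if not v else r for r, v in zip(responses, valid)
        ]
        train, _ = trials_to_schedules([], default_spec)
        s = SubjectData("S01", "G", default_spec, train, test.with_responses(responses, valid))
        with pytest.warns(UserWarning, match="no valid trials"):
            g = behavioral_gradient([s])
        assert np.isnan(g.per_subject.loc["S01", 45.0])


class TestPeakShift:
    def test_requires_two_subjects(self, default_spec):
        s = _subject_with_rule(default_spec, lambda x: "plus")
        with pytest.raises(ValueError):
            peak_shift_statistic([s])

    def test_flat_responders_have_zero_side_difference(self, default_spec):
        subs = [
            _subject_with_rule(default_spec, lambda x: "plus", sid=f"S{i}", seed=i)
            for i in range(3)
        ]
        res = peak_shift_statistic(subs)
        diffs = res.per_subject["far_side"] - res.per_subject["near_side"]
        assert np.allclose(diffs.to_numpy(), 0.0)

    def test_asymmetric_responding_gives_positive_statistic(self, default_spec):
        rng = np.random.default_rng(0)
        subs = []
        for i in range(6):
            # respond "+" more often on the far (low) side of the CS+
            rule = lambda x: "plus" if (x < 39 and rng.random() < 0.8) or (
                x > 39 and rng.random() < 0.3
            ) else "minus"
            subs.append(
                _subject_with_rule(default_spec, rule, sid=f"S{i}", seed=i)
            )
        res = peak_shift_statistic(subs)
        assert res.statistic > 0
        assert 0 < res.p_value < 0.5


class TestPearsonVII:
    def test_noise_free_self_fit(self):
        x = np.arange(17.0, 74.0, 4.0)
        truth = PearsonVIIFit(
            location=37.0, scale=12.0, shape=3.0, amplitude=0.6, residual_norm=0.0
        )
        fit = fit_pearson7(x, truth(x))
        assert fit.location == pytest.approx(37.0, abs=1e-4)
        assert fit.scale == pytest.approx(12.0, rel=1e-3)
        assert fit.shape == pytest.approx(3.0, rel=1e-3)
        assert fit.amplitude == pytest.approx(0.6, rel=1e-4)
        assert fit.residual_norm < 1e-8

    def test_gaussian_shaped_gradient_yields_large_shape(self):
        x = np.arange(17.0, 74.0, 4.0)
        y = 0.6 * np.exp(-((x - 39.0) ** 2) / (2 * 12.0**2))
        fit = fit_pearson7(x, y)
        assert fit.shape > 50  # Gaussian is the shape -> infinity limit
        assert kurtosis_of_fit(fit) == pytest.approx(3.0, abs=0.05)

    def test_flat_gradient_rejected(self):
        x = np.arange(17.0, 74.0, 4.0)
        with pytest.raises(ValueError, match="flat"):
            fit_pearson7(x, np.full_like(x, 0.4))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_pearson7([1, 2, 3, 4], [0.1, 0.5, 0.4, 0.1])


class TestKurtosis:
    def test_closed_form_student_t_equivalence(self):
        """Pearson VII with exponent m maps to a scaled Student-t with
        nu = 2m - 1 degrees of freedom, whose kurtosis is 3(nu-2)/(nu-4)."""
        for m in (3.0, 4.0, 6.0, 10.0):
            fit = PearsonVIIFit(0.0, 1.0, m, 1.0, 0.0)
            nu = 2 * m - 1
            assert kurtosis_of_fit(fit) == pytest.approx(
                3 * (nu - 2) / (nu - 4), rel=1e-6
            )

    def test_heavy_tail_flagged_infinite(self):
        fit = PearsonVIIFit(0.0, 1.0, 2.4, 1.0, 0.0)
        assert kurtosis_of_fit(fit) == np.inf

    def test_location_scale_invariance(self):
        a = PearsonVIIFit(0.0, 1.0, 5.0, 1.0, 0.0)
        b = PearsonVIIFit(40.0, 17.0, 5.0, 0.3, 0.0)
        assert kurtosis_of_fit(a) == pytest.approx(kurtosis_of_fit(b), rel=1e-9)


def _two_disjoint_copies(default_spec, n=4):
    """Two cohorts with identical data but distinct subject ids."""
    rng = np.random.default_rng(21)
    params = ModelParams(
        s_i=20.0, s_e=17.0, beta=3.0, offset_a=0.37, alpha_train=0.1, alpha_test=0.01
    )
    base = [
        quick_subject(rng, params, default_spec, f"A{i}", group="A", n_reps=10, n_reps_test=3)
        for i in range(n)
    ]
    clones = [
        SubjectData(f"B{i}", "B", s.spec, s.training, s.test)
        for i, s in enumerate(base)
    ]
    return base, clones


def _bell_profile_cohort(spec, n, prefix, group, seed=0):
    """Responders whose P(+) follows a Gaussian bump over orientation, giving
    well-behaved bell-shaped gradients."""
    rng = np.random.default_rng(seed)
    subs = []
    for i in range(n):
        def rule(x):
            p = 0.65 * np.exp(-((x - 37.0) ** 2) / (2 * 14.0**2))
            return "plus" if rng.random() < p else "minus"

        subs.append(
            _subject_with_rule(
                spec, rule, sid=f"{prefix}{i}", group=group, n_reps_test=6, seed=i
            )
        )
    return subs


class TestPermutationTests:
    def test_identical_cohorts_zero_observed_kurtosis_diff(self, default_spec):
        a = _bell_profile_cohort(default_spec, 5, "A", "A", seed=1)
        b = [
            SubjectData(f"B{i}", "B", s.spec, s.training, s.test)
            for i, s in enumerate(a)
        ]
        res = permutation_test_kurtosis(a, b, n_perm=19, seed=0)
        assert res.observed.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert 0 < res.p_values.iloc[0] <= 1

    def test_shared_subjects_rejected(self, default_spec):
        a, _ = _two_disjoint_copies(default_spec)
        with pytest.raises(ValueError, match="share"):
            permutation_test_kurtosis(a, a, n_perm=5, seed=0)

    def test_zero_permutations_rejected(self, default_spec):
        a, b = _two_disjoint_copies(default_spec)
        with pytest.raises(ValueError):
            permutation_test_parameters(a, b, 0.1, n_perm=0)

    def test_identical_cohorts_zero_observed_param_diff(self, default_spec):
        a, b = _two_disjoint_copies(default_spec)
        config = FitConfig(n_starts=1, seed=2, maxfev=150)
        res = permutation_test_parameters(
            a, b, 0.1, n_perm=9, seed=3, config=config
        )
        assert np.allclose(res.observed.to_numpy(), 0.0, atol=1e-12)
        assert ((res.p_values > 0) & (res.p_values <= 1)).all()
        assert len(res.null) == 9

    def test_seeded_reproducibility(self, default_spec):
        a, b = _two_disjoint_copies(default_spec)
        config = FitConfig(n_starts=1, seed=2, maxfev=120)
        r1 = permutation_test_parameters(a, b, 0.1, n_perm=5, seed=7, config=config)
        r2 = permutation_test_parameters(a, b, 0.1, n_perm=5, seed=7, config=config)
        assert r1.null.equals(r2.null)
        assert r1.p_values.equals(r2.p_values)


class TestLeaveOneOut:
    def test_identical_data_agents_score_near_zero(self, default_spec):
        """Subjects with literally identical data contribute identically, so
        every jackknife score collapses toward zero."""
        rng = np.random.default_rng(5)
        params = ModelParams(
            s_i=20.0, s_e=17.0, beta=3.0, offset_a=0.37, alpha_train=0.1, alpha_test=0.01
        )
        proto = quick_subject(rng, params, default_spec, "P", n_reps=20, n_reps_test=4)
        cohort = [
            SubjectData(f"S{i}", "G", proto.spec, proto.training, proto.test)
            for i in range(5)
        ]
        config = FitConfig(n_starts=2, seed=1, maxfev=1200)
        loo = loo_parameter_scores(cohort, 0.1, "gaussian", config)
        rel = (loo.scores["s_e"].abs() / loo.scores["s_e"].abs().max().clip(1e-9)).max()
        assert (loo.scores["s_e"].abs() < 0.05 * 17.0).all()
        assert (loo.scores["s_i"].abs() < 0.05 * 20.0).all()

    def test_planted_outlier_has_maximal_width_score(self, default_spec):
        """An agent generated with a doubled excitatory width receives the
        largest leave-one-out s_e score in the cohort."""
        rng = np.random.default_rng(9)
        base = ModelParams(
            s_i=20.0, s_e=14.0, beta=3.1, offset_a=0.36, alpha_train=0.1, alpha_test=0.01
        )
        wide = ModelParams(
            s_i=20.0, s_e=28.0, beta=3.1, offset_a=0.36, alpha_train=0.1, alpha_test=0.01
        )
        cohort = [
            quick_subject(rng, base, default_spec, f"S{i}", group="G", n_reps=30, n_reps_test=14)
            for i in range(7)
        ]
        cohort.append(
            quick_subject(rng, wide, default_spec, "OUT", group="G", n_reps=30, n_reps_test=14)
        )
        # enough starts that every sub-fit reaches the same basin
        config = FitConfig(n_starts=16, seed=0)
        loo = loo_parameter_scores(cohort, 0.1, "gaussian", config)
        assert loo.scores["s_e"].idxmax() == "OUT"
        # jackknife balance: scores roughly cancel over the whole cohort
        all_scores = loo.scores["s_e"]
        assert abs(all_scores.sum()) < max(2 * all_scores.std(), 0.5)

    def test_requires_three_subjects(self, default_spec):
        a, _ = _two_disjoint_copies(default_spec, n=1)
        with pytest.raises(ValueError):
            loo_parameter_scores(a[:2], 0.1)
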