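"""Likelihood, goodness of fit and ML estimation tests."""

import math

import numpy as np
import pytest

from lineup2ht import (
    ConditionParams,
    LineupCounts,
    ModelSpec,
    degrees_of_freedom,
    fit_model,
    g_squared,
    log_likelihood,
)
from lineup2ht.estimation import _neg_loglik_and_grad
from lineup2ht.model import counts_matrix


class TestLogLikelihood:
    def test_certain_categories_contribute_nothing(self):
        data = [LineupCounts("a", "none", 0, 10, 0, 0, 0, 0, 10)]
        params = {"a": ConditionParams(1.0, 0.0, 0.0, 1.0)}
        assert log_likelihood(data, params) == 0.0

    def test_zero_probability_with_positive_count_is_minus_infinity(self):
        data = [LineupCounts("a", "none", 0, 10, 5, 0, 0, 0, 10)]
        params = {"a": ConditionParams(1.0, 0.0, 0.0, 1.0)}
        assert log_likelihood(data, params) == -math.inf

    def test_saturated_fit_attains_multinomial_bound(self):
        # on counts the tree parameterisation can represent (interior
        # solution), the all-free fit reaches the bound sum O * ln(O/N)
        data = _representable_dataset()
        fit = fit_model(data, ModelSpec.saturated(("a", "b"),
                                                  sampling_constant=1 / 6),
                        n_starts=10, seed=0, compute_ci=False)
        expected = 0.0
        for cond in data:
            counts = cond.as_array()
            for o, n in zip(counts, [cond.cp_total] * 3 + [cond.ca_total] * 3):
                if o > 0:
                    expected += o * math.log(o / n)
        assert fit.log_likelihood == pytest.approx(expected, abs=1e-6)


class TestGSquared:
    def test_perfect_fit_is_zero(self):
        assert g_squared([5, 10, 15], [5.0, 10.0, 15.0]) == 0.0

    def test_hand_computed_value(self):
        # 2 * (10 ln(10/20) + 20 ln(20/20) + 30 ln(30/20))
        expected = 2 * (10 * math.log(0.5) + 30 * math.log(1.5))
        assert g_squared([10, 20, 30], [20, 20, 20]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(10.4652, abs=5e-4)

    def test_zero_expected_with_positive_observed_is_infinite(self):
        with pytest.warns(RuntimeWarning):
            assert g_squared([1, 1], [0.0, 2.0]) == math.inf

    def test_zero_observed_cells_are_ignored(self):
        assert g_squared([0, 10], [5.0, 10.0]) == 0.0


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "build, expected",
        [
            (lambda conds: ModelSpec.base(conds), 3),
            (lambda conds: ModelSpec.base(conds).with_equated("dP"), 6),
            (lambda conds: ModelSpec.saturated(conds[:1]), 0),
        ],
    )
    def test_free_parameter_accounting(self, conditions, build, expected):
        assert degrees_of_freedom(build(conditions)) == expected


def _exact_counts_dataset():
    """Counts exactly proportional to model probabilities at known params."""
    # dP=0.3, b=0.1, g=0.5, dA=0.2, c=1/6, N=2000 per tree -> integer counts
    return (
        [LineupCounts("a", "none", 0, 845, 525, 630, 280, 600, 1120)],
        ConditionParams(0.3, 0.1, 0.5, 0.2),
    )


def _representable_dataset():
    """Two conditions whose proportions lie exactly on interior parameters."""
    # condition b: dP=0.1, b=0.05, g=0.4, dA=0.1, c=1/6, N=1000 per tree
    return [
        _exact_counts_dataset()[0][0],
        LineupCounts("b", "1 day", 1, 202, 285, 513, 102, 285, 613),
    ]


class TestFitModel:
    def test_recovers_generating_params_from_exact_counts(self):
        data, truth = _exact_counts_dataset()
        spec = ModelSpec.saturated(("a",), sampling_constant=1 / 6)
        fit = fit_model(data, spec, n_starts=10, seed=3)
        assert fit.g_squared == pytest.approx(0.0, abs=1e-6)
        est = fit.params_for("a")
        for fam in ("dP", "b", "g", "dA"):
            assert getattr(est, fam) == pytest.approx(getattr(truth, fam),
                                                      abs=1e-4)

    def test_matches_exhaustive_grid_search_on_toy_data(self):
        # two conditions sharing one dP and one g; b and dA pinned to zero,
        # so the likelihood surface is two-dimensional and can be scanned
        data = [
            LineupCounts("a", "none", 0, 14, 20, 16, 6, 25, 19),
            LineupCounts("b", "1 day", 1, 11, 22, 17, 8, 21, 21),
        ]
        c = 1 / 6
        spec = (
            ModelSpec(("a", "b"), sampling_constant=c)
            .with_equated("dP").with_equated("g")
            .with_fixed("b", 0.0).with_fixed("dA", 0.0)
        )
        fit = fit_model(data, spec, n_starts=10, seed=5, compute_ci=False)

        # independent oracle: hand-written branch formulas on a 0.005 grid
        dp, g = np.meshgrid(np.arange(0, 1.0001, 0.005),
                            np.arange(0, 1.0001, 0.005), indexing="ij")
        probs = [
            dp + (1 - dp) * g * c,      # culprit id (b = 0)
            (1 - dp) * g * (1 - c),     # CP filler id
            (1 - dp) * (1 - g),         # CP rejection
            g * c,                      # suspect id (dA = 0)
            g * (1 - c),                # CA filler id
            (1 - g),                    # CA rejection
        ]
        counts = counts_matrix(data).sum(axis=0)  # shared params -> pooled
        ll = np.zeros_like(dp)
        for o, p in zip(counts, probs):
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = ll + np.where(o > 0, o * np.log(p), 0.0)
        grid_best = np.nanmax(ll)
        assert fit.log_likelihood >= grid_best - 1e-6
        assert fit.log_likelihood - grid_best < 0.01  # grid resolution bound

    def test_analytic_gradient_matches_finite_differences(self, study,
                                                          base_spec):
        pmap = base_spec.parameter_map()
        counts = counts_matrix(study)
        rng = np.random.default_rng(11)
        x = rng.uniform(0.1, 0.9, pmap.n_free)
        _, grad = _neg_loglik_and_grad(x, pmap, counts,
                                       base_spec.sampling_constant)
        eps = 1e-7
        for i in range(pmap.n_free):
            dx = np.zeros(pmap.n_free)
            dx[i] = eps
            f_plus = _neg_loglik_and_grad(x + dx, pmap, counts,
                                          base_spec.sampling_constant)[0]
            f_minus = _neg_loglik_and_grad(x - dx, pmap, counts,
                                           base_spec.sampling_constant)[0]
            assert grad[i] == pytest.approx((f_plus - f_minus) / (2 * eps),
                                            rel=1e-4, abs=1e-3)

    def test_saturated_model_fits_representable_data_perfectly(self):
        data = _representable_dataset()
        fit = fit_model(data, ModelSpec.saturated(("a", "b"),
                                                  sampling_constant=1 / 6),
                        n_starts=10, seed=0, compute_ci=False)
        assert fit.g_squared == pytest.approx(0.0, abs=1e-6)
        assert fit.df == 0

    def test_restriction_never_improves_likelihood(self, base_fit,
                                                   equality_fits):
        for fit in equality_fits.values():
            assert fit.log_likelihood <= base_fit.log_likelihood + 1e-8

    def test_invariance_to_condition_order_and_count_scaling(self, study,
                                                             base_spec,
                                                             base_fit):
        shuffled = [study[2], study[0], study[3], study[1]]
        refit = fit_model(shuffled, base_spec, n_starts=10, seed=9,
                          compute_ci=False)
        for name, value in base_fit.estimates.items():
            assert refit.estimates[name] == pytest.approx(value, abs=1e-5)

        scaled = [
            LineupCounts(
                cond.condition_id, cond.nominal_delay, cond.actual_delay_days,
                *(3 * v for v in (cond.cp_culprit, cond.cp_filler,
                                  cond.cp_reject, cond.ca_suspect,
                                  cond.ca_filler, cond.ca_reject)),
            )
            for cond in study
        ]
        scaled_fit = fit_model(scaled, base_spec, n_starts=10, seed=9,
                               compute_ci=False)
        for name, value in base_fit.estimates.items():
            assert scaled_fit.estimates[name] == pytest.approx(value, abs=1e-5)
        assert scaled_fit.g_squared == pytest.approx(3 * base_fit.g_squared,
                                                     rel=1e-4)

    def test_mismatched_conditions_rejected(self, study):
        from lineup2ht import ValidationError

        with pytest.raises(ValidationError):
            fit_model(study, ModelSpec.base(("x", "y", "z", "w")))


class TestWaldIntervals:
    def test_fixed_parameters_have_no_interval(self, study, conditions):
        spec = ModelSpec.base(conditions).with_fixed("dA", 0.0)
        fit = fit_model(study, spec, n_starts=10, seed=2)
        assert not any(name.startswith("dA") for name in fit.ci95)
        assert all(lo <= hi for lo, hi in fit.ci95.values())

    def test_intervals_clipped_to_unit_box(self, base_fit):
        for name, (lo, hi) in base_fit.ci95.items():
            assert 0.0 <= lo <= hi <= 1.0
            if not base_fit.boundary[name]:
                assert lo <= base_fit.estimates[name] <= hi

    def test_interval_width_shrinks_with_sample_size(self):
        from lineup2ht import simulate_study, study_design

        widths = {}
        for scale in (1, 4):
            design = study_design(
                participants=tuple(scale * n for n in (550, 532, 520, 506)),
                seed=17,
            )
            data = simulate_study(design)
            spec = ModelSpec.base(tuple(c.condition_id for c in data))
            fit = fit_model(data, spec, n_starts=10, seed=17)
            widths[scale] = fit.ci95["b"][1] - fit.ci95["b"][0]
        ratio = widths[1] / widths[4]
        assert 1.6 < ratio < 2.4  # ~2 for a 4x sample
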