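"""Spline ensemble: weights, LRE detection, Rubin pooling, averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radonrisk import (
    CohortConfig,
    DesignSpec,
    SplineConfig,
    TrueDoseResponse,
    akaike_weights,
    ensemble_configs,
    find_lre,
    fit_spline_member,
    generate_cohort,
    rubin_combine,
    run_ensemble,
    wald_or_ci,
)

SIX_RCS = [
    SplineConfig(basis="restricted_cubic", n_knots=k, placement=p)
    for k in (3, 4, 5)
    for p in ("quantile", "equal")
]


class TestEnsembleConfigs:
    def test_default_grid_has_twelve_members(self):
        configs = ensemble_configs()
        assert len(configs) == 12
        assert len(set(configs)) == 12

    def test_custom_single_config(self):
        one = [SplineConfig()]
        assert ensemble_configs(one) == one

    def test_duplicates_removed_order_preserved(self):
        a = SplineConfig(n_knots=3)
        b = SplineConfig(n_knots=4)
        assert ensemble_configs([a, b, a, b, a]) == [a, b]

    def test_empty_custom_rejected(self):
        with pytest.raises(ValueError):
            ensemble_configs([])


class TestAkaikeWeights:
    def test_closed_form_pair(self):
        w = akaike_weights([2.0, 0.0])
        e = np.e
        np.testing.assert_allclose(w, [e / (1 + e), 1 / (1 + e)], atol=1e-4)
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_single_model_gets_unit_weight(self):
        assert akaike_weights([5.0]) == pytest.approx([1.0])

    def test_equal_inputs_uniform(self):
        np.testing.assert_allclose(akaike_weights([3.0] * 4), 0.25)

    def test_empty_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])
        with pytest.raises(ValueError):
            akaike_weights([1.0, np.inf])

    @given(
        st.lists(st.floats(min_value=-50, max_value=700), min_size=1, max_size=20)
    )
    def test_weights_simplex_and_shift_invariance(self, daics):
        w = akaike_weights(daics)
        assert np.all(w >= 0)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, akaike_weights(np.array(daics) + 123.0), atol=1e-12)


class TestFindLre:
    def test_parabola_vertex(self):
        grid = np.arange(0.0, 121.0)
        assert find_lre(grid, (grid - 58.0) ** 2) == 58.0

    def test_monotone_curve_absent(self):
        grid = np.arange(0.0, 100.0)
        assert find_lre(grid, 0.01 * grid + 0.2) is None
        assert find_lre(grid, -0.01 * grid + 2.0) is None

    def test_two_dip_curve_takes_deeper_dip_matching_exhaustive_scan(self):
        grid = np.arange(0.0, 200.0)
        v = 0.5 + 0.2 * np.sin(grid / 18.0) + 0.001 * grid
        lre = find_lre(grid, v)
        # oracle: exhaustive scan over interior points for the lowest
        # qualifying local minimum
        interior = [
            i for i in range(1, len(v) - 1) if v[i] < v[i - 1] and v[i] < v[i + 1]
        ]
        assert lre == grid[min(interior, key=lambda i: v[i])]

    def test_shallow_noise_dip_ignored(self):
        grid = np.arange(0.0, 100.0)
        v = 0.01 * grid.copy()
        v[50] -= 0.004  # dip of 0.4% of the range
        assert find_lre(grid, v) is None

    def test_flat_curve_absent(self):
        grid = np.arange(0.0, 10.0)
        assert find_lre(grid, np.ones_like(grid)) is None


class TestRubinCombine:
    def test_single_model_identity(self):
        orr, lo, hi = rubin_combine([0.3], [0.04], [1.0])
        assert orr == pytest.approx(np.exp(0.3))
        assert lo == pytest.approx(np.exp(0.3 - 1.959964 * 0.2), rel=1e-6)
        assert hi == pytest.approx(np.exp(0.3 + 1.959964 * 0.2), rel=1e-6)

    def test_identical_estimates_have_no_between_variance(self):
        orr, lo, hi = rubin_combine([0.2, 0.2, 0.2], [0.01, 0.01, 0.01], [0.5, 0.3, 0.2])
        assert orr == pytest.approx(np.exp(0.2))
        assert lo == pytest.approx(np.exp(0.2 - 1.959964 * 0.1), rel=1e-6)

    def test_two_model_hand_arithmetic(self):
        # theta_bar = 0.3, U_bar = 0.01,
        # B = (0.5*0.01 + 0.5*0.01) / (1 - 0.5) = 0.02, m_eff = 2,
        # T = 0.01 + (1 + 1/2)*0.02 = 0.04
        orr, lo, hi = rubin_combine([0.2, 0.4], [0.01, 0.01], [0.5, 0.5])
        assert orr == pytest.approx(np.exp(0.3))
        assert lo == pytest.approx(np.exp(0.3 - 1.959964 * 0.2), rel=1e-6)
        assert hi == pytest.approx(np.exp(0.3 + 1.959964 * 0.2), rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rubin_combine([0.1], [-0.01], [1.0])
        with pytest.raises(ValueError):
            rubin_combine([0.1, 0.2], [0.01, 0.01], [0.6, 0.6])
        with pytest.raises(ValueError):
            rubin_combine([0.1, 0.2], [0.01], [0.5, 0.5])


class TestFitSplineMember:
    def test_flat_truth_splines_add_no_information(self):
        """Under a flat dose-response the spline improves the base AIC by
        at most 2 in >=80% of seeds."""
        cfg_member = SplineConfig(basis="restricted_cubic", n_knots=4, placement="quantile")
        ok = 0
        n_seeds = 50
        for s in range(n_seeds):
            cfg = CohortConfig(n_total=4000, seed=1000 + s,
                               dose_response=TrueDoseResponse(kind="flat"))
            member = fit_spline_member(generate_cohort(cfg), cfg_member)
            ok += member.delta_aic <= 2.0
        assert ok >= 0.8 * n_seeds

    def test_curve_variance_nonnegative(self, jshape_cohort):
        member = fit_spline_member(jshape_cohort, SplineConfig())
        _, var = member.log_or(member.grid, float(member.grid[0]))
        assert np.all(var >= 0.0)

    def test_quadratic_bspline_member_fits(self, jshape_cohort):
        member = fit_spline_member(
            jshape_cohort, SplineConfig(basis="natural_quadratic", n_knots=3)
        )
        assert np.isfinite(member.delta_aic)
        assert member.fit.converged

    def test_minimum_arm_size_enforced(self, jshape_cohort):
        with pytest.raises(ValueError, match="50"):
            fit_spline_member(jshape_cohort.head(60), SplineConfig())


class TestRunEnsemble:
    def test_weight_conservation(self, jshape_cohort):
        res = run_ensemble(jshape_cohort, configs=SIX_RCS)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.weights >= 0)

    def test_or_at_reference_is_unity(self, jshape_cohort):
        res = run_ensemble(jshape_cohort, configs=SIX_RCS,
                           report_exposures=(25.0, 100.0))
        th = [m.log_or([res.reference_exposure], res.reference_exposure)[0][0]
              for m in res.members]
        assert np.allclose(th, 0.0)

    def test_lre_interval_contains_mean(self, jshape_cohort):
        res = run_ensemble(jshape_cohort, configs=SIX_RCS)
        assert res.lre is not None
        assert res.lre_interval[0] <= res.lre <= res.lre_interval[1]

    def test_ensemble_of_one_reproduces_member(self, jshape_cohort):
        cfg = SplineConfig(basis="restricted_cubic", n_knots=4, placement="quantile")
        with pytest.warns(UserWarning, match="single spline"):
            res = run_ensemble(jshape_cohort, configs=[cfg],
                               report_exposures=(100.0,))
        member = res.members[0]
        th, var = member.log_or([100.0], res.reference_exposure)
        row = res.or_table.iloc[0]
        assert row["or"] == pytest.approx(np.exp(th[0]), rel=1e-10)
        assert row["lo"] == pytest.approx(np.exp(th[0] - 1.959964 * np.sqrt(var[0])), rel=1e-6)
        # and matches the member's own Wald interval for the same contrast
        names = list(member.fit.params.index)
        c = np.zeros(member.fit.n_params)
        C = (member.basis_at(100.0) - member.basis_at(res.reference_exposure))[0]
        for name, val in zip(member.spline_cols, C):
            c[names.index(name)] = val
        orr, lo, hi, _ = wald_or_ci(member.fit, c)
        assert row["or"] == pytest.approx(orr, rel=1e-10)
        assert row["lo"] == pytest.approx(lo, rel=1e-8)

    def test_grid_refinement_stability(self, jshape_cohort):
        """Halving the curve-evaluation step moves a member's LRE by less
        than one coarse grid step."""
        member = fit_spline_member(jshape_cohort, SplineConfig())
        assert member.lre is not None
        fine = np.arange(member.grid[0], member.grid[-1] + 0.25, 0.5)
        from scipy.special import expit

        bs = member.fit.params[member.spline_cols].to_numpy()
        prob_fine = expit(member.ref_eta0 + member.basis_at(fine) @ bs)
        lre_fine = find_lre(fine, prob_fine)
        assert lre_fine is not None
        assert abs(lre_fine - member.lre) < 1.0

    def test_fixed_reference_exposure_honoured(self, jshape_cohort):
        res = run_ensemble(jshape_cohort, configs=SIX_RCS,
                           report_exposures=(58.0,), reference_exposure=58.0)
        row = res.or_table.iloc[0]
        assert row["or"] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_truth_flags_absent_lre(self):
        """Strong log-linear truth at modest n: every member rises
        monotonically, the ensemble must say so rather than invent a dip."""
        cfg = CohortConfig(n_total=14489, seed=4,
                           dose_response=TrueDoseResponse(kind="lnt", beta=0.5))
        with pytest.warns(UserWarning, match="monotone"):
            res = run_ensemble(generate_cohort(cfg), configs=SIX_RCS)
        assert res.monotone_flag and res.lre is None
        assert res.reference_exposure > 0
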