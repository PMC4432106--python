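"""Non-compartmental estimators: trapezoid rules, means, TAT."""

import math

import numpy as np
import pytest

import toxkinsim as tk
from toxkinsim.design import Role
from toxkinsim.errors import InputError, InsufficientDataError
from toxkinsim.nca import ProfileSummary, SummaryKind


def profile(times, conc):
    return ProfileSummary(np.asarray(times, float), np.asarray(conc, float),
                          SummaryKind.INDIVIDUAL, np.ones(len(times), int))


class TestAucLinLog:
    def test_hand_computed_toy_profile(self):
        # rising 0->10 linear (5), falling 10->5 logarithmic (5/ln 2)
        p = profile((0, 1, 2), (0, 10, 5))
        expected = 5.0 + 5.0 / math.log(2.0)
        assert tk.nca_auc_linlog(p, (0, 2)) == pytest.approx(expected, rel=1e-12)

    def test_matches_fine_grid_integral_of_interpolant(self):
        # oracle: dense numerical integration of the piecewise lin-up /
        # log-down interpolant
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 24.0])
        c = np.array([0.0, 8.0, 6.5, 9.0, 4.0, 0.5])
        p = profile(t, c)
        total = 0.0
        for j in range(len(t) - 1):
            tt = np.linspace(t[j], t[j + 1], 20001)
            c1, c2 = c[j], c[j + 1]
            if c2 < c1 and c2 > 0:
                vals = c1 * (c2 / c1) ** ((tt - t[j]) / (t[j + 1] - t[j]))
            else:
                vals = c1 + (c2 - c1) * (tt - t[j]) / (t[j + 1] - t[j])
            total += np.trapezoid(vals, tt)
        assert tk.nca_auc_linlog(p) == pytest.approx(total, rel=1e-6)

    def test_constant_profile_is_linear_rule(self):
        p = profile((0, 6, 24), (2.0, 2.0, 2.0))
        assert tk.nca_auc_linlog(p) == pytest.approx(48.0)

    def test_all_zero_profile(self):
        p = profile((0, 12, 24), (0, 0, 0))
        assert tk.nca_auc_linlog(p) == 0.0

    def test_refinement_converges_to_analytic_auc(self):
        # noise-free 1-cmt profile on dyadic grids: lin-log AUC -> D/CL part
        spec = tk.ModelSpec(tk.ModelId.ONE_CMT)
        params = {"KA": 13.46, "V": 49.4, "CL": 2.72}
        reg = tk.DoseRegimen(dose=30.0, n_doses=1)
        exact = tk.cumulative_auc(spec, params, reg, 24.0)
        errs = []
        for n in (16, 32, 64, 128):
            t = np.linspace(0.0, 24.0, n + 1)
            c = tk.predict_concentration(spec, params, reg, t)
            errs.append(abs(tk.nca_auc_linlog(profile(t, c)) - exact))
        # decay with refinement; the sharp absorption peak (t1/2 ~ 3 min)
        # limits the uniform-grid accuracy
        assert errs[-1] < errs[0] / 8
        assert errs[-1] / exact < 5e-3

    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            tk.nca_auc_linlog(profile((1.0,), (2.0,)))


class TestCmax:
    def test_direct_maximum_and_earliest_tie(self):
        cmax, tmax = tk.nca_cmax(profile((0, 1, 2, 3), (0, 10, 5, 10)))
        assert cmax == 10.0 and tmax == 1.0

    def test_single_point(self):
        cmax, tmax = tk.nca_cmax(profile((2.0,), (3.5,)))
        assert cmax == 3.5 and tmax == 2.0

    def test_noisy_sampled_cmax_is_positively_biased(self):
        # max of noisy samples >= true curve max in expectation
        rng = np.random.default_rng(1234)
        spec = tk.ModelSpec(tk.ModelId.ONE_CMT)
        params = {"KA": 13.46, "V": 49.4, "CL": 2.72}
        reg = tk.DoseRegimen(dose=30.0, n_doses=1)
        t = np.array([0.1, 0.4, 1.0, 1.5, 4.0, 8.0, 24.0])
        c = tk.predict_concentration(spec, params, reg, t)
        true_peak = c.max()
        draws = c[None, :] * (1 + 0.15 * rng.standard_normal((10_000, t.size)))
        assert draws.max(axis=1).mean() > true_peak


class TestTat:
    def test_hand_computed_crossings(self):
        # up-crossing at 0.6 (linear), down-crossing where
        # 10*(0.5)^(t-1) = 6 (log interpolation)
        p = profile((0, 1, 2), (0, 10, 5))
        t_down = 1 + math.log(0.6) / math.log(0.5)
        expected = t_down - 0.6
        assert tk.nca_tat(p, 6.0, (0, 2)) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.137, abs=5e-4)

    def test_matches_millisecond_grid_brute_force(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 24.0])
        c = np.array([0.0, 8.0, 6.5, 9.0, 4.0, 0.5])
        p = profile(t, c)
        thr = 5.0
        dt = 1.0 / 3600.0
        total = 0.0
        for j in range(len(t) - 1):
            tt = np.arange(t[j], t[j + 1], dt)
            c1, c2 = c[j], c[j + 1]
            if c2 < c1 and c2 > 0:
                vals = c1 * (c2 / c1) ** ((tt - t[j]) / (t[j + 1] - t[j]))
            else:
                vals = c1 + (c2 - c1) * (tt - t[j]) / (t[j + 1] - t[j])
            total += np.sum(vals > thr) * dt
        assert tk.nca_tat(p, thr) == pytest.approx(total, abs=2 * dt * len(t))

    def test_zero_threshold_counts_positive_span(self):
        p = profile((0, 1, 24), (0, 10, 2))
        assert tk.nca_tat(p, 0.0) == pytest.approx(24.0)

    def test_threshold_above_peak_gives_zero(self):
        p = profile((0, 1, 24), (0, 10, 2))
        assert tk.nca_tat(p, 11.0) == 0.0


class TestSummaries:
    def test_arithmetic_and_geometric_textbook_means(self, week_dataset):
        from toxkinsim.nca import _summarize
        assert _summarize(np.array([2.0, 8.0]), SummaryKind.ARITHMETIC)[0] == 5.0
        assert _summarize(np.array([2.0, 8.0]), SummaryKind.GEOMETRIC)[0] == \
            pytest.approx(4.0)

    def test_geometric_mean_excludes_zeros(self):
        from toxkinsim.nca import _summarize
        m, n = _summarize(np.array([0.0, 2.0, 8.0]), SummaryKind.GEOMETRIC)
        assert m == pytest.approx(4.0)
        assert n == 2

    def test_composite_profile_averages_contributing_animals(self, week_dataset):
        prof = tk.composite_mean_profile(week_dataset, 30.0, 1,
                                         SummaryKind.ARITHMETIC)
        # prepended zero anchor + 7 scheduled times
        assert prof.times[0] == 0.0 and prof.conc[0] == 0.0
        assert len(prof.times) == 8
        assert (prof.n_contributing[1:] == 3).all()

    def test_serial_summary_averages_per_animal_values(self, week_dataset):
        res = tk.serial_nca_summary(week_dataset, 30.0, 1,
                                    SummaryKind.ARITHMETIC, threshold=0.01)
        aucs = []
        for aid in week_dataset.animals(dose=30.0, role=Role.SATELLITE):
            prof = tk.individual_profile(week_dataset, aid, 1)
            aucs.append(tk.nca_auc_linlog(prof))
        assert res.auc24 == pytest.approx(np.mean(aucs))
        assert res.n_animals == 3

    def test_serial_geometric_mean_of_aucs(self):
        from toxkinsim.nca import _summarize
        assert _summarize(np.array([1.0, 100.0]), SummaryKind.GEOMETRIC)[0] == \
            pytest.approx(10.0)

    def test_composite_equals_serial_for_identical_noise_free_animals(self):
        # all animals share parameters, sigma = 0: both arms see the
        # same profile, so composite and serial NCA must agree exactly
        pop = tk.PopulationParameters(theta={"KA": 13.46, "V": 49.4, "CL": 2.72},
                                      bsv_cv={}, sigma_prop=0.0)
        spec = tk.ModelSpec(tk.ModelId.ONE_CMT)
        design = tk.build_cohort_design("1_WEEK")
        ds = tk.simulate_trial(design, spec, pop, 99)
        comp = tk.composite_nca_summary(ds, 30.0, 1, SummaryKind.ARITHMETIC, 0.01)
        ser = tk.serial_nca_summary(ds, 30.0, 1, SummaryKind.ARITHMETIC, 0.01)
        assert comp.auc24 == pytest.approx(ser.auc24, rel=1e-12)
        assert comp.cmax24 == pytest.approx(ser.cmax24, rel=1e-12)
        assert comp.tat24 == pytest.approx(ser.tat24, rel=1e-12)

    def test_individual_summary_kind_rejected_for_pooled_profiles(self, week_dataset):
        with pytest.raises(InputError):
            tk.composite_mean_profile(week_dataset, 30.0, 1, SummaryKind.INDIVIDUAL)
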