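import math

import numpy as np
import pytest

from hemopk import (
    ConcentrationProfile,
    NonCompartmentalModel,
    PKParameters,
    StudyConfig,
    aggregate_group,
    auc_extrapolate,
    auc_linear_trapezoid,
    cmax,
    nca_subject,
    simulate_study,
    simulate_subject,
    terminal_slope,
)
from hemopk.nca import LN2, TerminalFitError


def profile(times, concs, analyte="free_hb"):
    return ConcentrationProfile("s01", analyte, np.asarray(times, float),
                                np.asarray(concs, float))


class TestCmax:
    def test_basic_and_monotone(self):
        assert cmax(profile([0, 0.25, 1], [0, 300, 200])) == (300.0, 0.25)
        assert cmax(profile([0, 1, 2], [50, 40, 30])) == (50.0, 0.0)

    def test_tie_goes_to_earlier_time(self):
        assert cmax(profile([0, 1, 2, 3], [0, 7, 7, 1]))[1] == 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            cmax(profile([0, 1], [np.nan, np.nan]))


class TestAucTrapezoid:
    def test_triangle_and_rectangle(self):
        assert auc_linear_trapezoid([0, 1, 2], [0, 10, 0]) == 10.0
        assert auc_linear_trapezoid([0, 4], [5, 5]) == 20.0

    def test_dense_exponential_matches_analytic(self):
        t = np.arange(0.0, 20.0, 0.001)
        c = 100.0 * np.exp(-0.5 * t)
        # analytic C0/k = 200 minus the tail beyond t=20 (negligible)
        assert auc_linear_trapezoid(t, c) == pytest.approx(200.0, rel=1e-4)

    def test_missing_samples_are_spanned(self):
        full = auc_linear_trapezoid([0, 1, 2], [0, 10, 0])
        gap = auc_linear_trapezoid([0, 1, 1.5, 2], [0, 10, np.nan, 0])
        assert gap == full

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            auc_linear_trapezoid([0, 1], [5, np.nan])

    def test_matches_cumsum_oracle_on_random_profiles(self, rng):
        """Independent oracle: explicit pairwise trapezoid accumulation."""
        for _ in range(1000):
            n = rng.integers(3, 15)
            t = np.sort(rng.uniform(0, 60, n))
            t += np.arange(n) * 1e-6  # strictly increasing
            c = rng.uniform(0, 400, n)
            oracle = sum((t[i + 1] - t[i]) * (c[i] + c[i + 1]) / 2.0
                         for i in range(n - 1))
            assert auc_linear_trapezoid(t, c) == pytest.approx(
                oracle, rel=1e-12, abs=1e-12)


class TestTerminalSlope:
    def test_exact_exponential(self):
        t = np.array([24.0, 32.0, 36.0, 48.0, 60.0])
        c = 50.0 * np.exp(-0.1 * t)
        k, r2, n = terminal_slope(t, c)
        assert k == pytest.approx(0.1, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_halving_over_24h(self):
        # halving from 10 uM at 24 h to 5 uM at 48 h, third point consistent
        t = np.array([12.0, 24.0, 48.0])
        c = 20.0 * 2.0 ** (-t / 24.0)  # (14.14, 10, 5)
        k, _, _ = terminal_slope(t, c)
        assert k == pytest.approx(math.log(2) / 24, rel=1e-9)

    def test_matches_brute_force_regression_oracle(self, rng):
        """OLS on log-concentration, computed from the normal equations."""
        for _ in range(200):
            n = int(rng.integers(4, 9))
            t = np.sort(rng.uniform(10, 60, n)) + np.arange(n) * 1e-4
            c = np.exp(rng.normal(2.0, 0.3, n) - 0.08 * t)
            k, _, m = terminal_slope(t, c, selection=n)
            x, y = t, np.log(c)
            slope = (n * (x * y).sum() - x.sum() * y.sum()) / (
                n * (x * x).sum() - x.sum() ** 2)
            assert k == pytest.approx(-slope, rel=1e-12)

    def test_rising_terminal_phase_flagged(self):
        with pytest.raises(TerminalFitError):
            terminal_slope([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])

    def test_selection_search_prefers_log_linear_stretch(self):
        """A profile with a fast early phase and clean slow tail: the
        adjusted-r^2 search must recover the tail rate, not a blend."""
        t = np.array([0.5, 1.0, 2.0, 8.0, 12.0, 16.0, 24.0, 32.0])
        c = 300.0 * np.exp(-2.0 * t) + 100.0 * np.exp(-0.05 * t)
        k, _, n = terminal_slope(t, c)
        assert k == pytest.approx(0.05, rel=0.01)


class TestAucExtrapolate:
    def test_formula_and_fraction(self):
        assert auc_extrapolate(10.0, 0.1) == 100.0
        assert auc_extrapolate(0.0, 0.5) == 0.0
        auc_inf = 900.0 + auc_extrapolate(10.0, 0.1)
        assert auc_extrapolate(10.0, 0.1) / auc_inf == pytest.approx(0.1)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            auc_extrapolate(10.0, 0.0)


class TestNcaSubject:
    def test_closed_form_one_compartment(self):
        """C(t) = (100/2) e^{-0.2 t}: CL = k V = 0.4 L/h, Vc = 2 L,
        t1/2 = ln2/0.2."""
        t = np.arange(0.0, 60.0, 0.01)
        t[0] = 1e-9
        p = profile(t, (100.0 / 2.0) * np.exp(-0.2 * t))
        res = nca_subject(p, dose_umol_heme=100.0)
        assert res.cl_L_per_h == pytest.approx(0.4, rel=0.005)
        assert res.vc_L == pytest.approx(2.0, rel=0.005)
        assert res.t_half_h == pytest.approx(math.log(2) / 0.2, rel=0.005)

    def test_identities_hold_exactly(self, prednisone_config):
        for free, bound, truth in simulate_study(prednisone_config):
            res = NonCompartmentalModel.from_profile(
                bound, truth.dose_umol_heme, loq_uM=1.0).fit().params
            assert res.auc_0_inf == pytest.approx(
                res.auc_0_clast + res.auc_clast_inf, rel=1e-15)
            assert res.cl_L_per_h * res.auc_0_inf == pytest.approx(
                res.dose_umol_heme, rel=1e-12)
            assert res.vc_L * res.cmax_uM == pytest.approx(
                res.dose_umol_heme, rel=1e-12)
            assert res.t_half_h * res.cl_L_per_h == pytest.approx(
                LN2 * res.vc_L, rel=1e-12)

    def test_pseudo_subject_from_group_mean_statistics(self):
        """Feeding group-mean Cmax and AUC through the defining ratios gives
        Vc = dose/Cmax and CL = dose/AUC; a mean of per-subject ratios is a
        nearby but different number (Jensen), so agreement is loose."""
        dose = 248.2
        cmax_mean, auc_mean = 377.2, 1929.0
        vc = dose / cmax_mean
        cl = dose / auc_mean
        assert vc == pytest.approx(0.658, abs=0.001)
        assert cl == pytest.approx(0.1287, abs=0.0005)
        # within ~5% of the corresponding mean-of-ratio estimates 0.667, 0.1319
        assert vc == pytest.approx(0.667, rel=0.05)
        assert cl == pytest.approx(0.1319, rel=0.05)

    def test_dose_scaling_law(self, one_compartment_config):
        free, _, truth = simulate_subject(one_compartment_config, 0)
        r1 = nca_subject(free, truth.dose_umol_heme)
        r2 = nca_subject(free, 2.0 * truth.dose_umol_heme)
        assert r2.cl_L_per_h == pytest.approx(2 * r1.cl_L_per_h, rel=1e-12)
        assert r2.vc_L == pytest.approx(2 * r1.vc_L, rel=1e-12)
        assert r2.t_half_h == pytest.approx(r1.t_half_h, rel=1e-12)

    def test_parameter_recovery_noise_free(self, one_compartment_config):
        """One-compartment arm on the 22-point schedule: CL within 2%, k
        within 1%; Vc within 6% (the 10-min infusion biases Cmax low)."""
        cfg = one_compartment_config
        free, _, truth = simulate_subject(cfg, 0)
        res = nca_subject(free, truth.dose_umol_heme)
        assert res.k_terminal == pytest.approx(cfg.k_el_free, rel=0.01)
        assert res.cl_L_per_h == pytest.approx(
            truth.cl_L_per_h["free_hb"], rel=0.02)
        assert res.vc_L == pytest.approx(cfg.plasma_volume_L, rel=0.06)

    def test_cl_recovery_under_proportional_noise(self):
        """Median |CL error| stays under 10% across replicate noisy studies."""
        errors = []
        for rep in range(30):
            cfg = StudyConfig(hp_dose_g=0.0, basal_hp_uM=0.0, k_el_free=0.2,
                              noise_cv=0.10, loq_uM=1.0, n_subjects=6,
                              seed=1000 + rep)
            for free, _, truth in simulate_study(cfg):
                res = nca_subject(free, truth.dose_umol_heme, loq_uM=1.0)
                errors.append(abs(res.cl_L_per_h / truth.cl_L_per_h["free_hb"] - 1))
        assert np.median(errors) < 0.10

    def test_from_dataframe_and_summary(self, one_compartment_config):
        free, _, truth = simulate_subject(one_compartment_config, 0)
        df = free.to_frame()
        res = NonCompartmentalModel.from_dataframe(df, truth.dose_umol_heme).fit()
        text = res.summary()
        assert "Cmax" in text and "t1/2" in text and "Vc" in text


class TestAggregateGroup:
    def _params(self, value):
        return PKParameters(*([value] * 10), 4, 1.0, 248.2)

    def test_identical_subjects_have_zero_sem(self):
        g = aggregate_group([self._params(2.0)] * 5)
        assert g.mean["cl_L_per_h"] == 2.0
        assert g.sem["cl_L_per_h"] == 0.0

    def test_mean_and_sem_hand_computed(self):
        g = aggregate_group([self._params(v) for v in (1.0, 2.0, 3.0)])
        assert g.mean["cmax_uM"] == pytest.approx(2.0)
        assert g.sem["cmax_uM"] == pytest.approx(0.5774, abs=1e-4)

    def test_single_subject_sem_is_missing(self):
        g = aggregate_group([self._params(1.0)])
        assert g.n == 1 and math.isnan(g.sem["cmax_uM"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group([])

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        """mean(dose/AUC_i) != dose/mean(AUC_i) whenever the AUCs vary."""
        dose = 100.0
        aucs = np.array([800.0, 1000.0, 1400.0])
        mean_of_ratios = np.mean(dose / aucs)
        ratio_of_means = dose / aucs.mean()
        assert mean_of_ratios > ratio_of_means
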