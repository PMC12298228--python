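"""PK metric definitions: extrema, AUCs, terminal half-life, CL/F, distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from losartan_pkpd import (
    AnalysisError,
    ConcentrationSeries,
    DoseRegimen,
    auc_0_inf,
    auc_x_y,
    cl_over_f,
    cmax_tmax,
    curve_distance,
    half_life_semilog,
    pk_summary,
    simulate,
)


def series_from(times, c_p, c_m=None, **meta):
    c_p = np.asarray(c_p, dtype=float)
    c_m = c_p.copy() if c_m is None else np.asarray(c_m, dtype=float)
    return ConcentrationSeries(times=np.asarray(times, float), C_p=c_p, C_m=c_m, **meta)


class TestCmaxTmax:
    def test_monotone_decreasing_peaks_at_first_point(self):
        t = np.linspace(0.0, 10, 101)
        s = series_from(t, 100 * np.exp(-0.3 * t))
        cmax, tmax = cmax_tmax(s)
        assert tmax == t[0] and cmax == pytest.approx(100.0)

    def test_bateman_extremum(self):
        # first-order absorption/elimination: tmax = ln(ka/ke)/(ka-ke)
        ka, ke = 1.0, 0.5
        t = np.arange(0.0, 24.0, 0.01)
        s = series_from(t, np.exp(-ke * t) - np.exp(-ka * t))
        _, tmax = cmax_tmax(s)
        assert tmax == pytest.approx(np.log(2.0) / 0.5, abs=0.011)

    def test_linearity_in_dose(self, gg_params):
        s1 = simulate(gg_params, DoseRegimen(dose_mg=50.0), t_end=12.0)
        s2 = simulate(gg_params, DoseRegimen(dose_mg=100.0), t_end=12.0)
        c1, t1 = cmax_tmax(s1)
        c2, t2 = cmax_tmax(s2)
        assert c2 == pytest.approx(2 * c1, rel=1e-6) and t1 == t2


class TestAUC:
    def test_zero_curve_zero_auc(self):
        t = np.linspace(0, 48, 100)
        assert auc_0_inf(series_from(t, np.zeros_like(t))) == 0.0

    def test_exponential_analytic_value(self):
        t = np.arange(0.0, 48.0001, 0.001)
        s = series_from(t, 100.0 * np.exp(-0.5 * t))
        assert auc_0_inf(s, horizon=48.0) == pytest.approx(200.0, rel=1e-4)

    def test_augmented_state_matches_fine_trapezoid(self, gg_params):
        s = simulate(gg_params, DoseRegimen(dose_mg=50.0), t_end=48.0, output_step=0.001)
        for analyte in ("losartan", "E3174"):
            ode = auc_0_inf(s, analyte, horizon=48.0, method="ode")
            trap = auc_0_inf(s, analyte, horizon=48.0, method="trapezoid")
            assert trap == pytest.approx(ode, rel=1e-4)

    def test_horizon_beyond_series_is_an_error(self):
        t = np.linspace(0, 24, 100)
        with pytest.raises(AnalysisError):
            auc_0_inf(series_from(t, np.ones_like(t)), horizon=48.0)

    def test_partial_aucs(self):
        t = np.linspace(0, 10, 1001)
        s = series_from(t, np.ones_like(t))
        assert auc_x_y(s, 2.0, 2.0) == 0.0
        assert auc_x_y(s, 2.0, 4.0) == pytest.approx(2.0, rel=1e-10)
        with pytest.raises(AnalysisError):
            auc_x_y(s, 4.0, 2.0)

    def test_partial_auc_additivity(self, gg_params):
        s = simulate(gg_params, DoseRegimen(dose_mg=50.0), t_end=24.0)
        lhs = auc_x_y(s, 0.0, 6.0) + auc_x_y(s, 6.0, 24.0)
        assert lhs == pytest.approx(auc_x_y(s, 0.0, 24.0), rel=1e-8)

    def test_auc_converges_with_horizon(self, gg_params):
        # past ~5 terminal half-lives the integral is effectively complete
        s = simulate(gg_params, DoseRegimen(dose_mg=50.0), t_end=96.0, output_step=0.02)
        a48 = auc_0_inf(s, "E3174", horizon=48.0)
        a96 = auc_0_inf(s, "E3174", horizon=96.0)
        assert abs(a96 - a48) / a96 < 1e-3


class TestHalfLife:
    def test_pure_exponential(self):
        t = np.arange(0.0, 12.001, 0.01)
        s = series_from(t, 50.0 * np.exp(-np.log(2.0) * t))
        assert half_life_semilog(s) == pytest.approx(1.0, rel=1e-6)

    def test_flat_curve_has_no_terminal_decline(self):
        t = np.arange(0.0, 12.001, 0.5)
        with pytest.raises(AnalysisError, match="no terminal decline"):
            half_life_semilog(series_from(t, np.ones_like(t)))

    def test_biexponential_matches_direct_ols_oracle(self):
        t = np.arange(0.0, 12.001, 0.01)
        c = 80.0 * np.exp(-0.9 * t) + 20.0 * np.exp(-0.25 * t)
        s = series_from(t, c)
        anchors = np.array([6.0, 8.0, 10.0])
        logc = np.log(80.0 * np.exp(-0.9 * anchors) + 20.0 * np.exp(-0.25 * anchors))
        slope = np.polyfit(anchors, logc, 1)[0]
        assert half_life_semilog(s) == pytest.approx(np.log(2.0) / -slope, rel=1e-8)

    def test_nonpositive_anchor_concentration_rejected(self):
        t = np.arange(0.0, 12.001, 0.5)
        c = np.where(t < 7.0, 10.0, 0.0)
        with pytest.raises(AnalysisError):
            half_life_semilog(series_from(t, c))


class TestClearance:
    @pytest.mark.parametrize(
        "auc,expected,tol",
        [
            (1349.1, 80.4, 0.05),
            (1352.644, 80.182, 0.001),
            (2444.236, 44.373, 0.001),
            (1352.6, 80.2, 0.05),
        ],
    )
    def test_published_dose_auc_pairs(self, auc, expected, tol):
        assert cl_over_f(DoseRegimen(dose_mg=50.0), auc) == pytest.approx(expected, abs=tol)

    def test_zero_branch_and_negative_error(self):
        assert cl_over_f(DoseRegimen(dose_mg=50.0), 0.0) == 0.0
        with pytest.raises(AnalysisError):
            cl_over_f(DoseRegimen(dose_mg=50.0), -1.0)

    def test_algebraic_inverse_recovers_dose(self):
        dose = DoseRegimen(dose_mg=50.0)
        auc = 1234.5
        cl = cl_over_f(dose, auc)
        assert cl * auc * dose.molecular_weight / 1e6 == pytest.approx(dose.dose_mg, rel=1e-12)


class TestCurveDistance:
    def test_identical_curves(self):
        t = np.linspace(0, 10, 11)
        s = series_from(t, np.sin(t) ** 2)
        assert curve_distance(s, s) == 0.0

    def test_unit_offsets_at_four_points(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        a = series_from(t, np.full(4, 5.0))
        b = series_from(t, np.full(4, 6.0))
        assert curve_distance(a, b) == pytest.approx(2.0, rel=1e-12)

    def test_against_brute_force_on_partial_overlap(self):
        rng = np.random.default_rng(7)
        ta = np.arange(0.0, 10.0, 0.5)
        tb = np.arange(0.25, 12.0, 0.25)
        ca, cb = rng.uniform(0, 100, ta.size), rng.uniform(0, 100, tb.size)
        a, b = series_from(ta, ca), series_from(tb, cb)
        common = sorted(set(ta) & set(tb))
        brute = np.sqrt(
            sum(
                (ca[list(ta).index(t)] - cb[list(tb).index(t)]) ** 2
                for t in common
            )
        )
        assert curve_distance(a, b) == pytest.approx(brute, rel=1e-12)

    def test_no_common_points_is_an_error(self):
        a = series_from([0.0, 1.0], [1.0, 1.0])
        b = series_from([0.5, 1.5], [1.0, 1.0])
        with pytest.raises(AnalysisError):
            curve_distance(a, b)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1e3), min_size=3, max_size=12))
    def test_symmetry_and_triangle_inequality(self, values):
        t = np.arange(len(values), dtype=float)
        rng = np.random.default_rng(len(values))
        a = series_from(t, values)
        b = series_from(t, rng.uniform(0, 1e3, t.size))
        c = series_from(t, rng.uniform(0, 1e3, t.size))
        d_ab = curve_distance(a, b)
        assert d_ab == curve_distance(b, a)
        assert d_ab <= curve_distance(a, c) + curve_distance(c, b) + 1e-9


class TestSummary:
    def test_summary_panel_consistency(self, gg_params, dose50):
        s = simulate(gg_params, dose50, t_end=48.0, genotype_label="GG/CC")
        summ = pk_summary(s, dose50, auc_windows=((0.0, 24.0),))
        assert summ.cmax_losartan == cmax_tmax(s, "losartan")[0]
        assert summ.auc0inf_losartan >= summ.auc_windows[(0.0, 24.0)][0]
        assert summ.cl_over_f == pytest.approx(
            cl_over_f(dose50, summ.auc0inf_losartan), rel=1e-12
        )
        d = summ.to_dict()
        assert d["Cmax_losartan_nM"] == summ.cmax_losartan
        assert d["AUC0inf_E3174_nmolh_L"] == summ.auc0inf_E3174
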