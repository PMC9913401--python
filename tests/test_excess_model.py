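"""Penalized excess-hazard regression: likelihood, AICc, selection, EHR."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import depsurv.excess_model as em
from depsurv.excess_model import (
    BasisConfig,
    ExcessHazardModel,
    ExcessModelFit,
    FormBasis,
    aicc,
    ehr_p90_p10_over_time,
    ehr_vs_edi,
    fit_excess_hazard,
    select_model,
)

from conftest import build_cohort, build_life_table


def weibull_cohort(n, seed, log_ehr=0.0, shape=0.8, scale=8.0):
    """Cohort with Weibull excess hazard and optional proportional EDI effect."""
    r = np.random.default_rng(seed)
    age = np.clip(r.normal(70, 10, n), 40, 95)
    edi = np.clip(r.normal(0, 6, n), -17, 51)
    beta = log_ehr / 8.3
    tex = scale * np.exp(-beta * edi / shape) * (-np.log(r.uniform(size=n))) ** (1 / shape)
    cens = r.uniform(3.5, 7.5, n)
    T = np.minimum(tex, cens)
    D = (tex <= cens).astype(int)
    return build_cohort(T, D, age=age, year=2007.0, edi=edi)


SMALL_CONFIG = BasisConfig(time_interior=(1.0,), age_interior_q=(), edi_interior_q=())


class TestAicc:
    def _dummy_fit(self, loglik, edf, n_events):
        return ExcessModelFit(
            form=1, basis=None, beta=np.zeros(1), covariance=np.eye(1),
            smoothing=np.zeros(0), edf=edf, loglik=loglik, penalized_loglik=loglik,
            aicc=np.nan, n_events=n_events, model=None,
        )

    def test_closed_form_value(self):
        # -2(-100) + 2*4 + 2*4*5/(50-5) = 208 + 40/45
        fit = self._dummy_fit(-100.0, 4.0, 50)
        assert aicc(fit) == pytest.approx(208.0 + 40.0 / 45.0, abs=1e-10)

    def test_zero_edf_limit(self):
        fit = self._dummy_fit(-123.0, 0.0, 50)
        assert aicc(fit) == pytest.approx(246.0, abs=1e-10)

    def test_undefined_when_too_few_events(self):
        fit = self._dummy_fit(-10.0, 5.0, 6)
        with pytest.raises(ValueError, match="undefined"):
            aicc(fit)

    def test_matches_independent_formula_on_real_fit(self):
        coh = weibull_cohort(500, 1)
        fit = fit_excess_hazard(coh, None, 1, basis_config=SMALL_CONFIG,
                                penalty_grid=(1.0,))
        want = (-2 * fit.loglik + 2 * fit.edf
                + 2 * fit.edf * (fit.edf + 1) / (fit.n_events - fit.edf - 1))
        assert aicc(fit) == pytest.approx(want, abs=1e-10)
        assert fit.aicc == pytest.approx(want, abs=1e-10)


class TestLikelihoodMachinery:
    def test_analytic_score_matches_finite_differences(self):
        coh = weibull_cohort(400, 2)
        lt = build_life_table(rate=0.03, ages=range(39, 97), years=range(2005, 2015))
        basis = FormBasis(2, BasisConfig(), coh)
        model = ExcessHazardModel(coh, lt, basis, gl_nodes=8)
        r = np.random.default_rng(3)
        beta = r.normal(0, 0.1, basis.p)
        g = model.score(beta, 1.0)
        num = np.zeros_like(beta)
        for j in range(len(beta)):
            e = np.zeros_like(beta)
            e[j] = 1e-5
            num[j] = (model.loglik(beta + e, 1.0) - model.loglik(beta - e, 1.0)) / 2e-5
        assert np.max(np.abs(g - num)) / np.max(np.abs(num)) < 1e-5

    def test_doubling_quadrature_nodes_changes_loglik_negligibly(self):
        coh = weibull_cohort(600, 4)
        fit = fit_excess_hazard(coh, None, 2, penalty_grid=(10.0,), gl_nodes=12)
        basis = fit.basis
        m24 = ExcessHazardModel(coh, None, basis, gl_nodes=24)
        ll12 = fit.loglik
        ll24 = m24.loglik(fit.beta, 0.0)
        assert abs(ll24 - ll12) / abs(ll24) < 1e-6

    def test_duplicating_records_leaves_argmax_invariant(self):
        coh = weibull_cohort(400, 5)
        double = pd.concat([coh, coh], ignore_index=True)
        f1 = fit_excess_hazard(coh, None, 1, basis_config=SMALL_CONFIG,
                               penalty_grid=(1.0,))
        f2 = fit_excess_hazard(double, None, 1, basis_config=SMALL_CONFIG,
                               penalty_grid=(2.0,))  # penalty scales with the data
        assert np.allclose(f1.beta, f2.beta, atol=1e-4)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-6)
        assert f2.aicc != pytest.approx(f1.aicc, rel=1e-3)

    def test_unpenalized_likelihoods_nest_with_shared_marginals(self):
        coh = weibull_cohort(1500, 6, log_ehr=np.log(1.6))
        config = BasisConfig(
            time_interior=(1.0,), age_interior_q=(), edi_interior_q=(),
            tensor3_time_interior=(1.0,), tensor3_age_interior_q=(),
            tensor3_edi_interior_q=(),
        )
        lls = []
        for form in (1, 2, 3, 4):
            fit = fit_excess_hazard(coh, None, form, basis_config=config,
                                    penalty_grid=(1e-6,))
            lls.append(fit.loglik)
        assert lls[1] >= lls[0] - 1e-3
        assert lls[2] >= lls[1] - 1e-3
        assert lls[3] >= lls[2] - 1e-2

    def test_empty_cohort_rejected(self):
        coh = weibull_cohort(10, 7).iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            fit_excess_hazard(coh, None, 1)


class TestModelSelection:
    def test_argmin_with_parsimony_tie_break(self, monkeypatch):
        values = {1: 10.0, 2: 9.0, 3: 11.0, 4: 12.0}

        def fake_fit(cohort, lt, form, **kw):
            return dataclasses.replace(
                ExcessModelFit(
                    form=form, basis=None, beta=np.zeros(1), covariance=np.eye(1),
                    smoothing=np.zeros(0), edf=1.0, loglik=0.0, penalized_loglik=0.0,
                    aicc=values[form], n_events=100, model=None,
                )
            )

        monkeypatch.setattr(em, "fit_excess_hazard", fake_fit)
        best, table = select_model(pd.DataFrame({"x": [1]}), None)
        assert best.form == 2
        assert table == values

    def test_exact_tie_prefers_lower_form(self, monkeypatch):
        def fake_fit(cohort, lt, form, **kw):
            return ExcessModelFit(
                form=form, basis=None, beta=np.zeros(1), covariance=np.eye(1),
                smoothing=np.zeros(0), edf=1.0, loglik=0.0, penalized_loglik=0.0,
                aicc=5.0 if form in (2, 3) else 9.0, n_events=100, model=None,
            )

        monkeypatch.setattr(em, "fit_excess_hazard", fake_fit)
        best, _ = select_model(pd.DataFrame({"x": [1]}), None)
        assert best.form == 2

    def test_failed_forms_are_skipped_with_warning(self, monkeypatch):
        def fake_fit(cohort, lt, form, **kw):
            if form in (1, 2):
                raise em.FitError("boom")
            return ExcessModelFit(
                form=form, basis=None, beta=np.zeros(1), covariance=np.eye(1),
                smoothing=np.zeros(0), edf=1.0, loglik=0.0, penalized_loglik=0.0,
                aicc=float(form), n_events=100, model=None,
            )

        monkeypatch.setattr(em, "fit_excess_hazard", fake_fit)
        with pytest.warns(UserWarning, match="failed"):
            best, table = select_model(pd.DataFrame({"x": [1]}), None)
        assert best.form == 3
        assert np.isnan(table[1]) and np.isnan(table[2])

    def test_all_forms_failing_raises(self, monkeypatch):
        def fake_fit(cohort, lt, form, **kw):
            raise em.FitError("boom")

        monkeypatch.setattr(em, "fit_excess_hazard", fake_fit)
        with pytest.raises(em.FitError, match="all candidate forms"):
            with pytest.warns(UserWarning):
                select_model(pd.DataFrame({"x": [1]}), None)


@pytest.fixture(scope="module")
def form2_fit():
    coh = weibull_cohort(1200, 8, log_ehr=np.log(1.5))
    return fit_excess_hazard(coh, None, 2, penalty_grid=(1.0, 100.0))


class TestEHRCurves:
    def test_reference_point_is_exactly_one_with_degenerate_ci(self, form2_fit):
        c = ehr_vs_edi(form2_fit, 1.0, 70.0, ref_edi=-3.9, edi_grid=[-3.9, 0.0])
        assert c.ehr[0] == 1.0 and c.lo[0] == 1.0 and c.hi[0] == 1.0
        assert c.lo[1] <= c.ehr[1] <= c.hi[1]

    def test_form1_curve_is_identically_one(self):
        coh = weibull_cohort(400, 9)
        fit = fit_excess_hazard(coh, None, 1, basis_config=SMALL_CONFIG,
                                penalty_grid=(1.0,))
        c = ehr_vs_edi(fit, 1.0, 70.0)
        assert np.allclose(c.ehr, 1.0) and np.allclose(c.lo, 1.0)
        curves = ehr_p90_p10_over_time(fit, np.linspace(0.1, 5, 7))
        for cv in curves:
            assert np.allclose(cv.ehr, 1.0)

    def test_linear_edi_smooth_gives_loglinear_ehr_with_slope_beta(self):
        coh = weibull_cohort(1200, 10, log_ehr=np.log(1.5))
        config = BasisConfig(edi_linear=True)
        fit = fit_excess_hazard(coh, None, 2, basis_config=config,
                                penalty_grid=(1.0,))
        beta_lin = fit.beta[-1]  # the single linear-EDI column comes last
        grid = np.array([-5.0, 0.0, 5.0, 10.0])
        c = ehr_vs_edi(fit, 1.0, 70.0, ref_edi=0.0, edi_grid=grid)
        assert np.allclose(np.log(c.ehr), beta_lin * grid, atol=1e-12)

    def test_form2_p90_p10_curve_is_flat_in_time_and_age(self, form2_fit):
        curves = ehr_p90_p10_over_time(form2_fit, np.linspace(0.1, 5, 9))
        vals = np.array([cv.ehr for cv in curves])
        assert np.ptp(vals) < 1e-10
        assert vals[0, 0] > 1.1  # the simulated effect is recovered as positive

    def test_ehr_invariant_under_affine_edi_rescaling(self):
        coh = weibull_cohort(800, 11, log_ehr=np.log(1.5))
        coh2 = coh.assign(edi=2.0 * coh["edi"] + 3.0)
        grid = np.array([-3.9, 0.0, 4.4])

        def ehr(cohort, edi_pen, ref, g):
            basis = FormBasis(2, BasisConfig(), cohort)
            model = ExcessHazardModel(cohort, None, basis, gl_nodes=12)
            beta = model.newton(np.array([10.0, 10.0, edi_pen]))
            m = len(g)
            d = (basis.design(np.ones(m), np.full(m, 70.0), g)
                 - basis.design([1.0], [70.0], [ref]))
            return np.exp(d @ beta)

        e1 = ehr(coh, 10.0, -3.9, grid)
        # the order-2 curvature penalty scales as a^3 under x -> ax + b
        e2 = ehr(coh2, 10.0 * 2.0**3, 2 * -3.9 + 3, 2 * grid + 3)
        assert np.allclose(e1, e2, rtol=1e-5)

    def test_extrapolation_beyond_support_warns(self, form2_fit):
        with pytest.warns(UserWarning, match="support"):
            ehr_vs_edi(form2_fit, 1.0, 70.0, edi_grid=[0.0, 500.0])
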