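"""Arrhenius fitting: closed-form equivalence, invariances, one-step fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aslt import (
    ArrheniusModel,
    ArrheniusRegression,
    OneStepArrhenius,
    RateConstantSet,
    compute_k0,
    fit_arrhenius_onestep,
    fit_arrhenius_twostep,
    predict_rate,
    reference_rate_set,
)
from aslt.arrhenius import GAS_CONSTANT, T_REF_DEFAULT, InsufficientDesignError
from aslt.synthetic import SyntheticIndexSpec, SyntheticStudyConfig, generate_series

R = GAS_CONSTANT


def two_point_ea(T1, k1, T2, k2):
    """Closed-form two-point solution: Ea = R ln(k2/k1) / (1/T1 - 1/T2)."""
    return R * np.log(k2 / k1) / (1.0 / T1 - 1.0 / T2)


class TestTwoStep:
    def test_two_point_closed_form_oracle(self):
        # k=1 at 300 K, k=2 at 310 K
        rates = RateConstantSet(
            "X", ((300 - 273.15, 1.0, 0.0), (310 - 273.15, 2.0, 0.0))
        )
        model = fit_arrhenius_twostep(rates)
        expected = two_point_ea(300.0, 1.0, 310.0, 2.0)
        assert expected == pytest.approx(53.6e3, rel=2e-3)  # sanity on the oracle
        assert model.Ea == pytest.approx(expected, rel=1e-10)
        assert model.r2 == 1.0

    def test_equal_rates_give_zero_ea(self):
        rates = RateConstantSet("X", ((25.0, 0.5, 0.0), (60.0, 0.5, 0.0)))
        model = fit_arrhenius_twostep(rates)
        assert model.Ea == pytest.approx(0.0, abs=1e-9)  # J/mol round-off
        assert model.k_ref == pytest.approx(0.5)
        assert model.k0 == pytest.approx(0.5)

    def test_log_linear_equals_closed_form_ols(self, k270_rates):
        """The fitted (Ea, ln k_ref) equal the analytic normal-equation OLS."""
        model = fit_arrhenius_twostep(k270_rates)
        T = k270_rates.temperatures + 273.15
        x = 1.0 / T - 1.0 / model.T_ref
        y = np.log(k270_rates.k)
        xm, ym = x.mean(), y.mean()
        slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        intercept = ym - slope * xm
        assert model.Ea == pytest.approx(-R * slope, rel=1e-12)
        assert model.k_ref == pytest.approx(np.exp(intercept), rel=1e-12)

    def test_insufficient_design_rejected(self):
        with pytest.raises(InsufficientDesignError):
            RateConstantSet("X", ((25.0, 1.0, 0.0), (25.0, 2.0, 0.0)))

    def test_nonpositive_rate_rejected_in_log_space(self):
        rates = RateConstantSet("X", ((25.0, -1.0, 0.0), (60.0, 2.0, 0.0)))
        with pytest.raises(ValueError, match="non-positive"):
            fit_arrhenius_twostep(rates)

    def test_nonlinear_space_matches_generating_parameters(self):
        Ea, kref = 60e3, 1e-3
        T = np.array([25.0, 40.0, 50.0, 60.0])
        x = 1.0 / (T + 273.15) - 1.0 / T_REF_DEFAULT
        k = kref * np.exp(-Ea / R * x)
        rates = RateConstantSet("X", tuple((t, kk, 0.0) for t, kk in zip(T, k)))
        model = fit_arrhenius_twostep(rates, fit_space="nonlinear")
        assert model.Ea == pytest.approx(Ea, rel=1e-8)
        assert model.k_ref == pytest.approx(kref, rel=1e-8)
        assert model.fit_space == "nonlinear"


class TestModelIdentities:
    def test_k0_identity_holds_exactly(self, k270_model):
        m = k270_model
        assert m.k0 == pytest.approx(
            np.exp(np.log(m.k_ref) + m.Ea / (m.gas_constant * m.T_ref)), rel=1e-14
        )
        assert compute_k0(m) == m.k0

    def test_k0_reduces_to_kref_when_ea_zero(self):
        m = ArrheniusModel(
            Ea=0.0, k_ref=0.7, T_ref=318.15, gas_constant=R, r2=1.0,
            covariance=np.zeros((2, 2)), fit_space="log-linear", method="two-step",
        )
        assert m.k0 == pytest.approx(0.7)

    def test_k0_direct_evaluation(self):
        m = ArrheniusModel(
            Ea=53.57e3, k_ref=1.0, T_ref=305.0, gas_constant=8.31, r2=1.0,
            covariance=np.zeros((2, 2)), fit_space="log-linear", method="two-step",
        )
        assert m.k0 == pytest.approx(np.exp(53570.0 / (8.31 * 305.0)), rel=1e-12)

    def test_predict_at_t_ref_returns_k_ref(self, k270_model):
        t_ref_c = k270_model.T_ref - 273.15
        assert predict_rate(k270_model, t_ref_c) == pytest.approx(
            k270_model.k_ref, rel=1e-14
        )

    def test_reparametrized_and_classical_forms_agree(self, k270_model):
        m = k270_model
        for t in (-5.0, 25.0, 45.0, 60.0, 75.0):
            via_kref = predict_rate(m, t)
            via_k0 = m.k0 * np.exp(-m.Ea / (m.gas_constant * (t + 273.15)))
            assert via_kref == pytest.approx(via_k0, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(t_ref=st.floats(280.0, 360.0))
    def test_t_ref_invariance(self, k270_rates, t_ref):
        """Changing T_ref moves k_ref but leaves Ea, k0 and predictions fixed."""
        base = fit_arrhenius_twostep(k270_rates)
        other = fit_arrhenius_twostep(k270_rates, T_ref=t_ref)
        assert other.Ea == pytest.approx(base.Ea, rel=1e-9)
        assert other.k0 == pytest.approx(base.k0, rel=1e-9)
        for t in (20.0, 25.0, 60.0):
            assert predict_rate(other, t) == pytest.approx(
                predict_rate(base, t), rel=1e-9
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3))
    def test_unit_scaling_invariance(self, k270_rates, c):
        """Rescaling all k by c rescales k_ref and k0 by c; Ea unchanged."""
        scaled = RateConstantSet(
            "K270", tuple((t, k * c, se) for t, k, se in k270_rates.entries)
        )
        base = fit_arrhenius_twostep(k270_rates)
        other = fit_arrhenius_twostep(scaled)
        assert other.Ea == pytest.approx(base.Ea, rel=1e-9)
        assert other.k_ref == pytest.approx(base.k_ref * c, rel=1e-9)
        assert other.k0 == pytest.approx(base.k0 * c, rel=1e-9)

    def test_serialization_round_trip(self, k270_model):
        m2 = ArrheniusModel.from_dict(k270_model.to_dict())
        assert m2.Ea == k270_model.Ea
        assert m2.k0 == k270_model.k0
        assert predict_rate(m2, 33.0) == predict_rate(k270_model, 33.0)


def _noiseless_study(Ea, k_ref, I0=0.15):
    spec = SyntheticIndexSpec(
        index_id="K270", I0=I0, sigma=0.0, unit="AU", Ea=Ea, k_ref=k_ref
    )
    cfg = SyntheticStudyConfig(indices=(spec,), seed=0)
    series, _ = generate_series(cfg)
    return series


class TestOneStep:
    def test_noiseless_recovery_of_generating_parameters(self, k270_model):
        series = _noiseless_study(Ea=58.39e3, k_ref=k270_model.k_ref)
        model = fit_arrhenius_onestep(series)
        assert model.Ea == pytest.approx(58.39e3, rel=1e-6)
        assert model.k_ref == pytest.approx(k270_model.k_ref, rel=1e-6)
        assert model.method == "one-step"

    def test_shared_intercept_identical_on_common_intercept_data(self, k270_model):
        series = _noiseless_study(Ea=58.39e3, k_ref=k270_model.k_ref)
        free = fit_arrhenius_onestep(series)
        shared = fit_arrhenius_onestep(series, shared_intercept=True)
        assert shared.Ea == pytest.approx(free.Ea, rel=1e-6)

    def test_noisy_recovery_mean_within_5_percent(self, k270_model):
        """Monte-Carlo: mean one-step Ea over replications near truth."""
        Ea_true = 58.39e3
        estimates = []
        for seed in range(40):
            spec = SyntheticIndexSpec(
                index_id="K270", I0=0.15, sigma=0.005, unit="AU",
                Ea=Ea_true, k_ref=k270_model.k_ref,
            )
            series, _ = generate_series(
                SyntheticStudyConfig(indices=(spec,), seed=seed)
            )
            estimates.append(fit_arrhenius_onestep(series).Ea)
        assert abs(np.mean(estimates) - Ea_true) / Ea_true < 0.05

    def test_estimator_interface(self):
        rng = np.random.default_rng(0)
        t = np.tile(np.linspace(0, 300, 10), 2)
        T = np.repeat([25.0, 60.0], 10)
        x = 1.0 / (T + 273.15) - 1.0 / T_REF_DEFAULT
        y = 0.15 + 1e-3 * np.exp(-60e3 / R * x) * t + rng.normal(0, 1e-4, t.size)
        est = OneStepArrhenius().fit(np.column_stack([t, T]), y)
        assert est.Ea_ == pytest.approx(60e3, rel=0.05)
        pred = est.predict(np.column_stack([[0.0], [25.0]]))
        assert pred[0] == pytest.approx(est.intercepts_[25.0])
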