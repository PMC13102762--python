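"""One-compartment infusion kinetics: closed forms against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meropk import (
    IndividualParams,
    PKTarget,
    PopulationModel,
    Regimen,
    ResidualSpec,
    attains,
    conc_profile,
    ft_above,
    individual_params,
)
from ._oracles import conc_by_superposition, ft_above_grid

hyp = settings(max_examples=60, deadline=None, derandomize=True)

ip_strategy = st.builds(
    IndividualParams,
    cl=st.floats(1.0, 25.0),
    vc=st.floats(8.0, 80.0),
)
reg_strategy = st.sampled_from(
    [Regimen(d, tau, tinf) for d in (500, 1000, 2000)
     for tau in (6, 8, 12) for tinf in (0.5, 2)]
)


class TestIndividualParams:
    def test_typical_subject_matches_published_estimates(self, model):
        ip = individual_params(model, crcl=47.7)
        assert ip.cl == pytest.approx(6.472)
        assert ip.vc == pytest.approx(26.69)
        assert ip.ke == pytest.approx(6.472 / 26.69)

    def test_zero_exponent_removes_renal_dependence(self, model):
        flat = PopulationModel(theta_cov=0.0)
        assert individual_params(flat, 20.0).cl == individual_params(flat, 120.0).cl

    def test_power_law_against_log_arithmetic(self, model):
        # doubling CRCL scales CL by 2^0.3834; checked via log/exp identity
        ip = individual_params(model, crcl=2 * 47.7)
        expected = 6.472 * np.exp(0.3834 * np.log(2.0))
        assert ip.cl == pytest.approx(expected, rel=1e-12)

    def test_eta_enters_exponentially(self, model):
        ip = individual_params(model, 47.7, eta_cl=0.5, eta_vc=-0.25)
        assert ip.cl == pytest.approx(6.472 * np.exp(0.5))
        assert ip.vc == pytest.approx(26.69 * np.exp(-0.25))

    def test_nonpositive_crcl_names_subject(self, model):
        with pytest.raises(ValueError, match="subject 7"):
            individual_params(model, crcl=-3.0, subject=7)


class TestConcProfile:
    def test_zero_before_first_infusion(self, typical_ip, q8h_regimen):
        assert conc_profile(typical_ip, q8h_regimen, 0.0, n_doses=1) == 0.0

    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 8.0929), (2.0, 34.6714), (7.5, 9.1361)],
        ids=["trough", "end-of-infusion-peak", "pre-dose-sample"],
    )
    def test_steady_state_matches_superposition(self, typical_ip, q8h_regimen,
                                                t, expected):
        # frozen values from the >=60-dose superposition oracle
        c = conc_profile(typical_ip, q8h_regimen, t)
        assert c == pytest.approx(expected, abs=2e-4)
        oracle = conc_by_superposition(typical_ip, q8h_regimen, t)
        assert c == pytest.approx(float(oracle), abs=1e-6)

    def test_superposition_converges_to_steady_state(self, typical_ip, q8h_regimen):
        # 20 half-lives: t_half = ln2/ke ~ 2.86 h -> ~8 intervals; use 20
        t = np.linspace(0.0, q8h_regimen.tau_h, 200, endpoint=False)
        ss = conc_profile(typical_ip, q8h_regimen, t)
        approx = conc_by_superposition(typical_ip, q8h_regimen, t, n_doses=20)
        assert np.max(np.abs(ss - approx)) < 1e-6

    @hyp
    @given(ip=ip_strategy, reg=reg_strategy)
    def test_dose_linearity(self, ip, reg):
        t = np.linspace(0.0, reg.tau_h, 25, endpoint=False)
        double = Regimen(2 * reg.dose_mg, reg.tau_h, reg.tinf_h)
        np.testing.assert_allclose(
            conc_profile(ip, double, t), 2 * conc_profile(ip, reg, t), rtol=1e-12
        )

    def test_continuous_at_end_of_infusion(self, typical_ip, q8h_regimen):
        eps = 1e-9
        left = conc_profile(typical_ip, q8h_regimen, 2.0 - eps)
        right = conc_profile(typical_ip, q8h_regimen, 2.0 + eps)
        assert left == pytest.approx(right, rel=1e-6)

    def test_negative_time_rejected(self, typical_ip, q8h_regimen):
        with pytest.raises(ValueError):
            conc_profile(typical_ip, q8h_regimen, -1.0)


class TestFtAbove:
    def test_zero_threshold_is_full_interval(self, typical_ip, q8h_regimen):
        assert ft_above(typical_ip, q8h_regimen, 0.0) == 1.0

    def test_below_trough_threshold(self, typical_ip, q8h_regimen):
        # steady-state trough ~8.09 mg/L > 4
        assert ft_above(typical_ip, q8h_regimen, 4.0) == 1.0

    def test_mid_threshold_matches_dense_grid(self, typical_ip, q8h_regimen):
        ft = ft_above(typical_ip, q8h_regimen, 16.0)
        assert ft == pytest.approx(0.586, abs=1e-3)
        assert ft == pytest.approx(
            ft_above_grid(typical_ip, q8h_regimen, 16.0), abs=1e-3
        )

    def test_above_peak_threshold_is_zero(self, typical_ip, q8h_regimen):
        assert ft_above(typical_ip, q8h_regimen, 50.0) == 0.0

    def test_closed_form_equals_grid_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        regs = [Regimen(d, tau, tinf) for d in (500, 1000, 2000)
                for tau in (6, 8, 12) for tinf in (0.5, 2)]
        for _ in range(200):
            ip = IndividualParams(cl=rng.uniform(1, 25), vc=rng.uniform(8, 80))
            reg = regs[rng.integers(len(regs))]
            thr = rng.uniform(0.5, 60.0)
            assert ft_above(ip, reg, thr) == pytest.approx(
                ft_above_grid(ip, reg, thr, dt=0.0005), abs=1e-3
            )

    @hyp
    @given(ip=ip_strategy, reg=reg_strategy,
           thr=st.floats(0.1, 50), delta=st.floats(0.1, 20))
    def test_nonincreasing_in_threshold(self, ip, reg, thr, delta):
        assert ft_above(ip, reg, thr) >= ft_above(ip, reg, thr + delta)

    def test_negative_threshold_rejected(self, typical_ip, q8h_regimen):
        with pytest.raises(ValueError):
            ft_above(typical_ip, q8h_regimen, -1.0)


class TestAttains:
    def test_forty_percent_target_at_mic4(self, typical_ip, q8h_regimen):
        assert attains(typical_ip, q8h_regimen, 4.0, PKTarget(0.4, 1.0))

    def test_stringent_target_fails_at_mic4(self, typical_ip, q8h_regimen):
        # fT>16 ~ 0.586 < 1.0
        assert not attains(typical_ip, q8h_regimen, 4.0, PKTarget(1.0, 4.0))

    def test_full_interval_target_uses_trough_criterion(self, typical_ip,
                                                        q8h_regimen):
        # trough ~8.09: 100% fT>MIC holds at MIC 8, fails just above
        assert attains(typical_ip, q8h_regimen, 8.0, PKTarget(1.0, 1.0))
        assert not attains(typical_ip, q8h_regimen, 8.2, PKTarget(1.0, 1.0))

    def test_free_fraction_scales_threshold(self, typical_ip, q8h_regimen):
        loose = attains(typical_ip, q8h_regimen, 16.0, PKTarget(0.5, 1.0), 1.0)
        tight = attains(typical_ip, q8h_regimen, 16.0, PKTarget(0.5, 1.0), 0.5)
        assert loose != tight  # halving free fraction doubles the threshold

    @hyp
    @given(ip=ip_strategy, reg=reg_strategy, mic=st.floats(0.5, 16),
           smaller=st.floats(0.05, 0.95))
    def test_monotone_in_mic_and_stringency(self, ip, reg, mic, smaller):
        target = PKTarget(0.6, 4.0)
        if attains(ip, reg, mic, target):
            assert attains(ip, reg, smaller * mic, target)
            assert attains(ip, reg, mic, PKTarget(0.6 * smaller, 4.0))
            assert attains(ip, reg, mic, PKTarget(0.6, 1.0))


class TestValidation:
    def test_regimen_invariants(self):
        with pytest.raises(ValueError):
            Regimen(-1.0, 8.0, 2.0)
        with pytest.raises(ValueError):
            Regimen(1000.0, 8.0, 9.0)  # infusion longer than interval

    def test_residual_spec_invariants(self):
        with pytest.raises(ValueError):
            ResidualSpec(kind="weird")
        with pytest.raises(ValueError):
            ResidualSpec(kind="proportional", sigma_prop=0.0)

    def test_population_model_invariants(self):
        with pytest.raises(ValueError):
            PopulationModel(rho=1.5)
        with pytest.raises(ValueError):
            PopulationModel(theta_cl=-1.0)

    def test_omega_matrix_is_psd(self, model):
        assert np.all(np.linalg.eigvalsh(model.omega) >= 0)
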