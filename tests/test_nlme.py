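"""Mixed-effects estimation: Laplace objective against quadrature, parameter
recovery, covariate selection, bootstrap and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

from meropk import (
    CovariateEffect,
    FitSettings,
    InfusionNLME,
    PopulationModel,
    ResidualSpec,
    TDMDataset,
    bootstrap,
    covariate_screen,
    evaluate,
    fit,
    neg2ll,
    published_covariates,
    stepwise_covariates,
)
from meropk.core_pk import conc_steady_state
from meropk.nlme import StructuralSpec, _resample_dataset
from .conftest import make_dataset, toy_dataset
from ._oracles import neg2ll_quadrature

FAST = FitSettings(outer_tol=1e-6, max_iter=150)


def _simulated_toy(n_subj, n_obs, seed, omega_sd=0.2, sigma=1.0):
    """Small dataset with known generating values, for objective checks."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_subj):
        eta = omega_sd * rng.standard_normal(2)
        cl, vc = 6.5 * np.exp(eta[0]), 27.0 * np.exp(eta[1])
        times = np.sort(rng.choice([2.0, 4.0, 6.0, 7.5], n_obs, replace=False))
        dvs = [
            float(conc_steady_state(cl, vc, 1000.0, 8.0, 2.0, t))
            + sigma * rng.standard_normal()
            for t in times
        ]
        specs.append((times, dvs))
    return toy_dataset(specs)


class TestNeg2ll:
    @pytest.mark.parametrize("n_subj, n_obs", [(1, 1), (2, 2), (3, 3)])
    def test_matches_adaptive_quadrature(self, n_subj, n_obs):
        """Laplace approximation agrees with an 80-node adaptive Gauss-Hermite
        oracle on toy problems."""
        ds = _simulated_toy(n_subj, n_obs, seed=n_subj * 10 + n_obs)
        omega = np.array([[0.04, 0.01], [0.01, 0.04]])
        oracle = neg2ll_quadrature(6.5, 27.0, omega, 1.0, ds)
        flat = {"cl": 6.5, "vc": 27.0, "omega_cl": 0.2, "omega_vc": 0.2,
                "rho": 0.25, "sigma_add": 1.0}
        mine = neg2ll(flat, ds, spec=StructuralSpec(residual="additive"))
        assert mine == pytest.approx(oracle, abs=0.1)

    def test_vanishing_iiv_reduces_to_residual_likelihood(self):
        """With omega -> 0 the marginal likelihood degenerates to the
        residual-only Gaussian density at eta = 0."""
        ds = _simulated_toy(4, 3, seed=2)
        sigma = 1.3
        flat = {"cl": 6.5, "vc": 27.0, "omega_cl": 1e-5, "omega_vc": 1e-5,
                "rho": 0.0, "sigma_add": sigma}
        mine = neg2ll(flat, ds, spec=StructuralSpec(residual="additive"))
        obs = ds.observations
        f = conc_steady_state(6.5, 27.0, 1000.0, 8.0, 2.0,
                              obs.TIME.to_numpy())
        direct = float(np.sum((obs.DV - f) ** 2 / sigma**2
                              + np.log(2 * np.pi * sigma**2)))
        assert mine == pytest.approx(direct, abs=1e-2)

    def test_additive_across_subjects(self):
        """Duplicating every subject doubles the objective."""
        ds = _simulated_toy(3, 2, seed=7)
        twice = ds.df.copy()
        twice["ID"] = twice.ID + ds.df.ID.max()
        doubled = TDMDataset(pd.concat([ds.df, twice], ignore_index=True))
        flat = {"cl": 6.5, "vc": 27.0, "omega_cl": 0.2, "omega_vc": 0.2,
                "rho": 0.0, "sigma_add": 1.0}
        spec = StructuralSpec(residual="additive")
        assert neg2ll(flat, doubled, spec=spec) == pytest.approx(
            2 * neg2ll(flat, ds, spec=spec), rel=1e-9
        )


class TestFit:
    def test_noiseless_data_recovers_typical_values(self):
        """omega ~ 0 data with known sigma: thetas recovered to optimizer
        tolerance."""
        gen = PopulationModel(omega_cl=1e-8, omega_vc=1e-8, rho=0.0,
                              residual=ResidualSpec("additive", 0.05))
        ds = make_dataset(20, seed=4, model=gen, n_samples=4,
                          nominal_times=(2.0, 4.0, 6.0, 7.5))
        res = fit(ds, covariates=published_covariates(47.7), init=gen,
                  settings=FAST, compute_rse=False)
        assert res.theta["cl"] == pytest.approx(6.472, rel=0.01)
        assert res.theta["vc"] == pytest.approx(26.69, rel=0.01)
        assert res.theta["CRCL~cl"] == pytest.approx(0.3834, abs=0.02)

    def test_recovery_on_simulated_cohort(self, small_fitted):
        """Fixed effects recovered from a 100-subject simulated cohort."""
        _, res = small_fitted
        assert res.converged
        assert res.theta["cl"] == pytest.approx(6.472, rel=0.15)
        assert res.theta["vc"] == pytest.approx(26.69, rel=0.15)
        assert res.theta["CRCL~cl"] == pytest.approx(0.3834, abs=0.12)

    def test_one_compartment_preferred_on_one_compartment_data(self):
        """Structural comparison hook: AIC favors the generating structure."""
        ds = make_dataset(50, seed=3, n_samples=4,
                          nominal_times=(2.0, 4.0, 6.0, 7.5))
        covs = published_covariates(47.7)
        one = fit(ds, covariates=covs, settings=FAST, compute_rse=False)
        two = fit(ds, covariates=covs, n_compartments=2, settings=FAST,
                  compute_rse=False)
        assert one.aic <= two.aic + 1e-6

    def test_estimator_params_roundtrip(self):
        est = InfusionNLME(residual="proportional")
        assert est.get_params()["residual"] == "proportional"
        est.set_params(residual="combined", compute_rse=False)
        assert est.residual == "combined"
        with pytest.raises(ValueError):
            est.set_params(nonexistent=1)

    def test_omega_estimate_psd(self, small_fitted):
        _, res = small_fitted
        assert np.all(np.linalg.eigvalsh(res.omega) >= -1e-12)

    def test_needs_two_subjects(self):
        ds = toy_dataset([([2.0, 6.0], [30.0, 15.0])])
        with pytest.raises(ValueError, match="two subjects"):
            fit(ds)


class TestCovariateScreen:
    def test_perfectly_collinear_pair_reduced(self):
        ds = make_dataset(30, seed=8, n_samples=3)
        df = ds.df.copy()
        df["CRCL2"] = df.CRCL * 1.0001
        ds2 = TDMDataset(df)
        kept = covariate_screen(ds2, ["CRCL", "CRCL2"], settings=FAST)
        assert len(kept) == 1

    def test_independent_covariates_all_retained(self):
        ds = make_dataset(40, seed=9, n_samples=3)
        # AGE, WT, CRCL are sampled independently in the generator
        kept = covariate_screen(ds, ["AGE", "WT", "CRCL"], settings=FAST)
        assert set(kept) == {"AGE", "WT", "CRCL"}

    def test_empty_candidates(self):
        ds = make_dataset(10, seed=10, n_samples=3)
        assert covariate_screen(ds, [], settings=FAST) == []

    def test_constant_covariate_excluded_with_warning(self):
        ds = make_dataset(10, seed=11, n_samples=3)
        df = ds.df.copy()
        df["CONST"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            kept = covariate_screen(TDMDataset(df), ["CONST", "CRCL"],
                                    settings=FAST)
        assert kept == ["CRCL"]


def _with_decoys(ds, seed, n_decoys=2):
    rng = np.random.default_rng(seed)
    df = ds.df.copy()
    ids = sorted(df.ID.unique())
    for j in range(1, n_decoys + 1):
        vals = dict(zip(ids, rng.lognormal(0.0, 0.4, len(ids))))
        df[f"X{j}"] = df.ID.map(vals)
    return TDMDataset(df)


class TestStepwise:
    def test_planted_crcl_effect_selected_decoys_rejected(self):
        ds = _with_decoys(
            make_dataset(120, seed=0, n_samples=4,
                         nominal_times=(2.0, 4.0, 6.0, 7.5)),
            seed=1000,
        )
        final, trace = stepwise_covariates(
            ds, ["CRCL", "X1", "X2"], settings=FAST, params=("cl",),
            init=PopulationModel(), compute_rse=False,
        )
        assert [c.key for c in final.spec.covariates] == ["CRCL~cl"]
        # threshold logic: every accepted forward step cleared 3.84
        accepted = [t for t in trace if t.get("accepted")]
        assert accepted and all(t["dofv"] > 3.84 for t in accepted)
        # every covariate surviving backward cleared 10.83
        kept = [t for t in trace if t["step"] == "backward" and not t["removed"]]
        assert all(t["dofv"] > 10.83 for t in kept)

    def test_null_data_selects_nothing(self):
        """With no covariate effects in truth, the forward/backward thresholds
        leave the selection empty in nearly all seeds."""
        gen = PopulationModel(theta_cov=0.0)
        empty = 0
        seeds = range(5)
        for seed in seeds:
            ds = _with_decoys(
                make_dataset(60, seed=seed, model=gen, n_samples=4,
                             nominal_times=(2.0, 4.0, 6.0, 7.5)),
                seed=2000 + seed,
            )
            final, _ = stepwise_covariates(
                ds, ["CRCL", "X1", "X2"], settings=FAST, params=("cl",),
                init=gen, compute_rse=False,
            )
            empty += not final.spec.covariates
        assert empty >= len(seeds) - 1

    def test_forward_steps_never_increase_ofv(self):
        ds = _with_decoys(
            make_dataset(80, seed=5, n_samples=4,
                         nominal_times=(2.0, 4.0, 6.0, 7.5)),
            seed=3000,
        )
        final, trace = stepwise_covariates(
            ds, ["CRCL", "X1"], settings=FAST, params=("cl",),
            init=PopulationModel(), compute_rse=False,
        )
        assert all(t["dofv"] > 0 for t in trace if t.get("accepted"))


@pytest.fixture(scope="module")
def boot_inputs():
    ds = make_dataset(30, seed=14, n_samples=4,
                      nominal_times=(2.0, 4.0, 6.0, 7.5))
    res = fit(ds, covariates=published_covariates(47.7),
              init=PopulationModel(), settings=FAST, compute_rse=False)
    return ds, res


class TestBootstrap:
    def test_seeded_resampling_deterministic(self, boot_inputs):
        ds, res = boot_inputs
        a = bootstrap(ds, res, n_replicates=2, seed=5, settings=FAST)
        b = bootstrap(ds, res, n_replicates=2, seed=5, settings=FAST)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_resampled_subjects_reidentified_uniquely(self, boot_inputs):
        ds, _ = boot_inputs
        rng = np.random.default_rng(0)
        rep = _resample_dataset(ds, rng)
        assert rep.n_subjects == ds.n_subjects
        assert sorted(rep.df.ID.unique()) == list(range(1, ds.n_subjects + 1))
        rep.validate()

    def test_interval_widens_as_cohort_shrinks(self, boot_inputs):
        """Percentile intervals from a 12-subject subset are wider on average
        than those from the full 30-subject dataset."""
        ds, res = boot_inputs
        small_df = ds.df[ds.df.ID <= 12].reset_index(drop=True)
        small = TDMDataset(small_df, lloq=ds.lloq, uloq=ds.uloq)
        small_res = fit(small, covariates=published_covariates(47.7),
                        init=res, settings=FAST, compute_rse=False)

        def mean_width(dataset, fitted):
            out = bootstrap(dataset, fitted, n_replicates=15, seed=7,
                            settings=FAST)
            tbl = out.table.set_index("parameter")
            return np.mean(
                [tbl.loc[p, "p97.5"] - tbl.loc[p, "p2.5"] for p in ("cl", "vc")]
            )

        assert mean_width(small, small_res) > mean_width(ds, res)

    def test_percentile_interval_covers_original_estimates(self, boot_inputs):
        ds, res = boot_inputs
        out = bootstrap(ds, res, n_replicates=20, seed=6, settings=FAST)
        assert out.n_converged >= 16
        tbl = out.table.set_index("parameter")
        for name in ("cl", "vc"):
            assert tbl.loc[name, "p2.5"] <= res.theta[name] <= tbl.loc[name, "p97.5"]


class TestCwres:
    def test_degenerate_iiv_gives_standardized_residuals(self):
        """omega = 0, additive error: CWRES equals (DV - PRED) / sigma."""
        ds = _simulated_toy(5, 3, seed=21, omega_sd=0.0, sigma=1.0)
        flat = {"cl": 6.5, "vc": 27.0, "omega_cl": 1e-5, "omega_vc": 1e-5,
                "rho": 0.0, "sigma_add": 2.0}
        res = evaluate(ds, flat, spec=StructuralSpec(residual="additive"))
        pred = res.predictions.PRED.to_numpy()
        dv = res.predictions.DV.to_numpy()
        np.testing.assert_allclose(
            res.predictions.CWRES, (dv - pred) / 2.0, atol=1e-3
        )

    def test_calibrated_under_generating_model(self, model):
        """Correct model: CWRES approximately standard normal."""
        ds = make_dataset(300, seed=22, model=model, n_samples=3)
        res = evaluate(ds, model)
        cw = res.predictions.CWRES
        assert abs(cw.mean()) < 0.1
        assert 0.85 < cw.std() < 1.15

    def test_sensitive_to_misspecified_clearance(self, model):
        ds = make_dataset(150, seed=23, model=model, n_samples=3)
        wrong = PopulationModel(theta_cl=model.theta_cl / 2)
        res = evaluate(ds, wrong)
        assert abs(res.predictions.CWRES.mean()) > 0.5

    def test_finite_for_all_observations(self, small_fitted):
        _, res = small_fitted
        assert np.all(np.isfinite(res.predictions.CWRES))


class TestFitResultIO:
    def test_json_roundtrip(self, small_fitted, tmp_path):
        _, res = small_fitted
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = type(res).from_json(path)
        assert back.theta == pytest.approx(res.theta)
        assert back.ofv == res.ofv
        assert back.spec == res.spec
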