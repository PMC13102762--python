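"""Nonlinear mixed-effects estimation for infusion pharmacokinetics.

The estimator maximizes an approximate marginal likelihood of the Laplace/FOCE
family: for each subject the joint density of observations and random effects
(etaCL, etaVc) is maximized over eta (an inner, damped Newton iteration run
vectorized across subjects), and the marginal likelihood is approximated with
the log-determinant of the negative Hessian at the conditional mode.  On top of
that sit stepwise covariate modeling with the study's forward/backward
likelihood-ratio thresholds, a nonparametric subject bootstrap, and
FOCE-linearized conditional weighted residuals (CWRES).

The public surface is a scikit-learn style estimator, :class:`InfusionNLME`
(``fit`` + trailing-underscore attributes + ``get_params``/``set_params``),
with thin module-level functions (:func:`fit`, :func:`neg2ll`,
:func:`stepwise_covariates`, :func:`bootstrap`, :func:`cwres`) wrapping it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import TDMDataset
from .core_pk import PopulationModel, ResidualSpec, conc_steady_state

__all__ = [
    "CovariateEffect",
    "StructuralSpec",
    "FitSettings",
    "FitResult",
    "InfusionNLME",
    "published_covariates",
    "neg2ll",
    "fit",
    "evaluate",
    "covariate_screen",
    "stepwise_covariates",
    "bootstrap",
    "cwres",
    "simulate_from_fit",
    "population_model_from_fit",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_BIG = 1e10  # objective value signalling an infeasible parameter vector


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    ``form="power"``: multiplier (x / ref)^theta, for continuous covariates
    normalized to a reference (typically the dataset median).
    ``form="linear"``: multiplier (1 + theta * x), for binary covariates.
    """

    param: str  # "cl" or "vc"
    column: str
    form: str = "power"
    ref: float = 1.0

    def __post_init__(self) -> None:
        if self.param not in ("cl", "vc"):
            raise ValueError("covariates may act on 'cl' or 'vc'")
        if self.form not in ("power", "linear"):
            raise ValueError("covariate form must be 'power' or 'linear'")
        if self.form == "power" and self.ref <= 0:
            raise ValueError("power-covariate reference must be positive")

    @property
    def key(self) -> str:
        return f"{self.column}~{self.param}"


def published_covariates(ref: float = 47.7) -> tuple[CovariateEffect, ...]:
    """The final model's covariate structure: CRCL power effect on CL."""
    return (CovariateEffect("cl", "CRCL", "power", ref),)


@dataclass(frozen=True)
class StructuralSpec:
    """Structural model: compartments, residual-error kind, covariate effects."""

    n_compartments: int = 1
    residual: str = "additive"
    covariates: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("only 1- and 2-compartment structures supported")
        if self.residual not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual kind {self.residual!r}")

    @property
    def theta_names(self) -> tuple[str, ...]:
        names = ["cl", "vc"]
        if self.n_compartments == 2:
            names += ["q", "vp"]
        names += [c.key for c in self.covariates]
        return tuple(names)

    @property
    def sigma_names(self) -> tuple[str, ...]:
        if self.residual == "additive":
            return ("add",)
        if self.residual == "proportional":
            return ("prop",)
        return ("add", "prop")


@dataclass(frozen=True)
class FitSettings:
    """Estimation and covariate-search settings.

    The forward/backward thresholds are the study's likelihood-ratio cutoffs:
    OFV decrease > 3.84 (alpha=0.05, 1 df) to enter, OFV increase > 10.83
    (alpha=0.001) to stay through backward elimination.
    """

    forward_dofv: float = 3.84
    backward_dofv: float = 10.83
    collinearity_r: float = 0.6
    inner_tol: float = 1e-7
    outer_tol: float = 1e-9
    max_iter: int = 400
    max_inner: int = 40
    fd_step: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.forward_dofv, self.backward_dofv, self.collinearity_r) <= 0:
            raise ValueError("selection thresholds must be positive")


# --------------------------------------------------------------------------
# concentration models
# --------------------------------------------------------------------------


def _conc_ss_2cmt(cl, vc, q, vp, dose, tau, tinf, t):
    """Steady-state central concentration of a two-compartment infusion model.

    Biexponential disposition with macro rates lambda1/lambda2; each
    exponential accumulates geometrically over dosing intervals exactly as in
    the one-compartment case.
    """
    cl, vc, q, vp, dose, tau, tinf, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (cl, vc, q, vp, dose, tau, tinf, t))
    )
    t = np.mod(t, tau)
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 1e-300))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    r0_vc = dose / tinf / vc
    out = np.zeros_like(t)
    for lam, other in ((lam1, lam2), (lam2, lam1)):
        coef = (k21 - lam) / (other - lam)
        acc = -np.expm1(-lam * tau)
        rise = -np.expm1(-lam * np.minimum(t, tinf))
        tail = (
            -np.expm1(-lam * tinf)
            * np.exp(-lam * (np.minimum(t, tinf) + tau - tinf))
            / acc
        )
        during = rise + tail
        after = -np.expm1(-lam * tinf) * np.exp(-lam * (t - tinf)) / acc
        out = out + coef / lam * np.where(t <= tinf, during, after)
    return r0_vc * out


# --------------------------------------------------------------------------
# internal objective: vectorized Laplace marginal likelihood
# --------------------------------------------------------------------------


class _Objective:
    """Per-dataset machinery: flat observation arrays, covariate design,
    transformed-parameter packing, inner Newton solver, Laplace assembly."""

    def __init__(self, dataset: TDMDataset, spec: StructuralSpec,
                 settings: FitSettings):
        self.spec = spec
        self.settings = settings
        obs = dataset.observations
        used = obs[obs.MDV == 0]  # BQL rows excluded from the likelihood (M1)
        used = used.sort_values(["ID", "TIME"], kind="stable")  # canonical order
        if used.empty:
            raise ValueError("dataset has no quantifiable observations")
        doses = dataset.doses.drop_duplicates("ID").set_index("ID")
        self.subject_ids = np.asarray(sorted(dataset.df.ID.unique()))
        id_to_idx = {sid: i for i, sid in enumerate(self.subject_ids)}
        if not set(used.ID).issubset(id_to_idx):
            raise ValueError("observation rows reference unknown subject IDs")
        missing_dose = set(self.subject_ids) - set(doses.index)
        if missing_dose:
            raise ValueError(f"subjects without dose events: {sorted(missing_dose)}")
        self.n_subjects = len(self.subject_ids)
        self.y = used.DV.to_numpy(dtype=float)
        self.t = used.TIME.to_numpy(dtype=float)
        self.subj_idx = used.ID.map(id_to_idx).to_numpy(dtype=int)
        self.obs_index = used.index.to_numpy()
        amt = doses.AMT.reindex(self.subject_ids).to_numpy(dtype=float)
        rate = doses.RATE.reindex(self.subject_ids).to_numpy(dtype=float)
        tau = doses.II.reindex(self.subject_ids).to_numpy(dtype=float)
        if np.any(~np.isfinite(tau)) or np.any(tau <= 0):
            raise ValueError("dose rows must carry a positive II (interval)")
        self.dose = amt[self.subj_idx]
        self.tau = tau[self.subj_idx]
        self.tinf = (amt / rate)[self.subj_idx]
        # per-subject covariate values (first row of each subject)
        first = dataset.df.drop_duplicates("ID").set_index("ID")
        self.cov_values = {
            c.column: first[c.column].reindex(self.subject_ids).to_numpy(dtype=float)
            for c in spec.covariates
        }
        self._warm_eta = np.zeros((self.n_subjects, 2))
        self.flagged_subjects: list = []

    # ---- parameter packing -------------------------------------------------

    def n_params(self) -> int:
        return len(self.spec.theta_names) + 3 + len(self.spec.sigma_names)

    def pack(self, theta: dict, omega: np.ndarray, sigma: dict) -> np.ndarray:
        x = []
        for name in self.spec.theta_names:
            val = theta[name]
            x.append(np.log(val) if "~" not in name else val)
        chol = np.linalg.cholesky(np.asarray(omega) + 1e-12 * np.eye(2))
        x += [np.log(chol[0, 0]), chol[1, 0], np.log(chol[1, 1])]
        for name in self.spec.sigma_names:
            x.append(np.log(sigma[name]))
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray):
        names = self.spec.theta_names
        theta = {}
        for i, name in enumerate(names):
            theta[name] = float(np.exp(x[i])) if "~" not in name else float(x[i])
        j = len(names)
        l11, l21, l22 = np.exp(x[j]), x[j + 1], np.exp(x[j + 2])
        chol = np.array([[l11, 0.0], [l21, l22]])
        omega = chol @ chol.T
        sigma = {}
        for k, name in enumerate(self.spec.sigma_names):
            sigma[name] = float(np.exp(x[j + 3 + k]))
        return theta, omega, sigma

    # ---- model evaluation --------------------------------------------------

    def typical_params(self, theta: dict):
        """Per-subject typical CL and Vc including covariate multipliers.

        Returns (tvcl, tvvc) arrays or None if a linear covariate multiplier
        is nonpositive (infeasible parameter vector).
        """
        tvcl = np.full(self.n_subjects, theta["cl"])
        tvvc = np.full(self.n_subjects, theta["vc"])
        for eff in self.spec.covariates:
            xv = self.cov_values[eff.column]
            if eff.form == "power":
                mult = (xv / eff.ref) ** theta[eff.key]
            else:
                mult = 1.0 + theta[eff.key] * xv
                if np.any(mult <= 0):
                    return None
            if eff.param == "cl":
                tvcl = tvcl * mult
            else:
                tvvc = tvvc * mult
        return tvcl, tvvc

    def predict(self, theta: dict, eta: np.ndarray) -> np.ndarray:
        """Predicted concentration per used observation, given eta (n, 2)."""
        tv = self.typical_params(theta)
        if tv is None:
            raise FloatingPointError("infeasible covariate multiplier")
        tvcl, tvvc = tv
        cl = tvcl * np.exp(np.clip(eta[:, 0], -30, 30))
        vc = tvvc * np.exp(np.clip(eta[:, 1], -30, 30))
        cl_o, vc_o = cl[self.subj_idx], vc[self.subj_idx]
        if self.spec.n_compartments == 1:
            return conc_steady_state(cl_o, vc_o, self.dose, self.tau, self.tinf, self.t)
        q, vp = theta["q"], theta["vp"]
        return _conc_ss_2cmt(cl_o, vc_o, q, vp, self.dose, self.tau, self.tinf, self.t)

    def _residual_var(self, f: np.ndarray, sigma: dict) -> np.ndarray:
        kind = self.spec.residual
        if kind == "additive":
            return np.full_like(f, sigma["add"] ** 2)
        if kind == "proportional":
            return np.maximum((sigma["prop"] * f) ** 2, 1e-12)
        return sigma["add"] ** 2 + (sigma["prop"] * f) ** 2

    def h_all(self, theta, omega_inv, log_det_omega, sigma, eta):
        """Negative log joint density per subject, vectorized; shape (n,)."""
        f = self.predict(theta, eta)
        v = self._residual_var(f, sigma)
        ll = 0.5 * ((self.y - f) ** 2 / v + np.log(v) + _LOG_2PI)
        per_subj = np.bincount(self.subj_idx, weights=ll, minlength=self.n_subjects)
        quad = np.einsum("ni,ij,nj->n", eta, omega_inv, eta)
        prior = 0.5 * quad + 0.5 * (log_det_omega + 2.0 * _LOG_2PI)
        return per_subj + prior

    # ---- inner optimization ------------------------------------------------

    def _inner_newton(self, theta, omega, sigma, eta0):
        """Vectorized damped Newton over per-subject eta; returns
        (eta_hat, h_hat, hessians) with hessians shape (n, 2, 2)."""
        omega_inv = np.linalg.inv(omega + 1e-12 * np.eye(2))
        sign, log_det = np.linalg.slogdet(omega + 1e-12 * np.eye(2))
        d = self.settings.fd_step
        eta = eta0.copy()

        def h(e):
            return self.h_all(theta, omega_inv, log_det, sigma, e)

        h0 = h(eta)
        bad = ~np.isfinite(h0)
        if np.any(bad):
            eta[bad] = 0.0
            h0 = h(eta)
        e1 = np.array([d, 0.0])
        e2 = np.array([0.0, d])
        g = np.zeros((self.n_subjects, 2))
        hess = np.tile(np.eye(2), (self.n_subjects, 1, 1))
        for _ in range(self.settings.max_inner):
            hp1, hm1 = h(eta + e1), h(eta - e1)
            hp2, hm2 = h(eta + e2), h(eta - e2)
            hpp, hmm = h(eta + e1 + e2), h(eta - e1 - e2)
            hpm, hmp = h(eta + e1 - e2), h(eta - e1 + e2)
            g[:, 0] = (hp1 - hm1) / (2 * d)
            g[:, 1] = (hp2 - hm2) / (2 * d)
            h11 = (hp1 - 2 * h0 + hm1) / d**2
            h22 = (hp2 - 2 * h0 + hm2) / d**2
            h12 = (hpp - hpm - hmp + hmm) / (4 * d**2)
            hess[:, 0, 0], hess[:, 1, 1] = h11, h22
            hess[:, 0, 1] = hess[:, 1, 0] = h12
            if np.max(np.abs(g)) < self.settings.inner_tol:
                break
            # project to positive definite: eigenvalue floor for 2x2
            tr = h11 + h22
            det = h11 * h22 - h12**2
            disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
            lam_min = tr / 2 - disc
            ridge = np.maximum(1e-6 - lam_min, 0.0)
            a = h11 + ridge
            c = h22 + ridge
            det_pd = a * c - h12**2
            step = np.empty_like(g)
            step[:, 0] = -(c * g[:, 0] - h12 * g[:, 1]) / det_pd
            step[:, 1] = -(a * g[:, 1] - h12 * g[:, 0]) / det_pd
            norm = np.sqrt(np.sum(step**2, axis=1))
            too_big = norm > 2.0
            step[too_big] *= (2.0 / norm[too_big])[:, None]
            # vectorized backtracking line search
            scale = np.ones(self.n_subjects)
            new_eta = eta + step
            new_h = h(new_eta)
            for _ls in range(8):
                worse = ~np.isfinite(new_h) | (new_h > h0 + 1e-12)
                if not np.any(worse):
                    break
                scale[worse] *= 0.5
                new_eta[worse] = eta[worse] + scale[worse, None] * step[worse]
                new_h[worse] = h(new_eta)[worse]
            improved = np.isfinite(new_h) & (new_h <= h0)
            eta[improved] = new_eta[improved]
            h0 = np.where(improved, new_h, h0)
        return eta, h0, hess

    def neg2ll(self, x: np.ndarray, warm: bool = True) -> float:
        """Laplace -2 log marginal likelihood at transformed parameters x."""
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 50:
            return _BIG
        theta, omega, sigma = self.unpack(x)
        if self.typical_params(theta) is None:
            return _BIG
        eta0 = self._warm_eta if warm else np.zeros((self.n_subjects, 2))
        try:
            eta, h0, hess = self._inner_newton(theta, omega, sigma, eta0)
        except FloatingPointError:
            return _BIG
        if warm:
            self._warm_eta = eta
        det = hess[:, 0, 0] * hess[:, 1, 1] - hess[:, 0, 1] ** 2
        bad = ~np.isfinite(h0) | (det <= 0) | ~np.isfinite(det)
        if np.any(bad):
            flagged = self.subject_ids[bad].tolist()
            if set(flagged) - set(self.flagged_subjects):
                self.flagged_subjects = sorted(set(self.flagged_subjects) | set(flagged))
                warnings.warn(
                    f"inner optimization failed for subjects {flagged}; "
                    "their contribution is penalized",
                    stacklevel=2,
                )
            det = np.where(bad, 1.0, det)
            h0 = np.where(bad, _BIG / self.n_subjects / 2.0, h0)
        value = float(np.sum(2.0 * h0 + np.log(det) - 2.0 * _LOG_2PI))
        return value if np.isfinite(value) else _BIG

    def ebes(self, x: np.ndarray) -> np.ndarray:
        """Converged conditional modes (EBEs) at parameters x."""
        theta, omega, sigma = self.unpack(x)
        eta, _, _ = self._inner_newton(theta, omega, sigma,
                                       np.zeros((self.n_subjects, 2)))
        return eta

    def deta_jacobian(self, theta, eta):
        """d f / d eta per observation (FD), shape (n_obs, 2)."""
        d = self.settings.fd_step
        out = np.empty((self.y.size, 2))
        for j, e in enumerate((np.array([d, 0.0]), np.array([0.0, d]))):
            fp = self.predict(theta, eta + e)
            fm = self.predict(theta, eta - e)
            out[:, j] = (fp - fm) / (2 * d)
        return out


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and diagnostics from one mixed-effects fit."""

    theta: dict
    omega: np.ndarray
    sigma: dict
    ofv: float
    aic: float
    n_params: int
    converged: bool
    spec: StructuralSpec
    rse: dict | None = None
    ebes: pd.DataFrame | None = None
    predictions: pd.DataFrame | None = None
    trace: list | None = None

    @property
    def omega_sd(self) -> tuple[float, float]:
        """(omegaCL, omegaVc) as SDs on the log scale."""
        return (float(np.sqrt(self.omega[0, 0])), float(np.sqrt(self.omega[1, 1])))

    @property
    def rho(self) -> float:
        s1, s2 = self.omega_sd
        if s1 == 0 or s2 == 0:
            return 0.0
        return float(self.omega[0, 1] / (s1 * s2))

    def flat_params(self) -> dict:
        out = dict(self.theta)
        out["omega_cl"], out["omega_vc"] = self.omega_sd
        out["rho"] = self.rho
        for name, val in self.sigma.items():
            out[f"sigma_{name}"] = val
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta": self.theta,
            "omega": np.asarray(self.omega).tolist(),
            "sigma": self.sigma,
            "ofv": self.ofv,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "rse": self.rse,
            "spec": {
                "n_compartments": self.spec.n_compartments,
                "residual": self.spec.residual,
                "covariates": [asdict(c) for c in self.spec.covariates],
            },
            "trace": self.trace,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        data = json.loads(Path(path).read_text())
        spec = StructuralSpec(
            n_compartments=data["spec"]["n_compartments"],
            residual=data["spec"]["residual"],
            covariates=tuple(
                CovariateEffect(**c) for c in data["spec"]["covariates"]
            ),
        )
        return cls(
            theta=data["theta"],
            omega=np.asarray(data["omega"]),
            sigma=data["sigma"],
            ofv=data["ofv"],
            aic=data["aic"],
            n_params=data["n_params"],
            converged=data["converged"],
            spec=spec,
            rse=data.get("rse"),
            trace=data.get("trace"),
        )


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

_DEFAULT_INIT = {
    "cl": 8.0,
    "vc": 30.0,
    "q": 5.0,
    "vp": 20.0,
    "cov_theta": 0.1,
    "omega_cl": 0.4,
    "omega_vc": 0.4,
    "rho": 0.0,
    "add": 3.0,
    "prop": 0.25,
}


class InfusionNLME:
    """Population PK estimator for repeated intravenous infusions.

    Laplace-approximate marginal likelihood with log-normal interindividual
    variability on CL and Vc (full 2x2 covariance, Cholesky-parameterized) and
    additive / proportional / combined residual error.

    Parameters
    ----------
    residual : residual-error kind.
    covariates : tuple of :class:`CovariateEffect`.
    n_compartments : 1 (default) or 2 (structural-comparison hook).
    settings : :class:`FitSettings`.
    init : None (defaults), dict of natural-scale starting values, or a
        :class:`FitResult` / :class:`PopulationModel` to start from.
    compute_rse : whether to differentiate the objective for relative
        standard errors after convergence (adds ~p^2 objective evaluations).

    Attributes (after ``fit``)
    --------------------------
    theta_ : dict of fixed effects; omega_ : 2x2 IIV covariance;
    sigma_ : residual SDs; ofv_ : -2 log-likelihood; aic_; rse_;
    ebes_ : per-subject conditional modes; predictions_ : PRED/IPRED/CWRES
    table; converged_ : bool.
    """

    def __init__(
        self,
        residual: str = "additive",
        covariates: Sequence[CovariateEffect] = (),
        n_compartments: int = 1,
        settings: FitSettings | None = None,
        init=None,
        compute_rse: bool = True,
    ):
        self.residual = residual
        self.covariates = tuple(covariates)
        self.n_compartments = n_compartments
        self.settings = settings
        self.init = init
        self.compute_rse = compute_rse

    # -- sklearn-style plumbing -------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            "residual": self.residual,
            "covariates": self.covariates,
            "n_compartments": self.n_compartments,
            "settings": self.settings,
            "init": self.init,
            "compute_rse": self.compute_rse,
        }

    def set_params(self, **params) -> "InfusionNLME":
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    # -- internals ----------------------------------------------------------

    def _spec(self) -> StructuralSpec:
        return StructuralSpec(
            n_compartments=self.n_compartments,
            residual=self.residual,
            covariates=self.covariates,
        )

    def _init_values(self, spec: StructuralSpec):
        base = dict(_DEFAULT_INIT)
        user = self.init
        if isinstance(user, FitResult):
            user = user.flat_params()
        elif isinstance(user, PopulationModel):
            pm = user
            user = {
                "cl": pm.theta_cl,
                "vc": pm.theta_vc,
                "omega_cl": pm.omega_cl,
                "omega_vc": pm.omega_vc,
                "rho": pm.rho,
                "add": pm.residual.sigma_add,
                "prop": pm.residual.sigma_prop,
            }
            for eff in spec.covariates:
                if eff.column == "CRCL" and eff.param == "cl":
                    user[eff.key] = pm.theta_cov
        elif user is None:
            user = {}
        merged = {**base, **{k: v for k, v in user.items() if v is not None}}
        theta = {"cl": merged["cl"], "vc": merged["vc"]}
        if spec.n_compartments == 2:
            theta["q"], theta["vp"] = merged["q"], merged["vp"]
        for eff in spec.covariates:
            theta[eff.key] = merged.get(eff.key, merged["cov_theta"])
        s1, s2, rho = merged["omega_cl"], merged["omega_vc"], merged["rho"]
        s1, s2 = max(s1, 1e-6), max(s2, 1e-6)
        rho = float(np.clip(rho, -0.98, 0.98))
        omega = np.array(
            [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
        )
        sigma = {}
        for name in spec.sigma_names:
            val = merged.get(f"sigma_{name}", merged.get(name, 0.0)) or 0.0
            sigma[name] = max(val, _DEFAULT_INIT[name] if val <= 0 else val, 1e-3)
        return theta, omega, sigma

    # -- fitting ------------------------------------------------------------

    def fit(self, dataset: TDMDataset) -> "InfusionNLME":
        spec = self._spec()
        settings = self.settings or FitSettings()
        if dataset.n_subjects < 2:
            raise ValueError("need at least two subjects to estimate IIV")
        obj = _Objective(dataset, spec, settings)
        theta0, omega0, sigma0 = self._init_values(spec)
        x0 = obj.pack(theta0, omega0, sigma0)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            res = optimize.minimize(
                obj.neg2ll,
                x0,
                method="L-BFGS-B",
                options={
                    "maxiter": settings.max_iter,
                    "ftol": settings.outer_tol,
                    "gtol": 1e-6,
                    "eps": 1e-5,
                },
            )
        x_hat = res.x
        ofv = obj.neg2ll(x_hat, warm=False)
        if ofv > res.fun + 1e-6:  # keep the better point if warm-start drifted
            ofv = float(res.fun)
        self._finalize(obj, dataset, x_hat, ofv, bool(res.success), settings)
        return self

    def _finalize(self, obj, dataset, x_hat, ofv, success, settings):
        spec = obj.spec
        theta, omega, sigma = obj.unpack(x_hat)
        self.theta_ = theta
        self.omega_ = omega
        self.sigma_ = sigma
        self.ofv_ = float(ofv)
        self.n_params_ = obj.n_params()
        self.aic_ = self.ofv_ + 2.0 * self.n_params_
        self.converged_ = bool(success) and np.isfinite(self.ofv_) and self.ofv_ < _BIG
        self._objective = obj
        self._x_hat = x_hat
        eta = obj.ebes(x_hat)
        self.ebes_ = pd.DataFrame(
            {"ID": obj.subject_ids, "ETA_CL": eta[:, 0], "ETA_VC": eta[:, 1]}
        )
        pred = obj.predict(theta, np.zeros_like(eta))
        ipred = obj.predict(theta, eta)
        cw = _cwres_values(obj, theta, omega, sigma, eta, ipred)
        self.predictions_ = pd.DataFrame(
            {
                "ID": obj.subject_ids[obj.subj_idx],
                "TIME": obj.t,
                "DV": obj.y,
                "PRED": pred,
                "IPRED": ipred,
                "CWRES": cw,
            }
        )
        self.rse_ = self._compute_rse(obj, x_hat) if self.compute_rse else None

    def _compute_rse(self, obj, x_hat) -> dict | None:
        """RSE%% per reported parameter via a finite-difference covariance step
        and the delta method from the transformed to the natural scale."""
        names = list(obj.spec.theta_names) + ["omega_cl", "omega_vc", "rho"] + [
            f"sigma_{s}" for s in obj.spec.sigma_names
        ]

        def nat(x):
            theta, omega, sigma = obj.unpack(x)
            vals = [theta[n] for n in obj.spec.theta_names]
            s1, s2 = np.sqrt(omega[0, 0]), np.sqrt(omega[1, 1])
            rho = omega[0, 1] / (s1 * s2) if s1 * s2 > 0 else 0.0
            vals += [s1, s2, rho]
            vals += [sigma[s] for s in obj.spec.sigma_names]
            return np.asarray(vals)

        p = x_hat.size
        step = 1e-3
        try:
            hess = np.zeros((p, p))
            f0 = obj.neg2ll(x_hat, warm=False)
            fp = np.zeros(p)
            fm = np.zeros(p)
            for i in range(p):
                ei = np.zeros(p)
                ei[i] = step
                fp[i] = obj.neg2ll(x_hat + ei, warm=False)
                fm[i] = obj.neg2ll(x_hat - ei, warm=False)
                hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
            for i in range(p):
                for j in range(i + 1, p):
                    ei = np.zeros(p)
                    ej = np.zeros(p)
                    ei[i] = step
                    ej[j] = step
                    fpp = obj.neg2ll(x_hat + ei + ej, warm=False)
                    hess[i, j] = hess[j, i] = (
                        fpp - fp[i] - fp[j] + f0
                    ) / step**2
            cov_x = 2.0 * np.linalg.pinv(hess)
            jac = np.zeros((len(names), p))
            for i in range(p):
                ei = np.zeros(p)
                ei[i] = step
                jac[:, i] = (nat(x_hat + ei) - nat(x_hat - ei)) / (2 * step)
            cov_nat = jac @ cov_x @ jac.T
            se = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))
            vals = nat(x_hat)
            with np.errstate(divide="ignore", invalid="ignore"):
                rse = 100.0 * se / np.abs(vals)
            return {n: float(r) for n, r in zip(names, rse)}
        except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
            warnings.warn("covariance step failed; RSEs unavailable", stacklevel=2)
            return None

    # -- post-fit accessors --------------------------------------------------

    def result(self, trace: list | None = None) -> FitResult:
        return FitResult(
            theta=self.theta_,
            omega=self.omega_,
            sigma=self.sigma_,
            ofv=self.ofv_,
            aic=self.aic_,
            n_params=self.n_params_,
            converged=self.converged_,
            spec=self._spec(),
            rse=self.rse_,
            ebes=self.ebes_,
            predictions=self.predictions_,
            trace=trace,
        )


def _cwres_values(obj, theta, omega, sigma, eta, ipred) -> np.ndarray:
    """FOCE-linearized conditional weighted residuals, per used observation."""
    g_mat = obj.deta_jacobian(theta, eta)
    v_res = obj._residual_var(ipred, sigma)
    out = np.empty_like(obj.y)
    for i in range(obj.n_subjects):
        mask = obj.subj_idx == i
        if not np.any(mask):
            continue
        g_i = g_mat[mask]
        v_i = g_i @ omega @ g_i.T + np.diag(v_res[mask])
        resid = obj.y[mask] - (ipred[mask] - g_i @ eta[i])
        try:
            chol = np.linalg.cholesky(v_i)
            out[mask] = np.linalg.solve(chol, resid)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular covariance for subject {obj.subject_ids[i]}; "
                "falling back to weighted residuals",
                stacklevel=2,
            )
            out[mask] = resid / np.sqrt(np.maximum(np.diag(v_i), 1e-12))
    return out


# --------------------------------------------------------------------------
# module-level functional surface
# --------------------------------------------------------------------------


def neg2ll(
    params: PopulationModel | dict,
    dataset: TDMDataset,
    spec: StructuralSpec | None = None,
    settings: FitSettings | None = None,
) -> float:
    """Laplace -2 log marginal likelihood at fixed parameters.

    ``params`` may be a :class:`PopulationModel` (evaluated with its published
    CRCL covariate structure) or a flat dict with keys matching the spec's
    theta names plus omega_cl/omega_vc/rho and sigma entries.
    """
    settings = settings or FitSettings()
    if isinstance(params, PopulationModel):
        spec = spec or StructuralSpec(
            residual=params.residual.kind,
            covariates=published_covariates(params.crcl_ref),
        )
        est = InfusionNLME(
            residual=spec.residual,
            covariates=spec.covariates,
            n_compartments=spec.n_compartments,
            settings=settings,
            init=params,
        )
    else:
        if spec is None:
            raise ValueError("spec is required when params is a dict")
        est = InfusionNLME(
            residual=spec.residual,
            covariates=spec.covariates,
            n_compartments=spec.n_compartments,
            settings=settings,
            init=params,
        )
    obj = _Objective(dataset, est._spec(), settings)
    theta, omega, sigma = est._init_values(est._spec())
    return obj.neg2ll(obj.pack(theta, omega, sigma), warm=False)


def fit(
    dataset: TDMDataset,
    residual: str = "additive",
    covariates: Sequence[CovariateEffect] = (),
    n_compartments: int = 1,
    init=None,
    settings: FitSettings | None = None,
    compute_rse: bool = True,
) -> FitResult:
    """Fit the mixed-effects model; thin wrapper over :class:`InfusionNLME`."""
    est = InfusionNLME(
        residual=residual,
        covariates=covariates,
        n_compartments=n_compartments,
        settings=settings,
        init=init,
        compute_rse=compute_rse,
    )
    est.fit(dataset)
    return est.result()


def evaluate(
    dataset: TDMDataset,
    params: PopulationModel | dict,
    spec: StructuralSpec | None = None,
    settings: FitSettings | None = None,
) -> FitResult:
    """Diagnostics at *fixed* parameters (no optimization): OFV, EBEs,
    PRED/IPRED and CWRES under the supplied model."""
    settings = settings or FitSettings()
    if isinstance(params, PopulationModel):
        spec = spec or StructuralSpec(
            residual=params.residual.kind,
            covariates=published_covariates(params.crcl_ref),
        )
    elif spec is None:
        raise ValueError("spec is required when params is a dict")
    est = InfusionNLME(
        residual=spec.residual,
        covariates=spec.covariates,
        n_compartments=spec.n_compartments,
        settings=settings,
        init=params,
        compute_rse=False,
    )
    obj = _Objective(dataset, spec, settings)
    theta, omega, sigma = est._init_values(spec)
    x = obj.pack(theta, omega, sigma)
    ofv = obj.neg2ll(x, warm=False)
    est._finalize(obj, dataset, x, ofv, True, settings)
    return est.result()


def cwres(fit_result: FitResult, dataset: TDMDataset,
          settings: FitSettings | None = None) -> pd.DataFrame:
    """CWRES plus PRED/IPRED for a fitted (or fixed) model on a dataset."""
    res = evaluate(dataset, fit_result.flat_params(), spec=fit_result.spec,
                   settings=settings)
    return res.predictions


def population_model_from_fit(fit_result: FitResult) -> PopulationModel:
    """Rebuild a :class:`PopulationModel` from a fit whose covariate structure
    is the published one (a single CRCL power effect on CL)."""
    spec = fit_result.spec
    cov_theta, ref = 0.0, 1.0
    for eff in spec.covariates:
        if eff.column == "CRCL" and eff.param == "cl" and eff.form == "power":
            cov_theta, ref = fit_result.theta[eff.key], eff.ref
            break
    s1, s2 = fit_result.omega_sd
    return PopulationModel(
        theta_cl=fit_result.theta["cl"],
        theta_vc=fit_result.theta["vc"],
        theta_cov=cov_theta,
        crcl_ref=ref,
        omega_cl=s1,
        omega_vc=s2,
        rho=fit_result.rho,
        residual=ResidualSpec(
            kind=spec.residual,
            sigma_add=fit_result.sigma.get("add", 0.0),
            sigma_prop=fit_result.sigma.get("prop", 0.0),
        ),
    )


def simulate_from_fit(
    fit_result: FitResult,
    dataset: TDMDataset,
    rng: np.random.Generator,
    include_residual: bool = True,
) -> np.ndarray:
    """Simulate one replicate of the dataset's quantifiable observations under
    the fitted model (same design: times, doses, covariates)."""
    settings = FitSettings()
    obj = _Objective(dataset, fit_result.spec, settings)
    eta = rng.multivariate_normal(np.zeros(2), fit_result.omega,
                                  size=obj.n_subjects)
    f = obj.predict(fit_result.theta, eta)
    if not include_residual:
        return f
    v = obj._residual_var(f, fit_result.sigma)
    dv = f + np.sqrt(v) * rng.standard_normal(f.size)
    neg = dv < 0
    tries = 0
    while np.any(neg) and tries < 100:
        dv[neg] = f[neg] + np.sqrt(v[neg]) * rng.standard_normal(int(neg.sum()))
        neg = dv < 0
        tries += 1
    return np.abs(dv)


# --------------------------------------------------------------------------
# covariate search
# --------------------------------------------------------------------------


def _candidate_effect(dataset: TDMDataset, column: str, param: str) -> CovariateEffect:
    vals = dataset.df.drop_duplicates("ID")[column].to_numpy(dtype=float)
    if set(np.unique(vals)).issubset({0.0, 1.0}):
        return CovariateEffect(param, column, "linear", 1.0)
    return CovariateEffect(param, column, "power", float(np.median(vals)))


def covariate_screen(
    dataset: TDMDataset,
    candidates: Sequence[str],
    settings: FitSettings | None = None,
    base_fit: FitResult | None = None,
    residual: str = "additive",
) -> list[str]:
    """Pre-screen candidate covariates for collinearity.

    Pairs with Pearson |r| >= the collinearity threshold are reduced to one
    member: the one whose single-covariate addition to the base model gives
    the larger OFV drop.  Constant covariates are excluded with a warning.
    """
    settings = settings or FitSettings()
    first = dataset.df.drop_duplicates("ID")
    usable = []
    for col in candidates:
        vals = first[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(f"covariate {col!r} is constant; excluded", stacklevel=2)
            continue
        usable.append(col)
    if len(usable) < 2:
        return usable

    corr = first[usable].astype(float).corr().abs()
    collinear_pairs = [
        (usable[i], usable[j])
        for i in range(len(usable))
        for j in range(i + 1, len(usable))
        if corr.iloc[corr.index.get_loc(usable[i]),
                     corr.index.get_loc(usable[j])] >= settings.collinearity_r
    ]
    if not collinear_pairs:
        return usable

    if base_fit is None:
        base_fit = fit(dataset, residual=residual, settings=settings,
                       compute_rse=False)

    def single_dofv(col: str) -> float:
        best = -np.inf
        for param in ("cl", "vc"):
            eff = _candidate_effect(dataset, col, param)
            res = fit(
                dataset,
                residual=residual,
                covariates=(eff,),
                init=base_fit,
                settings=settings,
                compute_rse=False,
            )
            best = max(best, base_fit.ofv - res.ofv)
        return best

    dofv_cache: dict[str, float] = {}
    dropped: set[str] = set()
    for a, b in collinear_pairs:
        if a in dropped or b in dropped:
            continue
        for col in (a, b):
            if col not in dofv_cache:
                dofv_cache[col] = single_dofv(col)
        dropped.add(a if dofv_cache[a] < dofv_cache[b] else b)
    return [c for c in usable if c not in dropped]


def stepwise_covariates(
    dataset: TDMDataset,
    candidates: Sequence[str],
    settings: FitSettings | None = None,
    residual: str = "additive",
    params: tuple[str, ...] = ("cl", "vc"),
    init=None,
    compute_rse: bool = True,
) -> tuple[FitResult, list[dict]]:
    """Stepwise covariate modeling with forward inclusion / backward
    elimination at the study's OFV thresholds (>3.84 in, >10.83 to stay).

    Continuous covariates enter as power functions normalized to the dataset
    median; binary covariates as proportional shifts.  Returns the final fit
    and a trace of every tested (covariate, parameter, dOFV).
    """
    settings = settings or FitSettings()
    trace: list[dict] = []
    current = fit(dataset, residual=residual, init=init, settings=settings,
                  compute_rse=False)
    included: list[CovariateEffect] = []
    tested_additions: set[tuple[str, str]] = set()
    candidates = list(candidates)

    while True:  # forward inclusion
        best_eff, best_dofv, best_fit = None, -np.inf, None
        for col in candidates:
            for param in params:
                if any(e.column == col and e.param == param for e in included):
                    continue
                eff = _candidate_effect(dataset, col, param)
                trial = fit(
                    dataset,
                    residual=residual,
                    covariates=tuple(included) + (eff,),
                    init=current,
                    settings=settings,
                    compute_rse=False,
                )
                dofv = current.ofv - trial.ofv
                trace.append(
                    {"step": "forward", "covariate": col, "param": param,
                     "dofv": float(dofv), "accepted": False}
                )
                if dofv > best_dofv:
                    best_eff, best_dofv, best_fit = eff, dofv, trial
        if best_eff is None or not best_dofv > settings.forward_dofv:
            break
        key = (best_eff.column, best_eff.param)
        if key in tested_additions:
            warnings.warn(
                f"covariate cycling detected for {key}; stopping search",
                stacklevel=2,
            )
            break
        tested_additions.add(key)
        included.append(best_eff)
        current = best_fit
        trace[-_pending_index(trace, best_eff)]["accepted"] = True

    changed = True
    while changed and included:  # backward elimination
        changed = False
        for eff in list(included):
            remaining = tuple(e for e in included if e is not eff)
            reduced = fit(
                dataset,
                residual=residual,
                covariates=remaining,
                init=current,
                settings=settings,
                compute_rse=False,
            )
            increase = reduced.ofv - current.ofv
            keep = increase > settings.backward_dofv
            trace.append(
                {"step": "backward", "covariate": eff.column, "param": eff.param,
                 "dofv": float(increase), "removed": not keep}
            )
            if not keep:
                included.remove(eff)
                current = reduced
                changed = True
                break

    final = fit(dataset, residual=residual, covariates=tuple(included),
                init=current, settings=settings, compute_rse=compute_rse)
    final.trace = trace
    return final, trace


def _pending_index(trace: list[dict], eff: CovariateEffect) -> int:
    """Offset from the end of the trace of the forward entry for ``eff``."""
    for off, entry in enumerate(reversed(trace), start=1):
        if (entry["step"] == "forward" and entry["covariate"] == eff.column
                and entry["param"] == eff.param):
            return off
    raise AssertionError("forward entry missing from trace")  # pragma: no cover


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Percentile summary of a nonparametric subject bootstrap."""

    table: pd.DataFrame  # parameter, median, p2.5, p97.5
    n_requested: int
    n_converged: int
    seed: int

    @property
    def unreliable(self) -> bool:
        return self.n_converged < 0.8 * self.n_requested


def _resample_dataset(dataset: TDMDataset, rng: np.random.Generator) -> TDMDataset:
    ids = np.asarray(sorted(dataset.df.ID.unique()))
    picks = rng.integers(0, ids.size, size=ids.size)
    blocks = []
    for new_id, pick in enumerate(picks, start=1):
        block = dataset.df[dataset.df.ID == ids[pick]].copy()
        block["ID"] = new_id  # duplicated subjects get unique IDs
        blocks.append(block)
    df = pd.concat(blocks, ignore_index=True)
    return TDMDataset(df=df, lloq=dataset.lloq, uloq=dataset.uloq)


def bootstrap(
    dataset: TDMDataset,
    fit_result: FitResult,
    n_replicates: int = 500,
    seed: int = 0,
    settings: FitSettings | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of the final model: resample subjects with
    replacement, refit from the final estimates, summarize converged
    replicates by the median and the 2.5/97.5 percentiles."""
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    rows = []
    n_converged = 0
    for _ in range(n_replicates):
        rep = _resample_dataset(dataset, rng)
        try:
            res = fit(
                rep,
                residual=fit_result.spec.residual,
                covariates=fit_result.spec.covariates,
                n_compartments=fit_result.spec.n_compartments,
                init=fit_result,
                settings=settings,
                compute_rse=False,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not res.converged:
            continue
        n_converged += 1
        rows.append(res.flat_params())
    if not rows:
        raise RuntimeError("no bootstrap replicate converged")
    reps = pd.DataFrame(rows)
    table = pd.DataFrame(
        {
            "parameter": reps.columns,
            "median": reps.median().to_numpy(),
            "p2.5": reps.quantile(0.025).to_numpy(),
            "p97.5": reps.quantile(0.975).to_numpy(),
        }
    )
    out = BootstrapResult(
        table=table,
        n_requested=n_replicates,
        n_converged=n_converged,
        seed=seed,
    )
    if out.unreliable:
        warnings.warn(
            f"only {n_converged}/{n_replicates} bootstrap replicates converged; "
            "percentiles may be unreliable",
            stacklevel=2,
        )
    return out
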