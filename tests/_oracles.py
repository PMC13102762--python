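"""Independent numerical oracles used to validate the closed-form and
Laplace-approximate computations.  Everything here recomputes quantities from
first principles (dense grids, explicit superposition, adaptive Gauss-Hermite
quadrature) without touching the code paths under test."""

import numpy as np
from scipy.optimize import minimize

from meropk.core_pk import conc_steady_state, conc_superposition


def ft_above_grid(ip, reg, threshold, dt=0.001):
    """Fraction of the steady-state interval above a threshold, by dense grid."""
    t = np.arange(0.0, reg.tau_h, dt)
    c = conc_steady_state(ip.cl, ip.vc, reg.dose_mg, reg.tau_h, reg.tinf_h, t)
    return float(np.mean(c > threshold))


def conc_by_superposition(ip, reg, t, n_doses=60):
    """Steady-state concentration approximated by explicit superposition."""
    return conc_superposition(
        ip.cl, ip.vc, reg.dose_mg, reg.tau_h, reg.tinf_h, t, n_doses
    )


def neg2ll_quadrature(theta_cl, theta_vc, omega, sigma_add, dataset,
                      dose=1000.0, tau=8.0, tinf=2.0, nodes=80):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Reimplements the joint density (steady-state one-compartment prediction,
    additive Gaussian residual, bivariate normal random effects) and
    integrates it per subject on a ``nodes`` x ``nodes`` adaptive tensor grid
    centered and scaled at the conditional mode.
    """
    om_inv = np.linalg.inv(omega)
    _, logdet_om = np.linalg.slogdet(omega)
    z, w = np.polynomial.hermite.hermgauss(nodes)
    total = 0.0
    for _, grp in dataset.observations.groupby("ID"):
        y = grp.DV.to_numpy(dtype=float)
        t = grp.TIME.to_numpy(dtype=float)

        def h(eta):
            eta = np.asarray(eta, dtype=float)
            cl = theta_cl * np.exp(eta[..., 0, None])
            vc = theta_vc * np.exp(eta[..., 1, None])
            f = conc_steady_state(cl, vc, dose, tau, tinf, t)
            ll = 0.5 * np.sum(
                (y - f) ** 2 / sigma_add**2 + np.log(2 * np.pi * sigma_add**2),
                axis=-1,
            )
            quad = 0.5 * np.einsum("...i,ij,...j->...", eta, om_inv, eta)
            return ll + quad + 0.5 * (logdet_om + 2 * np.log(2 * np.pi))

        mode = minimize(
            h, np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        ).x
        d = 1e-4
        hess = np.zeros((2, 2))
        for a in range(2):
            for b in range(2):
                ea = np.zeros(2)
                eb = np.zeros(2)
                ea[a] = d
                eb[b] = d
                hess[a, b] = (
                    h(mode + ea + eb) - h(mode + ea - eb)
                    - h(mode - ea + eb) + h(mode - ea - eb)
                ) / (4 * d * d)
        evals, evecs = np.linalg.eigh(hess)
        evals = np.maximum(evals, 1e-8)
        scale = evecs @ np.diag(1.0 / np.sqrt(evals))
        z1, z2 = np.meshgrid(z, z, indexing="ij")
        u = np.stack([z1.ravel(), z2.ravel()], axis=-1)
        etas = mode + np.sqrt(2.0) * u @ scale.T
        log_weights = np.log(np.outer(w, w).ravel()) + np.sum(u**2, axis=-1)
        log_terms = log_weights - h(etas)
        top = np.max(log_terms)
        log_integral = (
            np.log(2.0) - 0.5 * np.sum(np.log(evals))
            + top + np.log(np.sum(np.exp(log_terms - top)))
        )
        total += -2.0 * log_integral
    return total
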