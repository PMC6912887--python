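"""Constrained <-> unconstrained parameter transforms with log-Jacobians.

The samplers operate on an unconstrained real vector (layout documented in
:mod:`procjs._kernels`).  Standard deviations use a log map under the inverse
Wishart and half-normal priors and a scaled-logistic map under bounded
uniform priors; correlations use tanh (inverse Wishart) or a scaled logistic
(bounded uniform); probabilities use the logit.

``log_jacobian`` returns the total log-volume correction that turns the
constrained-scale prior density into the density of the unconstrained
vector.  Under the inverse Wishart prior this includes the volume factor
``|d Sigma / d (sigma_1, sigma_2, rho)| = 4 sigma_1^2 sigma_2^2`` because the
prior density is expressed with respect to Sigma while sampling is in
(sigma, rho) coordinates.
"""

from __future__ import annotations

import numpy as np

from .priors import CovarianceSpec, SeparatedPriorConfig, WishartPriorConfig

__all__ = [
    "expit",
    "logit",
    "unconstrain_params",
    "constrain_params",
    "log_jacobian",
]


def expit(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def logit(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires arguments strictly inside (0, 1)")
    out = np.log(p) - np.log1p(-p)
    return out if out.ndim else float(out)


def _bounded_to_real(value, lo, hi):
    if not lo < value < hi:
        raise ValueError(f"value {value} outside open interval ({lo}, {hi})")
    return logit((value - lo) / (hi - lo))


def _real_to_bounded(x, lo, hi):
    return lo + (hi - lo) * expit(x)


def _sigma_rho_to_real(cov: CovarianceSpec, covariance_prior):
    """Map (sigma_ad, sigma_juv, rho) to their unconstrained coordinates."""
    if isinstance(covariance_prior, WishartPriorConfig):
        if abs(cov.rho) >= 1.0:
            raise ValueError("|rho| = 1 is a boundary point and cannot be unconstrained")
        return (
            float(np.log(cov.sigma_ad)),
            float(np.log(cov.sigma_juv)),
            float(np.arctanh(cov.rho)),
        )
    cfg = covariance_prior
    x_rho = _bounded_to_real(cov.rho, cfg.rho_lower, cfg.rho_upper)
    if cfg.sigma_halfnormal_variance is None:
        x1 = _bounded_to_real(cov.sigma_ad, cfg.sigma_lower, cfg.sigma_upper)
        x2 = _bounded_to_real(cov.sigma_juv, cfg.sigma_lower, cfg.sigma_upper)
    else:
        x1 = float(np.log(cov.sigma_ad))
        x2 = float(np.log(cov.sigma_juv))
    return x1, x2, x_rho


def _real_to_sigma_rho(x1, x2, x_rho, covariance_prior) -> CovarianceSpec:
    if isinstance(covariance_prior, WishartPriorConfig):
        return CovarianceSpec(
            sigma_ad=float(np.exp(x1)),
            sigma_juv=float(np.exp(x2)),
            rho=float(np.tanh(x_rho)),
        )
    cfg = covariance_prior
    rho = _real_to_bounded(x_rho, cfg.rho_lower, cfg.rho_upper)
    if cfg.sigma_halfnormal_variance is None:
        s1 = _real_to_bounded(x1, cfg.sigma_lower, cfg.sigma_upper)
        s2 = _real_to_bounded(x2, cfg.sigma_lower, cfg.sigma_upper)
    else:
        s1, s2 = float(np.exp(x1)), float(np.exp(x2))
    return CovarianceSpec(sigma_ad=s1, sigma_juv=s2, rho=float(rho))


def unconstrain_params(params, priors) -> np.ndarray:
    """Flatten a :class:`~procjs.model.ModelParams` into the sampler vector."""
    from .model import AgeTimeDetection, ConstantDetection  # cycle guard

    x1, x2, xr = _sigma_rho_to_real(params.cov, priors.covariance)
    head = [params.mu_ad, params.mu_juv, x1, x2, xr]
    det = params.detection
    if isinstance(det, ConstantDetection):
        head.append(_bounded_to_real(det.p, 0.0, 1.0))
        tail = []
    elif isinstance(det, AgeTimeDetection):
        lo, hi = priors.sigma_p_bounds
        head.extend(
            [
                det.beta0,
                _bounded_to_real(det.sigma_p_sy, lo, hi),
                _bounded_to_real(det.sigma_p_ad, lo, hi),
            ]
        )
        tail = [det.eps_sy, det.eps_ad]
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown detection block {type(det)!r}")
    return np.concatenate(
        [np.asarray(head, float), params.eta_ad, params.eta_juv, *map(np.asarray, tail)]
    )


def constrain_params(theta, T: int, priors, detection: str = "constant"):
    """Inverse of :func:`unconstrain_params`."""
    from .model import AgeTimeDetection, ConstantDetection, ModelParams

    theta = np.asarray(theta, dtype=float)
    ni = T - 1
    cov = _real_to_sigma_rho(theta[2], theta[3], theta[4], priors.covariance)
    if detection == "constant":
        off = 6
        det = ConstantDetection(p=float(_real_to_bounded(theta[5], 0.0, 1.0)))
    elif detection == "age_time":
        off = 8
        lo, hi = priors.sigma_p_bounds
        det = AgeTimeDetection(
            beta0=float(theta[5]),
            sigma_p_sy=float(_real_to_bounded(theta[6], lo, hi)),
            sigma_p_ad=float(_real_to_bounded(theta[7], lo, hi)),
            eps_sy=theta[off + 2 * ni : off + 3 * ni].copy(),
            eps_ad=theta[off + 3 * ni : off + 4 * ni].copy(),
        )
    else:
        raise ValueError(f"unknown detection mode {detection!r}")
    expected = off + (2 if detection == "constant" else 4) * ni
    if theta.shape[0] != expected:
        raise ValueError(
            f"theta has length {theta.shape[0]}, expected {expected} for "
            f"T={T}, detection={detection!r}"
        )
    return ModelParams(
        mu_ad=float(theta[0]),
        mu_juv=float(theta[1]),
        cov=cov,
        eta_ad=theta[off : off + ni].copy(),
        eta_juv=theta[off + ni : off + 2 * ni].copy(),
        detection=det,
    )


def _logistic_jac(x):
    s = expit(np.asarray(x, float))
    return float(np.sum(np.log(s) + np.log(1.0 - s)))


def log_jacobian(theta, T: int, priors, detection: str = "constant") -> float:
    """Log-Jacobian of the unconstrained map (plus, for the inverse Wishart
    prior, the (sigma, rho) -> Sigma volume factor)."""
    theta = np.asarray(theta, dtype=float)
    cov_prior = priors.covariance
    lj = 0.0
    if isinstance(cov_prior, WishartPriorConfig):
        s1, s2 = np.exp(theta[2]), np.exp(theta[3])
        rho = np.tanh(theta[4])
        lj += float(np.log(4.0) + 3.0 * np.log(s1) + 3.0 * np.log(s2))
        lj += float(np.log1p(-(rho**2)))
    else:
        lj += _logistic_jac(theta[4])  # rho (bound width cancels against density)
        lj += float(np.log(cov_prior.rho_upper - cov_prior.rho_lower))
        if cov_prior.sigma_halfnormal_variance is None:
            lj += _logistic_jac(theta[2]) + _logistic_jac(theta[3])
            lj += 2.0 * float(np.log(cov_prior.sigma_upper - cov_prior.sigma_lower))
        else:
            lj += float(theta[2] + theta[3])  # d sigma / dx = sigma = exp(x)
    if detection == "constant":
        lj += _logistic_jac(theta[5])
    else:
        lo, hi = priors.sigma_p_bounds
        lj += _logistic_jac(theta[6]) + _logistic_jac(theta[7])
        lj += 2.0 * float(np.log(hi - lo))
    return lj
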