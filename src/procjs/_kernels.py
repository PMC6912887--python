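"""Jitted numerical kernels: m-array log-likelihood, log-posterior, samplers.

Everything here operates on plain float64 arrays so numba can compile it; the
readable reference implementations (scipy-based densities, dataclass
parameters) live in :mod:`procjs.model` and are tested for exact agreement
with these kernels.

Unconstrained parameter vector layouts
--------------------------------------
constant detection (det_mode = 0), d = 6 + 2(T-1)::

    [mu_ad, mu_juv, x_sig_ad, x_sig_juv, x_rho, x_p,
     eta_ad[0..T-2], eta_juv[0..T-2]]

age/time-varying detection (det_mode = 1), d = 8 + 4(T-1)::

    [mu_ad, mu_juv, x_sig_ad, x_sig_juv, x_rho, beta0, x_sigp_sy, x_sigp_ad,
     eta_ad[...], eta_juv[...], eps_sy[...], eps_ad[...]]

where eta are the logit-scale annual survival effects (centered
parameterization) and eps the logit-scale annual detection effects.

Transform conventions (prior_kind):
  0  inverse Wishart:   sigma_k = exp(x), rho = tanh(x)
  1  separated uniform: sigma_k and rho via bounded logistic maps
  2  separated half-normal sigmas: sigma_k = exp(x), rho bounded logistic

``consts`` packs the scalar hyperparameters:
  [sig_lo, sig_hi, rho_lo, rho_hi, iw_df, halfnorm_var, mean_sd,
   beta0_sd, sigp_lo, sigp_hi]
"""

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)

# consts indices
C_SIG_LO = 0
C_SIG_HI = 1
C_RHO_LO = 2
C_RHO_HI = 3
C_IW_DF = 4
C_HN_VAR = 5
C_MEAN_SD = 6
C_BETA0_SD = 7
C_SIGP_LO = 8
C_SIGP_HI = 9

N_CONSTS = 10


@njit(cache=True, inline="always")
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def loglik_marray(m_juv, m_ad, phi_ad, phi_juv, p_ad, p_sy):
    """Multinomial m-array log-likelihood (multinomial coefficient omitted).

    ``p_ad`` and ``p_sy`` are length-T detection vectors indexed by occasion;
    ``p_sy`` applies only at the occasion immediately after a juvenile
    release (constant detection passes the same vector twice).
    """
    T = m_juv.shape[1]
    ll = 0.0
    for arr in range(2):
        m = m_juv if arr == 0 else m_ad
        for r in range(T - 1):
            total = 0
            for c in range(T):
                total += m[r, c]
            if total == 0:
                continue
            alive = phi_juv[r] if arr == 0 else phi_ad[r]
            psum = 0.0
            for c in range(r + 1, T):
                if arr == 0 and c == r + 1:
                    pc = p_sy[c]
                else:
                    pc = p_ad[c]
                cellp = alive * pc
                cnt = m[r, c - 1]
                if cnt > 0:
                    if cellp <= 0.0:
                        return -1.0e300
                    ll += cnt * math.log(cellp)
                psum += cellp
                if c < T - 1:
                    alive *= (1.0 - pc) * phi_ad[c]
            never = 1.0 - psum
            cnt = m[r, T - 1]
            if cnt > 0:
                if never < 1.0e-300:
                    never = 1.0e-300
                ll += cnt * math.log(never)
    return ll


@njit(cache=True, inline="always")
def _norm_logpdf(x, sd):
    return -0.5 * LOG2PI - math.log(sd) - 0.5 * (x / sd) ** 2


@njit(cache=True)
def _cov_prior_and_jac(x_sig_ad, x_sig_juv, x_rho, prior_kind, consts, scale):
    """Transform the covariance block and return (sigma_ad, sigma_juv, rho, logdens).

    ``logdens`` is the prior log-density of the covariance block *plus* the
    log-Jacobian of the unconstrained map, i.e. the full contribution of
    these three coordinates to the log target.
    """
    if prior_kind == 0:
        # sigma = exp(x), rho = tanh(x); inverse-Wishart density on Sigma
        s1 = math.exp(x_sig_ad)
        s2 = math.exp(x_sig_juv)
        rho = math.tanh(x_rho)
        nu = consts[C_IW_DF]
        det_scale = scale[0, 0] * scale[1, 1] - scale[0, 1] * scale[1, 0]
        one_m_r2 = 1.0 - rho * rho
        if one_m_r2 < 1.0e-300:
            return s1, s2, rho, -1.0e300
        det_sigma = (s1 * s2) ** 2 * one_m_r2
        # Sigma^-1 entries
        inv11 = 1.0 / (s1 * s1 * one_m_r2)
        inv22 = 1.0 / (s2 * s2 * one_m_r2)
        inv12 = -rho / (s1 * s2 * one_m_r2)
        tr = scale[0, 0] * inv11 + scale[1, 1] * inv22 + 2.0 * scale[0, 1] * inv12
        # multivariate gamma_2(nu/2)
        lmg = 0.5 * math.log(math.pi) + math.lgamma(0.5 * nu) + math.lgamma(
            0.5 * nu - 0.5
        )
        logiw = (
            0.5 * nu * math.log(det_scale)
            - nu * math.log(2.0)
            - lmg
            - 0.5 * (nu + 3.0) * math.log(det_sigma)
            - 0.5 * tr
        )
        # |d Sigma / d (s1, s2, rho)| = 4 s1^2 s2^2; d sigma/dx = sigma;
        # d rho / dx = 1 - rho^2
        logjac = (
            math.log(4.0)
            + 2.0 * math.log(s1)
            + 2.0 * math.log(s2)
            + math.log(s1)
            + math.log(s2)
            + math.log(one_m_r2)
        )
        return s1, s2, rho, logiw + logjac
    else:
        rlo = consts[C_RHO_LO]
        rhi = consts[C_RHO_HI]
        q = _expit(x_rho)
        rho = rlo + (rhi - rlo) * q
        # uniform rho density 1/(rhi-rlo) times Jacobian (rhi-rlo) q (1-q)
        logdens = math.log(q) + math.log(1.0 - q)
        if prior_kind == 1:
            lo = consts[C_SIG_LO]
            hi = consts[C_SIG_HI]
            s = _expit(x_sig_ad)
            s1 = lo + (hi - lo) * s
            logdens += math.log(s) + math.log(1.0 - s)
            s = _expit(x_sig_juv)
            s2 = lo + (hi - lo) * s
            logdens += math.log(s) + math.log(1.0 - s)
        else:
            v = consts[C_HN_VAR]
            s1 = math.exp(x_sig_ad)
            s2 = math.exp(x_sig_juv)
            lhn = 0.5 * math.log(2.0 / (math.pi * v))
            logdens += lhn - s1 * s1 / (2.0 * v) + math.log(s1)
            logdens += lhn - s2 * s2 / (2.0 * v) + math.log(s2)
        return s1, s2, rho, logdens


@njit(cache=True)
def logpost(theta, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik):
    """Log posterior density of the unconstrained parameter vector."""
    T = m_juv.shape[1]
    ni = T - 1
    mu_ad = theta[0]
    mu_juv = theta[1]
    s1, s2, rho, lp = _cov_prior_and_jac(
        theta[2], theta[3], theta[4], prior_kind, consts, scale
    )
    if lp <= -1.0e299:
        return -1.0e300
    mean_sd = consts[C_MEAN_SD]
    lp += _norm_logpdf(mu_ad, mean_sd) + _norm_logpdf(mu_juv, mean_sd)

    p = 0.5
    beta0 = 0.0
    sigp_sy = 1.0
    sigp_ad = 1.0
    if det_mode == 0:
        off = 6
        x_p = theta[5]
        p = _expit(x_p)
        # p ~ Uniform(0,1); logit Jacobian p(1-p)
        lp += math.log(p) + math.log(1.0 - p)
    else:
        off = 8
        beta0 = theta[5]
        lp += _norm_logpdf(beta0, consts[C_BETA0_SD])
        splo = consts[C_SIGP_LO]
        sphi = consts[C_SIGP_HI]
        q = _expit(theta[6])
        sigp_sy = splo + (sphi - splo) * q
        lp += math.log(q) + math.log(1.0 - q)
        q = _expit(theta[7])
        sigp_ad = splo + (sphi - splo) * q
        lp += math.log(q) + math.log(1.0 - q)

    eta_ad = theta[off : off + ni]
    eta_juv = theta[off + ni : off + 2 * ni]
    eps_sy = theta[0:0]
    eps_ad = theta[0:0]
    if det_mode == 1:
        eps_sy = theta[off + 2 * ni : off + 3 * ni]
        eps_ad = theta[off + 3 * ni : off + 4 * ni]

    # bivariate normal year effects, centered parameterization
    one_m_r2 = 1.0 - rho * rho
    if one_m_r2 < 1.0e-12:
        one_m_r2 = 1.0e-12
    logdet = 2.0 * math.log(s1) + 2.0 * math.log(s2) + math.log(one_m_r2)
    for t in range(ni):
        a = (eta_ad[t] - mu_ad) / s1
        b = (eta_juv[t] - mu_juv) / s2
        quad = (a * a - 2.0 * rho * a * b + b * b) / one_m_r2
        lp += -LOG2PI - 0.5 * logdet - 0.5 * quad

    if det_mode == 1:
        for t in range(ni):
            lp += _norm_logpdf(eps_sy[t], sigp_sy)
            lp += _norm_logpdf(eps_ad[t], sigp_ad)

    if include_lik == 0:
        return lp

    phi_ad = np.empty(ni)
    phi_juv = np.empty(ni)
    for t in range(ni):
        phi_ad[t] = _expit(eta_ad[t])
        phi_juv[t] = _expit(eta_juv[t])
    p_ad_vec = np.empty(T)
    p_sy_vec = np.empty(T)
    if det_mode == 0:
        for c in range(T):
            p_ad_vec[c] = p
            p_sy_vec[c] = p
    else:
        p_ad_vec[0] = 0.5
        p_sy_vec[0] = 0.5
        for c in range(1, T):
            p_ad_vec[c] = _expit(beta0 + eps_ad[c - 1])
            p_sy_vec[c] = _expit(beta0 + eps_sy[c - 1])
    ll = loglik_marray(m_juv, m_ad, phi_ad, phi_juv, p_ad_vec, p_sy_vec)
    if ll <= -1.0e299:
        return -1.0e300
    return lp + ll


@njit(cache=True)
def run_am(
    theta0,
    n_iter,
    seed,
    m_juv,
    m_ad,
    prior_kind,
    det_mode,
    consts,
    scale,
    include_lik,
    init_step,
):
    """Adaptive Metropolis: joint Gaussian random walk with empirically
    adapted proposal covariance and Robbins-Monro step-size tuning toward an
    acceptance rate of 0.234.
    """
    np.random.seed(seed)
    d = theta0.shape[0]
    chain = np.empty((n_iter, d))
    lp_trace = np.empty(n_iter)
    theta = theta0.copy()
    lp = logpost(theta, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik)

    mean = theta.copy()
    cov_acc = np.zeros((d, d))
    n_s = 1.0
    L = np.eye(d) * init_step
    use_emp = False
    sd = 2.38 * 2.38 / d
    log_s = 0.0
    n_accept = 0
    adapt_start = 200 if 200 > 4 * d else 4 * d
    refresh = 100

    for i in range(n_iter):
        z = np.random.standard_normal(d)
        step = np.dot(L, z)
        prop = theta + math.exp(log_s) * step
        lpp = logpost(
            prop, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik
        )
        diff = lpp - lp
        if diff >= 0.0:
            acc_prob = 1.0
        elif diff < -50.0:
            acc_prob = 0.0
        else:
            acc_prob = math.exp(diff)
        if np.random.random() < acc_prob:
            theta = prop
            lp = lpp
            n_accept += 1
        chain[i] = theta
        lp_trace[i] = lp

        # running mean / covariance of the chain
        n_s += 1.0
        delta = theta - mean
        mean = mean + delta / n_s
        delta2 = theta - mean
        for a in range(d):
            da = delta[a]
            for b in range(d):
                cov_acc[a, b] += da * delta2[b]

        gamma = (i + 1.0) ** (-0.6)
        log_s += gamma * (acc_prob - 0.234)
        if log_s > 5.0:
            log_s = 5.0
        elif log_s < -5.0:
            log_s = -5.0

        if i >= adapt_start and (i % refresh) == 0:
            C = cov_acc / (n_s - 1.0)
            for a in range(d):
                C[a, a] += 1.0e-9 + 1.0e-6 * C[a, a]
            L = np.linalg.cholesky(sd * C)
            if not use_emp:
                use_emp = True
                log_s = 0.0

    return chain, lp_trace, n_accept / n_iter


@njit(cache=True, inline="always")
def _sig_rho_from_x(x_sig_ad, x_sig_juv, x_rho, prior_kind, consts):
    """Covariance-block transform only (no densities)."""
    if prior_kind == 0:
        return math.exp(x_sig_ad), math.exp(x_sig_juv), math.tanh(x_rho)
    rlo = consts[C_RHO_LO]
    rhi = consts[C_RHO_HI]
    rho = rlo + (rhi - rlo) * _expit(x_rho)
    if prior_kind == 1:
        lo = consts[C_SIG_LO]
        hi = consts[C_SIG_HI]
        s1 = lo + (hi - lo) * _expit(x_sig_ad)
        s2 = lo + (hi - lo) * _expit(x_sig_juv)
    else:
        s1 = math.exp(x_sig_ad)
        s2 = math.exp(x_sig_juv)
    return s1, s2, rho


@njit(cache=True)
def run_block(
    theta0,
    n_iter,
    seed,
    m_juv,
    m_ad,
    prior_kind,
    det_mode,
    consts,
    scale,
    include_lik,
    init_step,
):
    """Blocked adaptive Metropolis.

    One iteration updates (a) the hyperparameter head (means, covariance
    block, detection scalars) with a jointly adapted Gaussian proposal and
    (b) each annual-effect pair (eta_ad_t, eta_juv_t) — plus each detection
    pair in the age/time variant — with its own scalar-adapted 2-D random
    walk.  Pairs are nearly conditionally independent across years given the
    hyperparameters, so this mixes like a Gibbs scheme while needing only
    the joint density.
    """
    np.random.seed(seed)
    d = theta0.shape[0]
    T = m_juv.shape[1]
    ni = T - 1
    off = 6 if det_mode == 0 else 8
    nblocks = ni if det_mode == 0 else 2 * ni
    chain = np.empty((n_iter, d))
    lp_trace = np.empty(n_iter)
    theta = theta0.copy()
    lp = logpost(theta, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik)

    # hyper-block adaptive Metropolis state
    mean = theta[:off].copy()
    cov_acc = np.zeros((off, off))
    n_s = 1.0
    L = np.eye(off) * init_step
    sd = 2.38 * 2.38 / off
    log_s = 0.0
    reset_done = False
    adapt_start = 200
    refresh = 100

    # non-centered (interweaved) head update state: holds the standardized
    # year effects fixed while the head moves, breaking the sigma-eta funnel
    mean2 = theta[:off].copy()
    cov_acc2 = np.zeros((off, off))
    n_s2 = 1.0
    L2 = np.eye(off) * init_step
    log_s2 = 0.0
    reset2_done = False
    prop = theta.copy()
    u1 = np.empty(ni)
    u2 = np.empty(ni)
    v1 = np.empty(ni)
    v2 = np.empty(ni)

    # per-pair scales
    log_bs = np.full(nblocks, math.log(0.2))
    acc_b = np.zeros(nblocks)
    batch = 50
    n_batch = 0
    old_vals = np.empty(off)
    n_accept = 0.0
    n_total = 0.0

    hyper_reps = 5  # several cheap head updates per sweep: the head, not the
    # annual pairs, limits mixing of (sigma, rho) when data are weak

    for i in range(n_iter):
        # ---- hyperparameter block
        for rep in range(hyper_reps):
            for j in range(off):
                old_vals[j] = theta[j]
            z = np.random.standard_normal(off)
            step = np.dot(L, z)
            for j in range(off):
                theta[j] = old_vals[j] + math.exp(log_s) * step[j]
            lpp = logpost(
                theta, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik
            )
            diff = lpp - lp
            if diff >= 0.0:
                acc_prob = 1.0
            elif diff < -50.0:
                acc_prob = 0.0
            else:
                acc_prob = math.exp(diff)
            if np.random.random() < acc_prob:
                lp = lpp
                n_accept += 1.0
            else:
                for j in range(off):
                    theta[j] = old_vals[j]
            n_total += 1.0
            gamma = (i + 1.0) ** (-0.6)
            log_s += gamma * (acc_prob - 0.234)
            if log_s > 5.0:
                log_s = 5.0
            elif log_s < -5.0:
                log_s = -5.0
            n_s += 1.0
            for a in range(off):
                old_vals[a] = theta[a] - mean[a]  # reuse as delta buffer
            for a in range(off):
                mean[a] += old_vals[a] / n_s
            for a in range(off):
                da = old_vals[a]
                for b in range(off):
                    cov_acc[a, b] += da * (theta[b] - mean[b])
        if i >= adapt_start and (i % refresh) == 0:
            C = cov_acc / (n_s - 1.0)
            for a in range(off):
                C[a, a] += 1.0e-9 + 1.0e-6 * C[a, a]
            L = np.linalg.cholesky(sd * C)
            if not reset_done:
                reset_done = True
                log_s = 0.0

        # ---- non-centered head updates (ancillarity interweaving)
        for rep in range(hyper_reps):
            sc1, sc2, rc = _sig_rho_from_x(
                theta[2], theta[3], theta[4], prior_kind, consts
            )
            l11 = sc1
            l21 = sc2 * rc
            l22 = sc2 * math.sqrt(max(1.0 - rc * rc, 1.0e-12))
            for t in range(ni):
                e1 = theta[off + t] - theta[0]
                e2 = theta[off + ni + t] - theta[1]
                u1[t] = e1 / l11
                u2[t] = (e2 - l21 * u1[t]) / l22
            if det_mode == 1:
                splo = consts[C_SIGP_LO]
                sphi = consts[C_SIGP_HI]
                sp_sy = splo + (sphi - splo) * _expit(theta[6])
                sp_ad = splo + (sphi - splo) * _expit(theta[7])
                for t in range(ni):
                    v1[t] = theta[off + 2 * ni + t] / sp_sy
                    v2[t] = theta[off + 3 * ni + t] / sp_ad
            else:
                sp_sy = 1.0
                sp_ad = 1.0
            z = np.random.standard_normal(off)
            step = np.dot(L2, z)
            for j in range(d):
                prop[j] = theta[j]
            for j in range(off):
                prop[j] = theta[j] + math.exp(log_s2) * step[j]
            sn1, sn2, rn = _sig_rho_from_x(
                prop[2], prop[3], prop[4], prior_kind, consts
            )
            m11 = sn1
            m21 = sn2 * rn
            m22 = sn2 * math.sqrt(max(1.0 - rn * rn, 1.0e-12))
            for t in range(ni):
                prop[off + t] = prop[0] + m11 * u1[t]
                prop[off + ni + t] = prop[1] + m21 * u1[t] + m22 * u2[t]
            if det_mode == 1:
                spn_sy = splo + (sphi - splo) * _expit(prop[6])
                spn_ad = splo + (sphi - splo) * _expit(prop[7])
                for t in range(ni):
                    prop[off + 2 * ni + t] = spn_sy * v1[t]
                    prop[off + 3 * ni + t] = spn_ad * v2[t]
            else:
                spn_sy = 1.0
                spn_ad = 1.0
            lpp = logpost(
                prop, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik
            )
            # Jacobian of eta(head, u): det = (l11 l22)^(T-1) per class pair,
            # plus (sigp)^(T-1) per detection class in age/time mode
            corr = ni * (math.log(m11 * m22) - math.log(l11 * l22))
            if det_mode == 1:
                corr += ni * (
                    math.log(spn_sy * spn_ad) - math.log(sp_sy * sp_ad)
                )
            diff = lpp + corr - lp
            if diff >= 0.0:
                acc_prob = 1.0
            elif diff < -50.0:
                acc_prob = 0.0
            else:
                acc_prob = math.exp(diff)
            if np.random.random() < acc_prob:
                for j in range(d):
                    theta[j] = prop[j]
                lp = lpp
                n_accept += 1.0
            n_total += 1.0
            gamma = (i + 1.0) ** (-0.6)
            log_s2 += gamma * (acc_prob - 0.234)
            if log_s2 > 5.0:
                log_s2 = 5.0
            elif log_s2 < -5.0:
                log_s2 = -5.0
            n_s2 += 1.0
            for a in range(off):
                old_vals[a] = theta[a] - mean2[a]
            for a in range(off):
                mean2[a] += old_vals[a] / n_s2
            for a in range(off):
                da = old_vals[a]
                for b in range(off):
                    cov_acc2[a, b] += da * (theta[b] - mean2[b])
        if i >= adapt_start and (i % refresh) == 0:
            C = cov_acc2 / (n_s2 - 1.0)
            for a in range(off):
                C[a, a] += 1.0e-9 + 1.0e-6 * C[a, a]
            L2 = np.linalg.cholesky(sd * C)
            if not reset2_done:
                reset2_done = True
                log_s2 = 0.0

        # ---- annual-effect pairs (and detection pairs in age/time mode)
        for blk in range(nblocks):
            if blk < ni:
                j1 = off + blk
                j2 = off + ni + blk
            else:
                t = blk - ni
                j1 = off + 2 * ni + t
                j2 = off + 3 * ni + t
            o1 = theta[j1]
            o2 = theta[j2]
            s = math.exp(log_bs[blk])
            theta[j1] = o1 + s * np.random.standard_normal()
            theta[j2] = o2 + s * np.random.standard_normal()
            lpp = logpost(
                theta, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik
            )
            diff = lpp - lp
            accept = False
            if diff >= 0.0:
                accept = True
            elif diff > -50.0 and np.random.random() < math.exp(diff):
                accept = True
            if accept:
                lp = lpp
                acc_b[blk] += 1.0
                n_accept += 1.0
            else:
                theta[j1] = o1
                theta[j2] = o2
            n_total += 1.0

        chain[i] = theta
        lp_trace[i] = lp
        if (i + 1) % batch == 0:
            n_batch += 1
            delta = 0.05 if 0.05 < n_batch ** (-0.5) else n_batch ** (-0.5)
            for blk in range(nblocks):
                if acc_b[blk] / batch > 0.35:
                    log_bs[blk] += delta
                else:
                    log_bs[blk] -= delta
                if log_bs[blk] > 5.0:
                    log_bs[blk] = 5.0
                elif log_bs[blk] < -8.0:
                    log_bs[blk] = -8.0
                acc_b[blk] = 0.0

    return chain, lp_trace, n_accept / n_total


@njit(cache=True)
def run_mwg(
    theta0,
    n_iter,
    seed,
    m_juv,
    m_ad,
    prior_kind,
    det_mode,
    consts,
    scale,
    include_lik,
    init_step,
):
    """Adaptive Metropolis-within-Gibbs: one univariate Gaussian random-walk
    update per coordinate per sweep, with per-coordinate step sizes batch
    adapted toward a 0.44 acceptance rate.
    """
    np.random.seed(seed)
    d = theta0.shape[0]
    chain = np.empty((n_iter, d))
    lp_trace = np.empty(n_iter)
    theta = theta0.copy()
    lp = logpost(theta, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik)
    log_scales = np.full(d, math.log(init_step))
    acc = np.zeros(d)
    batch = 50
    n_batch = 0
    n_accept = 0.0
    n_total = 0.0

    for i in range(n_iter):
        for j in range(d):
            old = theta[j]
            theta[j] = old + math.exp(log_scales[j]) * np.random.standard_normal()
            lpp = logpost(
                theta, m_juv, m_ad, prior_kind, det_mode, consts, scale, include_lik
            )
            diff = lpp - lp
            accept = False
            if diff >= 0.0:
                accept = True
            elif diff > -50.0 and np.random.random() < math.exp(diff):
                accept = True
            if accept:
                lp = lpp
                acc[j] += 1.0
                n_accept += 1.0
            else:
                theta[j] = old
            n_total += 1.0
        chain[i] = theta
        lp_trace[i] = lp
        if (i + 1) % batch == 0:
            n_batch += 1
            delta = 0.05 if 0.05 < n_batch ** (-0.5) else n_batch ** (-0.5)
            for j in range(d):
                if acc[j] / batch > 0.44:
                    log_scales[j] += delta
                else:
                    log_scales[j] -= delta
                if log_scales[j] > 5.0:
                    log_scales[j] = 5.0
                elif log_scales[j] < -8.0:
                    log_scales[j] = -8.0
                acc[j] = 0.0

    return chain, lp_trace, n_accept / n_total
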