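"""Vectorized marginal-likelihood kernel (internal).

Per subject the marginal likelihood integrates the conditional likelihood
over bivariate-normal random intercepts.  With (tau0, tau1) = L u,
L = chol(S), u standard bivariate normal, and a Gauss-Hermite product rule
{(z_i, w_i)} normalized against the N(0,1) kernel, the subject
log-likelihood is a log-sum-exp over the q*q node grid of

    A_s(i)   = sum_obs log P(indicator | tau0)                   (all rows)
    B_s(i,j) = sum_obs log f_SN(log y; mu + tau1)                (y>0 rows)

A depends on the first node index only, B on both; exploiting that split
keeps the cost at q*N + q^2*N_pos rather than q^2*N.

Adaptive (recentered) quadrature substitutes u = M_s + C_s z per subject,
with M_s the mode of the conditional posterior g_s(u) = conditional
log-likelihood + log phi2(u) and C_s the Cholesky factor of its inverse
negative curvature:

    L_s = log sum_ij w_i w_j exp(g-terms) + log phi2(U)/phi2(z) + log|C_s|.

Because C_s is lower-triangular, tau0 still depends on the first node
index only and the A/B split survives.  Modes are located by a damped
Newton iteration run simultaneously for all subjects (the conditional
posterior is strictly concave in u for both links, so Newton is safe).

Gradients with respect to all model parameters are computed analytically
alongside the value via the posterior node weights P(i,j|s); for the
adaptive rule the recentering (M, C) is held fixed during a gradient
evaluation (the caller refreshes it between optimization cycles), which
keeps the gradient exact for the objective actually being optimized.
Everything is plain numpy; log-sum-exp accumulation keeps 51-observation
subjects from underflowing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import expit, log_expit, log_ndtr

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
_LOG2 = np.log(2.0)


@lru_cache(maxsize=32)
def gh_normal(n: int):
    """Gauss-Hermite nodes/weights normalized for the N(0,1) kernel.

    The returned weights sum to exactly 1; the n-point rule integrates
    polynomials of degree <= 2n-1 exactly against the standard normal.
    """
    if n < 1:
        raise ValueError(f"n_points must be >= 1, got {n}")
    z, w = np.polynomial.hermite_e.hermegauss(n)
    w = w / w.sum()
    z.setflags(write=False)
    w.setflags(write=False)
    return z, w


def _norm_logpdf(x):
    return -0.5 * x * x - _HALF_LOG_2PI


def _segment_sum(arr, starts, present, n_seg):
    """Row-block segment sums along the last axis, scattered to n_seg slots."""
    out = np.zeros(arr.shape[:-1] + (n_seg,))
    if present.size:
        out[..., present] = np.add.reduceat(arr, starts, axis=-1)
    return out


def _binary_d1d2(eta, sgn, link):
    """First/second derivatives of the binary-part log-density wrt eta."""
    if link == "probit":
        x = sgn * eta
        h = np.exp(_norm_logpdf(x) - log_ndtr(x))
        return sgn * h, -h * (x + h)
    p = expit(eta)
    # logit: y>0 -> log p, y=0 -> log(1-p); both have d2 = -p(1-p)
    return np.where(sgn > 0, 1.0 - p, -p), -p * (1.0 - p)


def _sn_d1d2(R, sigma, delta, s, s2):
    """First/second derivatives of the SN log-density wrt its location mu."""
    if delta == 0.0:
        return R / sigma, np.full_like(R, -1.0 / (sigma * sigma))
    W = (delta / sigma) * R
    h = np.exp(_norm_logpdf(W) - log_ndtr(W))
    d1 = R / s - h * (delta / (sigma * s))
    d2 = -1.0 / s2 - (delta * delta / (sigma * sigma * s2)) * h * (W + h)
    return d1, d2


def find_modes(data, beta1, beta2, sigma, delta, L, link="probit", max_iter=40, tol=1e-9):
    """Conditional-posterior modes and curvature factors for every subject.

    Returns ``(M, c00, c10, c11, logdetC)`` where ``M`` is the (S, 2) array
    of modes of g_s(u) (u-space) and ``(c00, c10, c11)`` the per-subject
    lower-Cholesky factor of the inverse negative Hessian at the mode.
    """
    L00, L10, L11 = L
    S = data.n_subjects
    eta = data.X1 @ beta1
    sgn = data.sgn
    subj = data.subj
    tm = data.t_pos - data.X2_pos @ beta2
    psub = data.pos_subj
    if delta == 0.0:
        s2, s = sigma * sigma, sigma
    else:
        s2 = sigma * sigma + delta * delta
        s = np.sqrt(s2)
    allseg = np.arange(S)

    u = np.zeros((S, 2))
    for _ in range(max_iter):
        tau0 = L00 * u[:, 0]
        tau1 = L10 * u[:, 0] + L11 * u[:, 1]
        d1b, d2b = _binary_d1d2(eta + tau0[subj], sgn, link)
        G0 = _segment_sum(d1b, data.starts, allseg, S)
        H0 = _segment_sum(d2b, data.starts, allseg, S)
        R = (tm - tau1[psub]) / s
        d1s, d2s = _sn_d1d2(R, sigma, delta, s, s2)
        G1 = _segment_sum(d1s, data.pos_starts, data.pos_present, S)
        H1 = _segment_sum(d2s, data.pos_starts, data.pos_present, S)

        g0 = L00 * G0 + L10 * G1 - u[:, 0]
        g1 = L11 * G1 - u[:, 1]
        huu = L00 * L00 * H0 + L10 * L10 * H1 - 1.0
        huv = L10 * L11 * H1
        hvv = L11 * L11 * H1 - 1.0
        det = huu * hvv - huv * huv
        d0 = -(hvv * g0 - huv * g1) / det
        d1 = -(huu * g1 - huv * g0) / det
        step = np.sqrt(d0 * d0 + d1 * d1)
        lim = np.minimum(1.0, 3.0 / np.maximum(step, 1e-300))
        u[:, 0] += lim * d0
        u[:, 1] += lim * d1
        if max(np.max(np.abs(g0)), np.max(np.abs(g1))) < tol:
            break

    # curvature at the (final) mode
    p00, p01, p11 = -huu, -huv, -hvv
    det = p00 * p11 - p01 * p01
    c00 = np.sqrt(p11 / det)
    c10 = -p01 / det / c00
    c11 = np.sqrt(np.maximum(p00 / det - c10 * c10, 1e-300))
    return u, c00, c10, c11, np.log(c00 * c11)


def loglik_parts(
    data,
    beta1,
    beta2,
    sigma,
    delta,
    L,
    z,
    w,
    link="probit",
    want_grad=False,
    centers=None,
):
    """Per-subject marginal log-likelihoods and (optionally) the gradient.

    Parameters
    ----------
    data : LongDataset
    beta1, beta2 : ndarray
    sigma, delta : float
    L : (L00, L10, L11) lower-Cholesky entries of the RE covariance
    z, w : 1-D quadrature nodes/weights (normal kernel, weights sum to 1)
    want_grad : bool
        If True also return a dict of gradients of sum(loglik) with respect
        to beta1, beta2, sigma, delta, L00, L10, L11.
    centers : tuple or None
        Per-subject recentering ``(M, c00, c10, c11, logdetC)`` from
        :func:`find_modes`; None means the plain (non-adaptive) rule.

    Returns
    -------
    ll : (n_subjects,) ndarray
    grads : dict or None
    """
    L00, L10, L11 = L
    q = z.shape[0]
    S = data.n_subjects
    logw = np.log(w)
    subj = data.subj
    Np = data.pos_idx.size

    if centers is None:
        # U0 (q, 1) broadcasts over subjects; U1 (q, q, 1) likewise
        U0 = z[:, None]
        U1 = np.broadcast_to(z[None, :, None], (q, q, 1))
        extra = 0.0
    else:
        M, c00, c10, c11, logdetC = centers
        U0 = M[None, :, 0] + c00[None, :] * z[:, None]  # (q, S)
        U1 = (
            M[None, None, :, 1]
            + c10[None, None, :] * z[:, None, None]
            + c11[None, None, :] * z[None, :, None]
        )  # (q, q, S)
        extra = (
            logdetC[None, None, :]
            - 0.5 * (U0 * U0)[:, None, :]
            - 0.5 * U1 * U1
            + 0.5 * (z * z)[:, None, None]
            + 0.5 * (z * z)[None, :, None]
        )

    # ---- binary part: tau0 = L00 * U0 depends on the first index only ----
    eta = data.X1 @ beta1  # (N,)
    tau0 = L00 * U0  # (q, S) or (q, 1)
    Eg = eta[None, :] + (tau0 if centers is None else tau0[:, subj])  # (q, N)
    sg = data.sgn[None, :]
    if link == "probit":
        A_obs = log_ndtr(sg * Eg)
    elif link == "logit":
        A_obs = log_expit(sg * Eg)
    else:
        raise ValueError(f"unknown link {link!r}")
    A = _segment_sum(A_obs, data.starts, np.arange(S), S)  # (q, S)

    # ---- severity part: positives only ----
    tm = data.t_pos - data.X2_pos @ beta2  # (Np,)
    tau1 = L10 * U0[:, None, :] + L11 * U1  # (q, q, S) adaptive, (q, q, 1) plain
    if delta == 0.0:
        s2, s = sigma * sigma, sigma
    else:
        s2 = sigma * sigma + delta * delta
        s = np.sqrt(s2)
    tau1_obs = tau1[:, :, data.pos_subj] if centers is not None else tau1
    R = (tm[None, None, :] - tau1_obs) / s  # (q, q, Np)
    if delta == 0.0:
        B_obs = -_HALF_LOG_2PI - np.log(sigma) - 0.5 * R * R
        lcdf = None
    else:
        W = (delta / sigma) * R
        lcdf = log_ndtr(W)
        B_obs = _LOG2 - _HALF_LOG_2PI - 0.5 * np.log(s2) - 0.5 * R * R + lcdf
    B = _segment_sum(
        B_obs.reshape(q * q, Np), data.pos_starts, data.pos_present, S
    ).reshape(q, q, S)

    # ---- combine on the node grid ----
    C = (A + logw[:, None])[:, None, :] + logw[None, :, None] + B + extra  # (q, q, S)
    Cmax = C.max(axis=(0, 1))
    ll = Cmax + np.log(np.exp(C - Cmax).sum(axis=(0, 1)))

    if not want_grad:
        return ll, None

    P = np.exp(C - ll)  # posterior node weights, sums to 1 over (i,j)

    # binary part gradient: dA/deta
    if link == "probit":
        npdf = -0.5 * Eg * Eg - _HALF_LOG_2PI
        G_eta = sg * np.exp(npdf - A_obs)
    else:
        G_eta = sg * expit(-sg * Eg)
    P0 = P.sum(axis=1)  # (q, S)
    P0_obs = P0[:, subj]  # (q, N)
    WG = P0_obs * G_eta
    g_beta1 = data.X1.T @ WG.sum(axis=0)
    if centers is None:
        g_L00 = float(z @ WG.sum(axis=1))
    else:
        g_L00 = float((U0[:, subj] * WG).sum())

    # severity part gradient
    if Np:
        Pp = P[:, :, data.pos_subj]  # (q, q, Np)
        if delta == 0.0:
            Gmu = R / s
            Gsig = (R * R - 1.0) / sigma
            Gdel = np.sqrt(2.0 / np.pi) * R / sigma
        else:
            h = np.exp(-0.5 * W * W - _HALF_LOG_2PI - lcdf)  # phi/Phi at W
            Gmu = R / s - h * (delta / (sigma * s))
            Gsig = (R * R - 1.0) * sigma / s2 - h * (delta * R) * (1.0 / s2 + 1.0 / (sigma * sigma))
            Gdel = (R * R - 1.0) * delta / s2 + h * R * sigma / s2
        T = Pp * Gmu  # Gmu is d logf / d mu with mu = x2'beta2 + tau1
        gobs_mu = T.sum(axis=(0, 1))  # (Np,)
        g_beta2 = data.X2_pos.T @ gobs_mu
        if centers is None:
            g_L10 = float(np.einsum("ijn,i->", T, z))
            g_L11 = float(np.einsum("ijn,j->", T, z))
        else:
            g_L10 = float((U0[:, None, data.pos_subj] * T).sum())
            g_L11 = float((U1[:, :, data.pos_subj] * T).sum())
        g_sigma = float((Pp * Gsig).sum())
        g_delta = float((Pp * Gdel).sum())
    else:
        g_beta2 = np.zeros_like(beta2)
        g_L10 = g_L11 = g_sigma = g_delta = 0.0

    grads = {
        "beta1": g_beta1,
        "beta2": g_beta2,
        "sigma": g_sigma,
        "delta": g_delta,
        "L00": g_L00,
        "L10": g_L10,
        "L11": g_L11,
    }
    return ll, grads
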